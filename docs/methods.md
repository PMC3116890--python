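# Methods

This note records the modelling assumptions, default constants, numerical
choices and known limitations of `levmodel`. Nothing here states an
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## The generative model

One cortical unit comprises two single-compartment layer IV GABAergic
interneurons — a *transmission* interneuron driven by thalamo-cortical
input Ψ₁ and a *feedback* interneuron driven by pyramidal output — and a
layer V pyramidal cell with soma, basal and apical compartments (basal
receives thalamo-cortical input Ψ₂, apical the cortico-cortical input Ψ₃,
zero in the simulated protocol). Membrane potentials are deviations from
rest (mV) and obey `dV/dt = (−V + R·I)/τ_m`, with axial currents
`(V_i − V_j)/r_axial` between pyramidal compartments, GABAergic inhibition
`Ω·[θ(V_IN,t) + θ(V_IN,f)]` on the soma, and pyramidal excitation
`w_fb·θ_pc(V_soma)` of the feedback interneuron. Threshold functions are
logistics shifted to output zero at rest, so the all-zero state is an exact
fixed point. The EEG proxy is the apical axial current: layer V apical
dendrites are parallel and normal to the cortical surface, so their
extracellular currents sum coherently into the scalp signal.

Stimulation is a train of Gaussian current pulses (width = one 60 Hz screen
refresh interval, 1/60 s) at the checkerboard reversal rate, truncated at
±4 widths and at block boundaries, scaled per frequency by the measured
display luminance (1.00, 0.96, 0.93, 0.91, 0.88, 0.82, 0.74 for 4–30 Hz;
linear interpolation between table entries is enabled only in
frequency-scan mode). Ψ₂ lags Ψ₁ by 100 ms; a configurable flag allows the
alternative reading of which input carries the delay.

Three coupling mechanisms map unit activity to the Balloon drive: NO
release (even saturating function of soma capacitive currents, low-pass
filtered, plus a baseline concentration), pyramidal firing rate (logistic
of the soma potential), and their convex mixture. The hemodynamic model is
the canonical extended Balloon model with BOLD factors k₁ = 7E₀, k₂ = 2,
k₃ = 2E₀ − 0.2 and V₀ = 0.02 (1.5 T / TE 40 ms defaults).

### Mixture convention

The mixture combines components **scaled to unit SD** (SD taken over the
10 Hz block-meaned drive concatenated across the protocol frequencies), so
the coefficients (α, 1−α) compare the mechanisms on a common amplitude
scale. On natural scales the NO component dominates numerically and α is
confounded with the NO energetic factor (only the product α·k_IN would be
identified); with unit-SD components k_IN affects only the *shape* of the
NO component and the mixing weight is meaningful on its own. The same
convention is used in data generation and in fitting.

## Free parameters, priors and truths

Estimated parameters, their prior means (defaults) and the generating
("true") values of the recovery experiments:

| block | parameter | prior | truth | units |
|---|---|---|---|---|
| electrical | gain₁, gain₂, gain₃ (inputs Ψ₁–Ψ₃) | 1.00, 1.00, 1.00 | 0.80, 1.00, 0.50 | – |
| electrical | Ω (GABAergic synaptic factor) | 0.30 | 0.50 | – |
| electrical | v̄_pc, r_pc (PC voltage–ampere) | 0.60, 6.00 | 0.90, 4.00 | mV, 1/mV |
| vascular | κ (signal decay) | 0.65 | 0.50 | 1/s |
| vascular | γ (autoregulation) | 0.41 | 0.28 | 1/s |
| vascular | τ (transit time) | 0.98 | 0.78 | s |
| vascular | α_G (stiffness), E₀ (resting O₂ extraction) | 0.32, 0.34 | 0.25, 0.30 | – |
| NO coupling | u₀ (baseline), k_IN (energetic factor) | 0.10, 1.59·10³ | 0.30, 1.50·10³ | – |
| FR coupling | v̄_fr, r_fr | 0.78, 5.62 | 0.90, 4.00 | mV, 1/mV |
| mixture | α (NO coefficient; FR = 1−α) | 0.50 | 0.40 | – |

Strictly positive parameters are estimated through a log transform
`θ = prior_mean · exp(λ − s²/2)` with λ ~ N(0, s²), s = √ln 2, so the
lognormal *prior mean* equals the stated prior value and the prior
coefficient of variation is exactly 1. (0,1)-bounded parameters (α_G, E₀,
α) use a logit transform (prior SD √ln 2; 1.0 for α). Reported point
estimates are exact posterior means of the natural parameters, so a
parameter untouched by the data reports its prior mean.

Free-parameter counts in step 3: 7 for each single-mechanism model
(5 vascular + 2 coupling) and 10 for the mixture (+2 FR parameters and the
mixing weight).

## Reconstructed constants

The published description of this model family relegates the compartment
equations, fixed constants, the NO release function's parameters and the
input amplitudes to supplementary material that is not available, so the
fixed constants here are a documented reconstruction. They were calibrated
**once**, against the model family's reported qualitative behaviour —
phase-locked steady-state EEG, a synaptic-input frequency-response curve
peaking near 8 Hz with decline above, a non-decreasing spiking-output
curve, Balloon drive excursions of order 0.1–1, and coupling-parameter
recovery being possible at the design SNRs — and then frozen. No stated
value (priors, truths, SNRs, protocol timings, luminances) was ever
adjusted. Defaults: τ_m = 20 ms, all membrane resistances 1, axial
resistances 0.5, soma capacitances C = τ_m/R = 0.02, interneuron threshold
(v̄ = 1.5 mV, r = 4 mV⁻¹), PC→feedback gain 1, base input amplitude 3
(arbitrary current units), NO release g_max = 1, g_scale = 50, k_PC
(fixed) = 3.18·10³, filter gain 1, cut-off 2 rad/s, damping 0.7. Every
value is configurable.

## The synthetic-data generator

Per frequency, the full model is integrated over one 15.3 s stimulation +
15.3 s rest block (5 + 5 scans at TR 3.06 s) on a 1 ms grid with classical
RK4; EEG is reported at 100 Hz, the drive as 100-ms block means (10 Hz) and
BOLD once per TR, starting from the canonical hemodynamic rest state
(0, 1, 1, 1). The fitted data are a 2 s EEG segment per frequency taken
from the middle of the stimulation block (6.5–8.5 s, avoiding onset/offset
transients) and the 10-scan BOLD epoch. Both modalities are standardized
**globally** across the concatenated all-frequency series — per-frequency
standardization would erase the relative amplitudes across frequencies on
which the model comparison rests — and i.i.d. Gaussian noise is added on
the standardized scale at SNR 1 (EEG, σ = 1.0) and SNR 2 (BOLD, σ = 0.5);
SNR is signal SD over noise SD, the alternative σ reading is a parameter
away. Datasets are bit-reproducible given the seed.

What the generator does *not* emulate: multichannel scalp EEG with spatial
covariance (the lead field defaults to a scalar), scanner drift and
artifacts, trial-to-trial variability beyond observation noise, and
session/subject heterogeneity. A green recovery test therefore establishes
internal consistency of the pipeline at the stated noise level — not
robustness to the preprocessing chain of real recordings.

## Inversion: numerical choices

- Variational Laplace as regularized Gauss-Newton ascent on the free
  energy; Jacobians by central finite differences (relative step 1e-4).
- Levenberg-Marquardt damping multiplies the Hessian diagonal; each
  candidate step is evaluated with a fully refreshed Jacobian, covariance
  and noise estimate and accepted only if F does not decrease, so the
  accepted-step F trajectory is monotone by construction. Damping grows
  ×16 on rejection (up to 8 retries) and shrinks ÷4 on acceptance.
- Convergence: ΔF < 0.01 nats on 3 consecutive accepted steps, cap 32
  iterations. Multistart from deterministically jittered prior means with
  the best-F result kept: step-3 fits default to 4 starts (their landscape
  shows occasional local optima), step-1 fits to a single start (measured
  start-robust).
- Noise: a single isotropic variance per modality, updated each accepted
  iteration by its closed-form maximizer of F (empirical Bayes with a flat
  hyperprior); can be fixed for oracle tests. On linear-Gaussian problems
  with fixed noise the scheme reproduces the conjugate posterior and the
  exact log evidence (tested to 1e-6 relative).
- Prediction scaling: the data are standardized series; the forward
  prediction is mean-corrected and multiplied by a **fixed** per-modality
  observation gain obtained by a one-off least-squares regression of the
  data on the prior-mean prediction (the scalar analogue of a known
  lead-field/scanner gain). Re-standardizing every prediction would make
  the input gain and the GABAergic factor exactly scale-degenerate; a
  fixed gain keeps amplitude information while using only prior
  information.
- Step 3 integrates the Balloon model at TR/30 = 0.102 s so scan times fall
  exactly on grid nodes; 10 Hz drives are linearly interpolated. The soma
  potential is carried at 100 Hz into step 3 so the firing-rate logistic
  (whose parameters are free there) is applied before the 10 Hz block-mean
  (applying it after would alias the drive's harmonics).
- Positivity of the hemodynamic states is guaranteed by integrating
  log f, log v, log q internally — an implementation device, not a model
  change.
- Model comparison reports ties when |ΔF| < 0.05 instead of ranking noise.

## Known limitations

- **Estimator precision at the design SNRs.** With 70 BOLD samples at
  noise SD 0.5, the posteriors of the mixing coefficient and the NO
  baseline are diffuse (posterior SDs ≈ 0.2 and 0.08). Across noise
  realizations the mixing-coefficient posterior mean scatters around
  ~0.5 for a generating value of 0.40 (prior shrinkage plus a genuine
  functional near-degeneracy: a mixture at α = 0.5 with shifted
  firing-rate and baseline parameters reproduces α = 0.4 data almost
  exactly, noise-free). Tests therefore use the 2-posterior-SD criterion
  alongside the 0.05 absolute band.
- The electrical step has a mild (+~10%) sampling bias on the GABAergic
  factor at EEG SNR 1.
- **Model recovery is not certain at the design SNRs.** For a minority of
  noise realizations the spiking-output model edges out the mixture on
  mixture-generated data by ~1 nat: the mixture nests the single
  mechanisms, so when noise masks the NO contribution its extra parameters
  cost more than they explain. The winner and the minimum Bayes factor are
  therefore seed-dependent.
- Vascular parameters are only weakly identified from standardized epoched
  BOLD and often remain near their priors — consistent with the behaviour
  this model family reports.
- Fixed-effects (summed log-evidence) group inference only; random-effects
  model selection across subjects is out of scope.
- The frequency regimes (low 4–15 Hz, high 10–30 Hz) deliberately overlap,
  reproducing the original analysis design rather than "fixing" it.
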