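# levmodel

Generative modelling of coupled EEG–BOLD signals from a single cortical
unit, for asking a specific physiological question: **is the BOLD response
driven by synaptic input, by spiking output, or by a mixture of the two?**

The package implements a local electro-vascular (LEV) model — a neural mass
model of a visual-cortex unit (two layer IV GABAergic interneurons and a
three-compartment layer V pyramidal cell) coupled to the extended Balloon
hemodynamic model through one of three neurovascular coupling mechanisms —
together with a variational-Laplace inversion scheme and Bayesian model
comparison, and a synthetic-data generator that emulates a
reversing-checkerboard EEG–fMRI experiment (7 flicker frequencies between
4 and 30 Hz, 15.3 s stimulation / 15.3 s rest blocks, EEG at 100 Hz, BOLD
every TR = 3.06 s). It is aimed at researchers studying neurovascular
coupling and EEG–fMRI fusion who want a fully reproducible simulation and
estimation pipeline with no external data.

## The model

**Electrical.** Each compartment follows leaky voltage-source dynamics
`dV/dt = (−V + R·I)/τ_m`, with logistic threshold functions
`σ(v) = 1/(1 + exp(−r(v − v̄)))` (shifted to vanish at rest) mediating
GABAergic inhibition onto the pyramidal soma and pyramidal excitation of the
feedback interneuron. The EEG-visible signal is the axial current along the
apical dendrite, `j = (V_apical − V_soma)/r_axial`. Stimulation enters as
Gaussian current pulses at the checkerboard reversal rate, scaled per
frequency by measured display luminance.

**Coupling** (the drive `u(t)` of the Balloon model):

- *synaptic input*: total nitric-oxide release, an even saturating function
  `g(x) = g_max x²/(g_scale² + x²)` of the soma capacitive currents `C dV/dt`
  (both de- and hyperpolarizing transients release NO), low-pass filtered
  (second order, gain ε, cut-off ω, damping d) on top of a baseline
  concentration `u₀`;
- *spiking output*: the pyramidal population firing rate,
  `u = σ(V_soma; v̄_fr, r_fr)`;
- *mixture*: `u = α·û_NO + (1−α)·û_FR` with the components scaled to unit
  SD, so α weighs the two mechanisms on a common amplitude scale.

**Hemodynamic.** The extended Balloon model:
`ds/dt = u − κs − γ(f−1)`, `df/dt = s`, `τ dv/dt = f − v^{1/α}`,
`τ dq/dt = f·E(f)/E₀ − v^{1/α} q/v`, with BOLD read out as
`y = V₀(k₁(1−q) + k₂(1−q/v) + k₃(1−v))`.

**Inversion.** Gaussian priors (log/logit transforms keep parameters in
their domains; prior coefficient of variation 1), variational Laplace
(regularized Gauss-Newton ascent on the free energy
`F = accuracy − KL(posterior ‖ prior)`), organized in three steps: (1) fit
the six electrical parameters to 2-s standardized EEG segments per
frequency; (2) integrate the neural and coupling equations once at the
electrical posterior means; (3) fit the vascular + coupling parameters of
each candidate model to the epoched BOLD series. The step-3 free energy is
the log-evidence surrogate; models are compared via Bayes factors
(log-BF 3 ≈ BF 20 = "strong evidence"), posterior model probabilities, and
fixed-effects group evidence, optionally per frequency regime
(low 4–15 Hz, high 10–30 Hz, all).

## Worked example

```python
from levmodel import frequency_response_curve, LEVParams, StimulusProtocol
from levmodel.model_selection import model_recovery_experiment

curve = frequency_response_curve(
    LEVParams.synthetic_truth(), "in",
    [4.0, 7.5, 8.0, 10.0, 12.0, 15.0, 20.0, 30.0],
    StimulusProtocol(), normalize=True)

exp = model_recovery_experiment(seed=0)   # ~20 s on one CPU
```

Printing the curve, the per-dataset winners and two recovered parameters
gives (actual output of this example):

```
synaptic-input frequency response (normalized):
    4.0 Hz  0.647
    7.5 Hz  0.980
    8.0 Hz  1.000
   10.0 Hz  0.977
   12.0 Hz  0.930
   15.0 Hz  0.773
   20.0 Hz  0.196
   30.0 Hz  0.077

model recovery (seed 0):
  data from 'in': winner 'in', log-BF vs runner-up 2.83, p(true model) 0.944
  data from 'out': winner 'out', log-BF vs runner-up 8.74, p(true model) 1.000
  data from 'mix': winner 'mix', log-BF vs runner-up 9.71, p(true model) 1.000

NO baseline posterior mean 0.288 (truth 0.30)
GABAergic factor posterior mean 0.482 (truth 0.50)
```

Reading: the synaptic-input mechanism predicts a BOLD response that peaks
near 8 Hz and collapses at high flicker rates (the spiking-output
mechanism's curve, by contrast, rises monotonically with frequency) — so
the two hypotheses are separable from BOLD data alone. In the recovery
experiment each synthetic dataset is correctly attributed to the mechanism
that generated it, and the coupling parameters are recovered from noisy
data (SNR 1 EEG, SNR 2 BOLD).

A CLI mirrors the library: `levmodel simulate | freqscan | fit | compare |
recover` (see `levmodel --help`); configuration is YAML
(protocol, coupling, noise/seed, optimizer), results are HDF5/CSV/JSON with
a checksummed manifest.

## Acceptance script

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes, from scratch at the given seed: the model-recovery experiment
(minimum Bayes factor and posterior probability of the generating model
across the three synthetic datasets), the posterior means of the mixture
coefficients, the NO baseline and the GABAergic synaptic factor from the
corresponding fits, and the frequency at which the synaptic-input model's
BOLD response peaks. It writes one JSON object keyed by target id.

See `docs/methods.md` for the modelling assumptions, the reconstruction of
fixed constants, numerical choices, and known limitations.
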