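"""Variational-Laplace model inversion and the three-step fitting scheme.

The core optimizer assumes a nonlinear observation y = h(theta) + e with
i.i.d. Gaussian noise and a Gaussian prior, and maximizes the variational
free energy

    F = E_q[log p(y | theta)] - KL(q || prior)

over a Gaussian posterior q = N(m, S) by regularized Gauss-Newton ascent
(Levenberg-Marquardt damping with step retries on F decrease).  With the
local linearization h(theta) ~ h(m) + J (theta - m),

    F = -n/2 log(2 pi s2) - (||r||^2 + tr(J S J')) / (2 s2)
        - 1/2 [ (m-m0)' P0 (m-m0) + tr(P0 S) - p + log det(S0) - log det(S) ]

which is exact (equals the log evidence) for linear-Gaussian problems.  The
noise variance per modality is either fixed or updated by its closed-form
maximizer of F (empirical Bayes); each candidate step is evaluated with a
fully refreshed Jacobian, covariance and noise scale, and accepted only if
F does not decrease, so the recorded F trajectory is monotone by
construction.

The disparity between EEG (100 Hz) and BOLD (one sample per TR) time scales
is handled by a three-step scheme: (1) fit the six electrical parameters to
2-s standardized EEG segments per frequency; (2) integrate the neural and
coupling equations once at the electrical posterior means, emitting the
vascular drive ingredients at 10 Hz; (3) fit the vascular + coupling
parameters of each candidate model to the epoched BOLD series.  The step-3
free energy is the model-comparison score.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .coupling import (FRCouplingParams, MixtureParams, NOCouplingParams,
                       firing_rate_drive, mixture_drive, no_drive_components)
from .hemodynamics import BoldObsParams, HemodynamicParams, bold_observation
from . import _kernels
from .neural_mass import ElectricalConstants, ElectricalParams, simulate_electrical
from .observation import standardize
from .priors import ParamSpec, electrical_specs, prior_moments, step3_specs, to_natural
from .stimulus import StimulusProtocol, build_protocol_inputs

__all__ = [
    "GaussianDensity", "VLSettings", "InversionResult", "DriveComponents",
    "variational_laplace", "invert_electrical_step1",
    "integrate_coupling_step2", "invert_hemodynamic_step3",
    "multistep_invert", "fit_all_models",
]


@dataclass(frozen=True)
class GaussianDensity:
    """Gaussian density over the unconstrained parameter vector."""

    mean: np.ndarray
    cov: np.ndarray

    def __post_init__(self) -> None:
        m = np.atleast_1d(np.asarray(self.mean, dtype=float))
        c = np.atleast_2d(np.asarray(self.cov, dtype=float))
        if c.shape != (m.size, m.size):
            raise ValueError("covariance shape must match mean length")
        if not np.allclose(c, c.T, atol=1e-10):
            raise ValueError("covariance must be symmetric")
        if np.any(np.linalg.eigvalsh(c) <= 0):
            raise ValueError("covariance must be positive definite")
        object.__setattr__(self, "mean", m)
        object.__setattr__(self, "cov", c)


@dataclass(frozen=True)
class VLSettings:
    """Optimizer policy for the variational-Laplace scheme."""

    max_iter: int = 32
    f_tol: float = 0.01  #: free-energy convergence tolerance (nats)
    n_converged: int = 3  #: consecutive small improvements to declare done
    noise_mode: str = "estimated"  #: 'estimated' | 'fixed'
    sigma0: float = 1.0  #: initial (or fixed) noise SD
    fd_step: float = 1e-4  #: central finite-difference step
    reg_init: float = 1e-6
    reg_up: float = 16.0
    reg_down: float = 4.0
    max_retries: int = 8
    n_starts: int = 1  #: multistart count (jittered prior-mean inits)
    start_jitter: float = 0.5  #: SD of the deterministic init jitter
    start_seed: int = 0  #: seed of the jitter stream (determinism)

    def __post_init__(self) -> None:
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")
        if self.f_tol <= 0:
            raise ValueError("f_tol must be > 0")
        if self.noise_mode not in ("estimated", "fixed"):
            raise ValueError("noise_mode must be 'estimated' or 'fixed'")


@dataclass(frozen=True)
class InversionResult:
    """Posterior, free energy and bookkeeping for one fit."""

    posterior: GaussianDensity
    free_energy: float
    f_trajectory: tuple[float, ...]
    residual_sd: float
    converged: bool
    model_id: str = ""
    specs: tuple[ParamSpec, ...] = ()
    n_data: int = 0

    @property
    def natural_means(self) -> dict[str, float]:
        """Exact posterior means of the natural parameters."""
        sds = np.sqrt(np.diag(self.posterior.cov))
        return {s.name: s.posterior_mean(float(m), float(sd))
                for s, m, sd in zip(self.specs, self.posterior.mean, sds)}

    @property
    def natural_medians(self) -> dict[str, float]:
        """Posterior medians (transform of the unconstrained mean)."""
        return to_natural(list(self.specs), self.posterior.mean)

    @property
    def natural_sds(self) -> dict[str, float]:
        sds = np.sqrt(np.diag(self.posterior.cov))
        return {s.name: s.natural_sd(float(m), float(sd))
                for s, m, sd in zip(self.specs, self.posterior.mean, sds)}


def _jacobian(predict, m: np.ndarray, h: np.ndarray, step: float) -> np.ndarray:
    p = m.size
    jac = np.empty((h.size, p))
    for i in range(p):
        d = step * (1.0 + abs(m[i]))
        mp = m.copy(); mp[i] += d
        mm = m.copy(); mm[i] -= d
        jac[:, i] = (predict(mp) - predict(mm)) / (2.0 * d)
    return jac


def _free_energy(r, jac, cov, sigma2, m, m0, prior_prec, prior_logdet, p):
    n = r.size
    tr_pred = float(np.sum((jac @ cov) * jac))
    accuracy = (-0.5 * n * np.log(2.0 * np.pi * sigma2)
                - (r @ r + tr_pred) / (2.0 * sigma2))
    dm = m - m0
    sign, logdet_cov = np.linalg.slogdet(cov)
    kl = 0.5 * (dm @ prior_prec @ dm + np.trace(prior_prec @ cov)
                - p + prior_logdet - logdet_cov)
    return accuracy - kl


def variational_laplace(
    predict,
    data: np.ndarray,
    prior: GaussianDensity,
    settings: VLSettings | None = None,
    model_id: str = "",
    specs: tuple[ParamSpec, ...] = (),
    init: np.ndarray | None = None,
) -> InversionResult:
    """Gauss-Newton variational Laplace with monotone accepted-step F.

    ``predict`` maps an unconstrained parameter vector to a predicted data
    vector (deterministic; differentiated by central finite differences).
    """
    settings = settings or VLSettings()
    if settings.n_starts > 1:
        # local-minima mitigation: deterministic jittered restarts, the
        # best-F result is kept
        rng = np.random.default_rng(settings.start_seed)
        single = replace(settings, n_starts=1)
        best = None
        for k in range(settings.n_starts):
            start = init
            if k > 0:
                start = prior.mean + rng.normal(
                    0.0, settings.start_jitter, size=prior.mean.size)
            try:
                res = variational_laplace(predict, data, prior, single,
                                          model_id=model_id, specs=specs,
                                          init=start)
            except FloatingPointError:
                continue
            if best is None or res.free_energy > best.free_energy:
                best = res
        if best is None:
            raise FloatingPointError(
                "model prediction non-finite at every start")
        return best
    y = np.asarray(data, dtype=float)
    if not np.all(np.isfinite(y)):
        raise ValueError("data must be finite")
    m0 = prior.mean
    p = m0.size
    prior_prec = np.linalg.inv(prior.cov)
    _, prior_logdet = np.linalg.slogdet(prior.cov)

    def evaluate(m, sigma2_start):
        """Full state at m: prediction, Jacobian, covariance, noise, F.

        Any numerical failure (divergent integration, overflow) marks the
        point as invalid; the step policy treats that as a rejection.
        """
        try:
            h = predict(m)
            if h.shape != y.shape or not np.all(np.isfinite(h)):
                return None
            r = y - h
            jac = _jacobian(predict, m, h, settings.fd_step)
        except (FloatingPointError, ZeroDivisionError, OverflowError,
                ValueError):
            return None
        if not np.all(np.isfinite(jac)):
            return None
        jtj = jac.T @ jac
        sigma2 = sigma2_start
        n = y.size
        for _ in range(4 if settings.noise_mode == "estimated" else 1):
            post_prec = jtj / sigma2 + prior_prec
            cov = np.linalg.inv(post_prec)
            cov = 0.5 * (cov + cov.T)
            if settings.noise_mode == "estimated":
                tr_pred = float(np.sum((jac @ cov) * jac))
                sigma2 = max((r @ r + tr_pred) / n, 1e-12)
        f = _free_energy(r, jac, cov, sigma2, m, m0, prior_prec,
                         prior_logdet, p)
        return {"m": m, "r": r, "jac": jac, "cov": cov,
                "sigma2": sigma2, "F": f}

    m = m0.copy() if init is None else np.asarray(init, dtype=float).copy()
    cur = evaluate(m, settings.sigma0**2)
    if cur is None:
        raise FloatingPointError("model prediction non-finite at the prior mean")
    f_traj = [cur["F"]]
    reg = settings.reg_init
    converged = False
    streak = 0
    for _ in range(settings.max_iter):
        g = (cur["jac"].T @ cur["r"]) / cur["sigma2"] - prior_prec @ (m - m0)
        hess = cur["jac"].T @ cur["jac"] / cur["sigma2"] + prior_prec
        accepted = None
        for _retry in range(settings.max_retries):
            damped = hess + reg * np.diag(np.diag(hess))
            try:
                delta = np.linalg.solve(damped, g)
            except np.linalg.LinAlgError:
                reg *= settings.reg_up
                continue
            cand = evaluate(m + delta, cur["sigma2"])
            if cand is not None and cand["F"] >= cur["F"] - 1e-12:
                accepted = cand
                reg = max(reg / settings.reg_down, 1e-8)
                break
            reg *= settings.reg_up
        if accepted is None:
            break
        df = accepted["F"] - cur["F"]
        cur = accepted
        m = cur["m"]
        f_traj.append(cur["F"])
        streak = streak + 1 if df < settings.f_tol else 0
        if streak >= settings.n_converged:
            converged = True
            break
    return InversionResult(
        posterior=GaussianDensity(mean=m, cov=cur["cov"]),
        free_energy=float(cur["F"]),
        f_trajectory=tuple(float(v) for v in f_traj),
        residual_sd=float(np.sqrt(cur["sigma2"])),
        converged=converged,
        model_id=model_id,
        specs=tuple(specs),
        n_data=y.size,
    )


# ---------------------------------------------------------------------------
# Multi-step scheme
# ---------------------------------------------------------------------------

#: EEG fitting segment within the stimulation block (s from block onset).
SEGMENT_WINDOW = (6.5, 8.5)


def _electrical_params(values: dict[str, float]) -> ElectricalParams:
    return ElectricalParams(**{k: values[k] for k in
                               ("gain1", "gain2", "gain3", "gaba_factor",
                                "pc_vbar", "pc_r")})


def _predict_eeg_segments(
    theta: ElectricalParams,
    base_trains: dict[float, tuple[np.ndarray, np.ndarray, np.ndarray]],
    consts: ElectricalConstants,
    dt: float,
    seg_idx: tuple[int, int],
) -> np.ndarray:
    """Concatenated raw 100 Hz EEG segments for all frequencies."""
    segs = []
    for f in base_trains:
        b1, b2, b3 = base_trains[f]
        traj = simulate_electrical(theta.gain1 * b1, theta.gain2 * b2,
                                   theta.gain3 * b3, theta, consts, dt)
        j = traj.extracellular_current[::10]  # 1 kHz -> 100 Hz
        segs.append(j[seg_idx[0]:seg_idx[1]])
    return np.concatenate(segs)


def _fixed_gain_observation(raw: np.ndarray, gain: float) -> np.ndarray:
    """Mean-correct and apply the fixed observation gain.

    The fitted data are standardized series; predictions are mapped to the
    same convention with a single gain calibrated at the natural prior-mean
    parameters (the model's unit convention), NOT re-standardized per
    prediction.  A
    per-prediction standardization would discard all amplitude information
    and make the input gain and the GABAergic factor exactly degenerate.
    """
    return (raw - raw.mean()) * gain


def _calibration_gain(raw0: np.ndarray, y: np.ndarray | None = None) -> float:
    """Observation gain fixed before optimization.

    With data ``y`` supplied, the gain is the least-squares regression of
    the (mean-corrected) data on the prior-mean prediction — the scalar
    analogue of estimating a known lead-field/scanner gain once before the
    fit.  Without data it falls back to unit prior-predictive SD.  Either
    way the gain is then held fixed, so amplitude information constrains
    the parameters.
    """
    h0 = raw0 - raw0.mean()
    denom = float(h0 @ h0)
    if denom == 0 or not np.isfinite(denom):
        raise FloatingPointError("degenerate prior-mean prediction")
    if y is not None:
        yc = y - y.mean()
        g = float(h0 @ yc) / denom
        if np.isfinite(g) and g > 0:
            return g
    return 1.0 / float(np.std(h0, ddof=1))


def invert_electrical_step1(
    eeg_segments: dict[float, np.ndarray],
    protocol: StimulusProtocol,
    consts: ElectricalConstants | None = None,
    settings: VLSettings | None = None,
    dt: float = 1e-3,
    segment_window: tuple[float, float] = SEGMENT_WINDOW,
) -> InversionResult:
    """Step 1: fit the six electrical parameters to per-frequency EEG.

    ``eeg_segments`` maps frequency (Hz) to a standardized 100 Hz segment
    (200 samples for the default 2-s window).  Predictions are integrated
    at 1 ms, downsampled by 10 and standardized across the concatenated
    segments, mirroring the data processing.
    """
    consts = consts or ElectricalConstants()
    settings = settings or VLSettings()
    specs = electrical_specs()
    freqs = [f for f in protocol.frequencies if f in eeg_segments]
    if not freqs:
        raise ValueError("no protocol frequency present in eeg_segments")
    y = np.concatenate([np.asarray(eeg_segments[f], dtype=float)
                        for f in freqs])
    # integrate only up to the segment end: the fit does not need the rest
    t_end = segment_window[1]
    n = int(round(t_end / dt))
    unit = replace(ElectricalParams(), gain1=1.0, gain2=1.0, gain3=1.0)
    base: dict[float, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
    for f in freqs:
        p1, p2, p3 = build_protocol_inputs(f, unit, protocol, dt,
                                           duration=n * dt)
        base[f] = (p1.values, p2.values, p3.values)
    i0 = int(round(segment_window[0] * 100))
    i1 = int(round(segment_window[1] * 100))
    m0, cov0 = prior_moments(specs)

    def predict_raw(lam):
        vals = to_natural(specs, lam)
        return _predict_eeg_segments(_electrical_params(vals), base,
                                     consts, dt, (i0, i1))

    lam_nat = np.array([sp.lam_natural for sp in specs])
    gain = _calibration_gain(predict_raw(lam_nat), y)

    def predict(lam):
        return _fixed_gain_observation(predict_raw(lam), gain)

    return variational_laplace(predict, y, GaussianDensity(m0, cov0),
                               settings, model_id="electrical",
                               specs=tuple(specs))


@dataclass(frozen=True)
class DriveComponents:
    """Step-2 output for one frequency: drive ingredients for step 3.

    The NO drive is linear in (baseline, k_in) once the release terms have
    been low-pass filtered, so only the unit-coefficient filtered components
    are stored; the firing-rate nonlinearity has free parameters, so the PC
    soma potential is kept at 100 Hz and the logistic is applied in step 3
    before block-averaging to 10 Hz.
    """

    a_in: np.ndarray  #: filtered interneuron NO release @ 10 Hz (unit k_in)
    a_pc: np.ndarray  #: filtered PC NO release @ 10 Hz (unit k_pc)
    v_soma: np.ndarray  #: PC soma potential @ 100 Hz
    rate: float = 10.0


def _block_mean(x: np.ndarray, factor: int) -> np.ndarray:
    n = (len(x) // factor) * factor
    return x[:n].reshape(-1, factor).mean(axis=1)


def integrate_coupling_step2(
    elec_params: ElectricalParams,
    protocol: StimulusProtocol,
    consts: ElectricalConstants | None = None,
    no_params: NOCouplingParams | None = None,
    dt: float = 1e-3,
    frequencies: tuple[float, ...] | None = None,
    *,
    interpolate_luminance: bool = False,
) -> dict[float, DriveComponents]:
    """Step 2: one full neural + coupling integration per frequency.

    Runs the neural mass model over a whole stimulation + rest block and
    emits, per frequency, the 10 Hz drive ingredients consumed by step 3.
    ``no_params`` supplies only the *fixed* part of the NO pathway (release
    shape and filter constants); its free coefficients are ignored here.
    """
    consts = consts or ElectricalConstants()
    no_params = no_params or NOCouplingParams()
    out: dict[float, DriveComponents] = {}
    for f in (frequencies or protocol.frequencies):
        p1, p2, p3 = build_protocol_inputs(
            f, elec_params, protocol, dt,
            interpolate_luminance=interpolate_luminance)
        traj = simulate_electrical(p1, p2, p3, elec_params, consts, dt)
        a_in, a_pc = no_drive_components(traj, no_params, dt)
        factor10 = int(round(1.0 / (10.0 * dt)))
        factor100 = int(round(1.0 / (100.0 * dt)))
        out[f] = DriveComponents(
            a_in=_block_mean(a_in, factor10),
            a_pc=_block_mean(a_pc, factor10),
            v_soma=_block_mean(traj.v_pc_soma, factor100),
        )
    return out


def _balloon_equilibrium(u_rest: float, hp: HemodynamicParams) -> np.ndarray:
    """Fixed point (s, log f, log v, log q) under constant drive."""
    f = 1.0 + u_rest / hp.gamma_fb
    v = f ** hp.alpha_g
    e_f = 1.0 - (1.0 - hp.e0) ** (1.0 / f)
    q = v * e_f / hp.e0
    return np.array([0.0, np.log(f), np.log(v), np.log(q)])


def _component_drives_10hz(vals, comp: DriveComponents,
                           no_fixed: NOCouplingParams, model_id: str):
    """Per-frequency 10 Hz component drives for one parameter setting."""
    out = {}
    if model_id in ("in", "mix"):
        out["u_no"] = (no_fixed.filt_gain * vals["baseline"]
                       + vals["k_in"] * comp.a_in
                       + no_fixed.k_pc * comp.a_pc)
        out["u_no_rest"] = no_fixed.filt_gain * vals["baseline"]
    if model_id in ("out", "mix"):
        fr = FRCouplingParams(fr_vbar=vals["fr_vbar"], fr_r=vals["fr_r"])
        out["u_fr"] = _block_mean(firing_rate_drive(comp.v_soma, fr), 10)
        out["u_fr_rest"] = float(firing_rate_drive(np.zeros(1), fr)[0])
    return out


def predict_bold(
    model_id: str,
    vals: dict[str, float],
    components: dict[float, DriveComponents],
    frequencies: list[float],
    tr: float,
    n_scans: int,
    no_fixed: NOCouplingParams,
    dt: float | None = None,
    obs_gain: float | None = None,
) -> np.ndarray:
    """Concatenated BOLD epochs predicted for one model.

    With ``obs_gain`` the raw concatenated prediction is mean-corrected and
    scaled by that fixed gain (the standardized-data convention); without it
    the raw prediction is returned.
    """
    hp = HemodynamicParams(**{k: vals[k] for k in
                              ("kappa", "gamma_fb", "tau_t", "alpha_g", "e0")})
    obs = BoldObsParams.for_e0(hp.e0)
    dt = dt if dt is not None else tr / 30.0
    steps_per_scan = int(round(tr / dt))
    comps = {f: _component_drives_10hz(vals, components[f], no_fixed,
                                       model_id) for f in frequencies}
    if model_id == "in":
        drives = {f: comps[f]["u_no"] for f in frequencies}
    elif model_id == "out":
        drives = {f: comps[f]["u_fr"] for f in frequencies}
    else:
        # mixture: components scaled to unit SD over the fitted frequencies
        s_no = float(np.std(np.concatenate(
            [comps[f]["u_no"] for f in frequencies])))
        s_fr = float(np.std(np.concatenate(
            [comps[f]["u_fr"] for f in frequencies])))
        s_no = s_no if s_no > 1e-12 else 1.0
        s_fr = s_fr if s_fr > 1e-12 else 1.0
        a = vals["alpha_no"]
        drives = {f: a * comps[f]["u_no"] / s_no
                  + (1.0 - a) * comps[f]["u_fr"] / s_fr
                  for f in frequencies}
    epochs = []
    for f in frequencies:
        u = drives[f]
        n_out = (n_scans - 1) * steps_per_scan + 1
        x0 = np.zeros(4)  # canonical rest state at epoch onset
        states = _kernels.integrate_balloon(
            np.ascontiguousarray(u, dtype=float), 0.1, dt, n_out,
            hp.kappa, hp.gamma_fb, hp.tau_t, hp.alpha_g, hp.e0, x0)
        idx = np.arange(n_scans) * steps_per_scan
        y = bold_observation(states[idx, 2], states[idx, 3], obs)
        epochs.append(y)
    raw = np.concatenate(epochs)
    if obs_gain is None:
        return raw
    return _fixed_gain_observation(raw, obs_gain)


def invert_hemodynamic_step3(
    components: dict[float, DriveComponents],
    bold_epochs: dict[float, np.ndarray],
    model_id: str,
    protocol: StimulusProtocol,
    settings: VLSettings | None = None,
    no_fixed: NOCouplingParams | None = None,
    frequencies: list[float] | None = None,
) -> InversionResult:
    """Step 3: fit vascular + coupling parameters to epoched BOLD.

    The parameter set is 5 vascular + 2 coupling for the single-mechanism
    models and 5 + 4 + 1 (mixing coefficient) for the mixture.  Returns the
    result whose free energy is the model-selection score.
    """
    if model_id not in ("in", "out", "mix"):
        raise ValueError(f"unknown coupling model {model_id!r}")
    # step-3 landscapes have occasional local optima; default to multistart
    settings = settings or VLSettings(n_starts=4)
    no_fixed = no_fixed or NOCouplingParams()
    freqs = [f for f in (frequencies or protocol.frequencies)
             if f in bold_epochs]
    if not freqs:
        raise ValueError("no requested frequency present in bold_epochs")
    missing = [f for f in freqs if f not in components]
    if missing:
        raise ValueError(f"missing step-2 components for {missing}")
    y = np.concatenate([np.asarray(bold_epochs[f], dtype=float)
                        for f in freqs])
    n_scans = len(bold_epochs[freqs[0]])
    specs = step3_specs(model_id)
    m0, cov0 = prior_moments(specs)

    def predict_raw(lam):
        vals = to_natural(specs, lam)
        return predict_bold(model_id, vals, components, freqs,
                            protocol.tr, n_scans, no_fixed)

    lam_nat = np.array([sp.lam_natural for sp in specs])
    gain = _calibration_gain(predict_raw(lam_nat), y)

    def predict(lam):
        return _fixed_gain_observation(predict_raw(lam), gain)

    return variational_laplace(predict, y, GaussianDensity(m0, cov0),
                               settings, model_id=model_id,
                               specs=tuple(specs))


def multistep_invert(
    dataset,
    model_id: str,
    settings: VLSettings | None = None,
    consts: ElectricalConstants | None = None,
    no_fixed: NOCouplingParams | None = None,
    step1_result: InversionResult | None = None,
    step2_components: dict[float, DriveComponents] | None = None,
    frequencies: list[float] | None = None,
) -> tuple[InversionResult, InversionResult, dict[float, DriveComponents]]:
    """Run steps 1-3 for one coupling model on one dataset.

    Step 1 is coupling-independent, so a cached ``step1_result`` (and the
    matching ``step2_components``) may be supplied to fit several models to
    the same data without re-estimating the electrical parameters.  Returns
    ``(step3_result, step1_result, step2_components)``.
    """
    protocol = dataset.protocol
    if step1_result is None:
        step1_result = invert_electrical_step1(
            dataset.eeg, protocol, consts=consts, settings=settings)
    if step2_components is None:
        elec = _electrical_params(step1_result.natural_means)
        step2_components = integrate_coupling_step2(
            elec, protocol, consts=consts, no_params=no_fixed)
    step3 = invert_hemodynamic_step3(
        step2_components, dataset.bold, model_id, protocol,
        settings=settings, no_fixed=no_fixed, frequencies=frequencies)
    return step3, step1_result, step2_components


def fit_all_models(
    dataset,
    settings: VLSettings | None = None,
    consts: ElectricalConstants | None = None,
    no_fixed: NOCouplingParams | None = None,
    frequencies: list[float] | None = None,
) -> dict:
    """Fit the three coupling models to one dataset, sharing steps 1-2.

    Returns ``{"step1": InversionResult, "step2": components,
    "step3": {model_id: InversionResult}}``.
    """
    step1 = step2 = None
    fits: dict[str, InversionResult] = {}
    for mid in ("in", "out", "mix"):
        res, step1, step2 = multistep_invert(
            dataset, mid, settings=settings, consts=consts,
            no_fixed=no_fixed, step1_result=step1,
            step2_components=step2, frequencies=frequencies)
        fits[mid] = res
    return {"step1": step1, "step2": step2, "step3": fits}
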