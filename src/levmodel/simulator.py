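"""Forward simulation of the full local electro-vascular model.

Per stimulation frequency the neural, coupling and hemodynamic equations
are integrated jointly on a 1-ms grid over one 15.3-s stimulation +
15.3-s rest block; the EEG proxy is reported at 100 Hz, the Balloon drive
at 10 Hz and the BOLD signal once per TR.  The synthetic-data generator
reproduces the study design: seven reversal frequencies with luminance
scaling, a 2-s EEG fitting segment from the middle of the stimulation
block, one BOLD epoch of 10 scans per frequency, global standardization
per modality, and additive i.i.d. Gaussian noise at SNR 1 (EEG) and 2
(BOLD) on the standardized signals.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .coupling import (FRCouplingParams, MixtureParams, NOCouplingParams,
                       capacitive_no_release, firing_rate_drive,
                       mixture_drive, no_lowpass_drive)
from .hemodynamics import (BoldObsParams, HemodynamicParams,
                           bold_observation)
from . import _kernels
from .inversion import SEGMENT_WINDOW, _block_mean
from .neural_mass import ElectricalConstants, ElectricalParams, simulate_electrical
from .observation import (DEFAULT_SIGMA_BOLD, DEFAULT_SIGMA_EEG, LeadField,
                          add_observation_noise, eeg_forward, standardize)
from .stimulus import StimulusProtocol, build_protocol_inputs, luminance_factor

__all__ = [
    "LEVParams", "LEVSimulation", "SyntheticDataset",
    "integrate_lev", "frequency_response_curve", "generate_synthetic_dataset",
    "mixture_component_scales",
]


@dataclass(frozen=True)
class LEVParams:
    """Complete parameter record of the local electro-vascular model."""

    electrical: ElectricalParams = field(default_factory=ElectricalParams)
    hemodynamic: HemodynamicParams = field(default_factory=HemodynamicParams)
    no: NOCouplingParams = field(default_factory=NOCouplingParams)
    fr: FRCouplingParams = field(default_factory=FRCouplingParams)
    mixture: MixtureParams = field(default_factory=MixtureParams)

    @classmethod
    def priors(cls) -> "LEVParams":
        """Prior-mean parameter record."""
        return cls()

    @classmethod
    def synthetic_truth(cls) -> "LEVParams":
        """Generating values of the recovery experiments."""
        return cls(
            electrical=ElectricalParams.synthetic_truth(),
            hemodynamic=HemodynamicParams.synthetic_truth(),
            no=NOCouplingParams.synthetic_truth(),
            fr=FRCouplingParams.synthetic_truth(),
            mixture=MixtureParams.synthetic_truth(),
        )


@dataclass(frozen=True)
class LEVSimulation:
    """One integrated block at one frequency.

    The hemodynamic state starts at canonical rest (0, 1, 1, 1), so a
    sustained rest drive (e.g. the NO baseline) produces an onset transient;
    ``bold_rest`` is the trace obtained under the rest drive alone and
    serves as the reference for stimulus-evoked amplitude.
    """

    freq: float
    eeg: np.ndarray  #: extracellular-current EEG proxy @ 100 Hz
    drive: np.ndarray  #: Balloon drive @ 10 Hz (block means)
    bold: np.ndarray  #: BOLD signal at TR samples (fractional change)
    bold_rest: np.ndarray  #: BOLD trace under the rest drive alone
    eeg_rate: float = 100.0
    drive_rate: float = 10.0

    @property
    def peak_amplitude(self) -> float:
        """Maximum stimulus-evoked BOLD deflection above the rest trace."""
        return float(np.max(self.bold - self.bold_rest))


def _component_drives(traj, params: LEVParams, dt: float):
    """NO and firing-rate drives on the 1-ms grid, with rest values."""
    n_series = capacitive_no_release(traj.derivatives, params.no,
                                     traj.constants)
    u_no, _ = no_lowpass_drive(n_series, params.no, dt)
    u_no_rest = params.no.filt_gain * params.no.baseline
    u_fr = firing_rate_drive(traj.v_pc_soma, params.fr)
    u_fr_rest = float(firing_rate_drive(np.zeros(1), params.fr)[0])
    return u_no, u_no_rest, u_fr, u_fr_rest


def mixture_component_scales(
    params: LEVParams,
    protocol: StimulusProtocol,
    consts: ElectricalConstants | None = None,
    dt: float = 1e-3,
    frequencies=None,
) -> tuple[float, float]:
    """SDs of the two coupling drives across the whole protocol.

    The mixture combines its components scaled to unit SD, so the mixing
    coefficients weigh the two mechanisms on a common amplitude scale;
    the SDs are computed over the 10 Hz block-meaned drives concatenated
    across frequencies (the resolution at which the slow vascular model
    consumes them), which keeps the convention identical between data
    generation and step-3 fitting.
    """
    consts = consts or ElectricalConstants()
    factor10 = int(round(1.0 / (10.0 * dt)))
    all_no, all_fr = [], []
    for f in (frequencies or protocol.frequencies):
        p1, p2, p3 = build_protocol_inputs(f, params.electrical, protocol, dt)
        traj = simulate_electrical(p1, p2, p3, params.electrical, consts, dt)
        u_no, _, u_fr, _ = _component_drives(traj, params, dt)
        all_no.append(_block_mean(u_no, factor10))
        all_fr.append(_block_mean(u_fr, factor10))
    sd_no = float(np.std(np.concatenate(all_no)))
    sd_fr = float(np.std(np.concatenate(all_fr)))
    return (sd_no if sd_no > 1e-12 else 1.0,
            sd_fr if sd_fr > 1e-12 else 1.0)


def _drive_1khz(model_id: str, traj, params: LEVParams, dt: float,
                mixture_scales: tuple[float, float] | None = None):
    """Balloon drive on the 1-ms grid plus its rest value.

    For the mixture, the NO and firing-rate components are scaled to unit
    SD (``mixture_scales``) before the convex combination, so the mixing
    coefficients compare the mechanisms on a common amplitude scale.
    """
    if model_id == "in":
        u_no, u_no_rest, _, _ = _component_drives(traj, params, dt)
        return u_no, u_no_rest
    if model_id == "out":
        _, _, u_fr, u_fr_rest = _component_drives(traj, params, dt)
        return u_fr, u_fr_rest
    if model_id == "mix":
        if mixture_scales is None:
            raise ValueError("mixture drive needs component scales")
        u_no, u_no_rest, u_fr, u_fr_rest = _component_drives(traj, params, dt)
        s_no, s_fr = mixture_scales
        return (mixture_drive(u_no / s_no, u_fr / s_fr, params.mixture),
                params.mixture.alpha_no * u_no_rest / s_no
                + params.mixture.alpha_fr * u_fr_rest / s_fr)
    raise ValueError(f"unknown coupling model {model_id!r}")


def integrate_lev(
    params: LEVParams,
    model_id: str,
    freq: float,
    protocol: StimulusProtocol,
    consts: ElectricalConstants | None = None,
    dt: float = 1e-3,
    lead: LeadField | None = None,
    *,
    interpolate_luminance: bool = False,
    mixture_scales: tuple[float, float] | None = None,
) -> LEVSimulation:
    """Integrate neural + coupling + hemodynamic states for one block.

    The hemodynamic states start at canonical rest; ``bold_rest`` records
    the trace under the rest drive alone.  For the mixture model the
    component scales are computed over the whole protocol unless supplied.
    """
    consts = consts or ElectricalConstants()
    if model_id == "mix" and mixture_scales is None:
        mixture_scales = mixture_component_scales(params, protocol, consts, dt)
    p1, p2, p3 = build_protocol_inputs(
        freq, params.electrical, protocol, dt,
        interpolate_luminance=interpolate_luminance)
    traj = simulate_electrical(p1, p2, p3, params.electrical, consts, dt)
    j = traj.extracellular_current
    if lead is not None:
        j = eeg_forward(j, lead)[0] if lead.n_channels == 1 else j
    stride = int(round(1.0 / (100.0 * dt)))
    eeg = j[::stride]

    u, u_rest = _drive_1khz(model_id, traj, params, dt, mixture_scales)
    hp = params.hemodynamic
    x0 = np.zeros(4)  # canonical rest: (s, log f, log v, log q) = 0
    n_out = len(u)
    obs = BoldObsParams.for_e0(hp.e0)
    steps_per_scan = int(round(protocol.tr / dt))
    n_scans = int(np.floor(((n_out - 1) * dt) / protocol.tr)) + 1
    idx = np.arange(n_scans) * steps_per_scan

    def bold_trace(drive_series):
        states = _kernels.integrate_balloon(
            np.ascontiguousarray(drive_series, dtype=float), dt, dt, n_out,
            hp.kappa, hp.gamma_fb, hp.tau_t, hp.alpha_g, hp.e0, x0)
        if not np.all(np.isfinite(states)):
            raise FloatingPointError(
                "balloon state diverged during integration")
        return bold_observation(states[idx, 2], states[idx, 3], obs)

    bold = bold_trace(u)
    bold_rest = bold_trace(np.full_like(u, u_rest))
    drive = _block_mean(u, int(round(1.0 / (10.0 * dt))))
    return LEVSimulation(freq=freq, eeg=eeg, drive=drive, bold=bold,
                         bold_rest=bold_rest)


def frequency_response_curve(
    params: LEVParams,
    model_id: str,
    freqs,
    protocol: StimulusProtocol,
    consts: ElectricalConstants | None = None,
    dt: float = 1e-3,
    normalize: bool = False,
) -> dict[float, float]:
    """Peak BOLD amplitude (above pre-stimulus baseline) per frequency.

    Frequencies outside the luminance table are allowed here: their factors
    are linearly interpolated between table entries (scan mode).  With
    ``normalize`` the curve is divided by its maximum.
    """
    freqs = list(freqs)
    if not freqs:
        raise ValueError("need at least one frequency")
    scales = (mixture_component_scales(params, protocol, consts, dt)
              if model_id == "mix" else None)
    curve: dict[float, float] = {}
    for f in freqs:
        sim = integrate_lev(params, model_id, f, protocol, consts=consts,
                            dt=dt, interpolate_luminance=True,
                            mixture_scales=scales)
        curve[f] = sim.peak_amplitude
    if normalize:
        peak = max(curve.values())
        if peak > 0:
            curve = {f: v / peak for f, v in curve.items()}
    return curve


@dataclass(frozen=True)
class SyntheticDataset:
    """A complete noisy EEG-fMRI dataset emulating the study design.

    ``eeg`` maps frequency to a 2-s, 200-sample standardized noisy EEG
    segment; ``bold`` maps frequency to a 10-scan standardized noisy epoch.
    Standardization is global per modality (one mean/SD across the
    concatenated all-frequency series) so relative amplitudes across
    frequencies are preserved.  Clean (pre-noise) signals are retained for
    diagnostics.
    """

    model_id: str
    true_params: LEVParams
    protocol: StimulusProtocol
    eeg: dict[float, np.ndarray]
    bold: dict[float, np.ndarray]
    eeg_clean: dict[float, np.ndarray]
    bold_clean: dict[float, np.ndarray]
    snr_eeg: float
    snr_bold: float
    seed: int

    def __post_init__(self) -> None:
        if set(self.eeg) != set(self.protocol.frequencies):
            raise ValueError("one EEG segment per protocol frequency required")
        if set(self.bold) != set(self.protocol.frequencies):
            raise ValueError("one BOLD epoch per protocol frequency required")


def generate_synthetic_dataset(
    model_id: str,
    true_params: LEVParams | None = None,
    protocol: StimulusProtocol | None = None,
    snr_eeg: float = 1.0 / DEFAULT_SIGMA_EEG,
    snr_bold: float = 1.0 / DEFAULT_SIGMA_BOLD,
    seed: int = 0,
    consts: ElectricalConstants | None = None,
    dt: float = 1e-3,
    segment_window: tuple[float, float] = SEGMENT_WINDOW,
) -> SyntheticDataset:
    """Generate one noisy synthetic dataset from a chosen coupling model.

    SNR is signal SD over noise SD on the standardized (unit-SD) signals,
    so noise SDs are 1/snr.  The same integer seed always produces a
    bit-identical dataset.
    """
    true_params = true_params or LEVParams.synthetic_truth()
    protocol = protocol or StimulusProtocol()
    if snr_eeg <= 0 or snr_bold <= 0:
        raise ValueError("SNRs must be > 0")
    i0 = int(round(segment_window[0] * 100))
    i1 = int(round(segment_window[1] * 100))
    scales = (mixture_component_scales(true_params, protocol, consts, dt)
              if model_id == "mix" else None)
    eeg_raw, bold_raw = {}, {}
    for f in protocol.frequencies:
        sim = integrate_lev(true_params, model_id, f, protocol,
                            consts=consts, dt=dt, mixture_scales=scales)
        eeg_raw[f] = sim.eeg[i0:i1]
        bold_raw[f] = sim.bold
    freqs = protocol.frequencies
    eeg_cat = standardize(np.concatenate([eeg_raw[f] for f in freqs]))
    bold_cat = standardize(np.concatenate([bold_raw[f] for f in freqs]))
    rng = np.random.default_rng(seed)
    eeg_noisy = add_observation_noise(eeg_cat, 1.0 / snr_eeg, rng)
    bold_noisy = add_observation_noise(bold_cat, 1.0 / snr_bold, rng)

    def split(cat, lens):
        out, pos = {}, 0
        for f, ln in zip(freqs, lens):
            out[f] = cat[pos:pos + ln]
            pos += ln
        return out

    eeg_lens = [len(eeg_raw[f]) for f in freqs]
    bold_lens = [len(bold_raw[f]) for f in freqs]
    return SyntheticDataset(
        model_id=model_id,
        true_params=true_params,
        protocol=protocol,
        eeg=split(eeg_noisy, eeg_lens),
        bold=split(bold_noisy, bold_lens),
        eeg_clean=split(eeg_cat, eeg_lens),
        bold_clean=split(bold_cat, bold_lens),
        snr_eeg=snr_eeg,
        snr_bold=snr_bold,
        seed=seed,
    )
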