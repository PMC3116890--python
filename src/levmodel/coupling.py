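"""Neurovascular coupling mechanisms: from neural activity to vascular drive.

Three candidate mechanisms turn cortical-unit activity into the drive
``u(t)`` of the extended Balloon model:

* **synaptic input** (``"in"``): the drive follows the total nitric-oxide
  (NO) release, modelled as an even, saturating function of the
  transmembrane *capacitive* currents ``C dV/dt`` in the three somas
  (both depolarizing and hyperpolarizing transients release NO), passed
  through a second-order low-pass filter with a baseline concentration;
* **spiking output** (``"out"``): the drive is the pyramidal population
  firing rate, a logistic function of the PC soma potential;
* **mixture** (``"mix"``): a convex combination of the two,
  ``u = alpha_no * u_no + (1 - alpha_no) * u_fr``.

The NO release function here is the rational even saturating form
``g(x) = g_max x^2 / (g_scale^2 + x^2)``; it satisfies the two structural
requirements (symmetry around zero, saturation) and is pluggable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from . import _kernels
from .neural_mass import ElectricalConstants, ElectricalTrajectory, logistic_rate

__all__ = [
    "MODEL_IDS",
    "NOCouplingParams",
    "FRCouplingParams",
    "MixtureParams",
    "no_release_function",
    "capacitive_no_release",
    "no_lowpass_drive",
    "firing_rate_drive",
    "mixture_drive",
    "no_drive_components",
]

#: The three coupling model identifiers.
MODEL_IDS = ("in", "out", "mix")


@dataclass(frozen=True)
class NOCouplingParams:
    """Synaptic-input (NO) coupling parameters.

    ``baseline`` and ``k_in`` are estimated from BOLD data (step 3);
    everything else is fixed.  Defaults are the prior means for the free
    parameters and reconstructed constants otherwise (see module note in
    :mod:`levmodel.neural_mass` about unavailable published constants).
    """

    baseline: float = 0.10  #: NO concentration baseline before stimulation
    k_in: float = 1.59e3  #: energetic factor, interneuron somas (estimated)
    k_pc: float = 3.18e3  #: energetic factor, PC soma (fixed)
    g_max: float = 1.0  #: saturation ceiling of the release function
    g_scale: float = 50.0  #: current scale of the release function
    filt_gain: float = 1.0  #: low-pass DC gain (epsilon_N)
    filt_cutoff: float = 2.0  #: low-pass cut-off frequency (rad/s, omega_N)
    filt_damping: float = 0.7  #: low-pass damping factor (d_N)

    def __post_init__(self) -> None:
        if self.baseline < 0 or self.k_in < 0 or self.k_pc < 0:
            raise ValueError("baseline, k_in, k_pc must be >= 0")
        if min(self.g_max, self.g_scale, self.filt_cutoff,
               self.filt_damping) <= 0:
            raise ValueError("g_max, g_scale, filter constants must be > 0")

    @classmethod
    def synthetic_truth(cls) -> "NOCouplingParams":
        return cls(baseline=0.30, k_in=1.50e3)


@dataclass(frozen=True)
class FRCouplingParams:
    """Spiking-output coupling: PC firing-rate logistic parameters.

    These are a separate copy of the PC voltage-ampere function, estimated
    from BOLD (step 3) rather than EEG, with their own priors.
    """

    fr_vbar: float = 0.78  #: half-activation potential (mV)
    fr_r: float = 5.62  #: growth rate (1/mV)

    def __post_init__(self) -> None:
        if self.fr_r <= 0:
            raise ValueError("fr_r must be > 0")

    @classmethod
    def synthetic_truth(cls) -> "FRCouplingParams":
        return cls(fr_vbar=0.90, fr_r=4.00)


@dataclass(frozen=True)
class MixtureParams:
    """Convex mixture of the NO and firing-rate drives.

    A single free coefficient ``alpha_no`` in [0, 1]; the firing-rate
    coefficient is constrained to ``1 - alpha_no`` (the two reported
    coefficients always sum to one).
    """

    alpha_no: float = 0.50

    def __post_init__(self) -> None:
        if not (0.0 <= self.alpha_no <= 1.0):
            raise ValueError("alpha_no must lie in [0, 1]")

    @property
    def alpha_fr(self) -> float:
        return 1.0 - self.alpha_no

    @classmethod
    def synthetic_truth(cls) -> "MixtureParams":
        return cls(alpha_no=0.40)


def no_release_function(x, params: NOCouplingParams):
    """Even saturating release g(x) = g_max x^2 / (g_scale^2 + x^2)."""
    x = np.asarray(x, dtype=float)
    return params.g_max * x * x / (params.g_scale**2 + x * x)


def capacitive_no_release(
    dv_dt: np.ndarray,
    params: NOCouplingParams,
    consts: ElectricalConstants,
) -> np.ndarray:
    """Total NO release from soma capacitive currents.

    ``dv_dt`` has columns (v_in_t, v_in_f, v_pc_soma[, ...]) derivatives;
    only the three soma channels contribute:
    N = k_in g(C_in dv1) + k_in g(C_in dv2) + k_pc g(C_pc dvs).
    """
    d = np.atleast_2d(np.asarray(dv_dt, dtype=float))
    if d.shape[1] < 3:
        raise ValueError("need derivatives for both IN somas and the PC soma")
    g = lambda x: no_release_function(x, params)
    return (params.k_in * g(consts.c_in * d[:, 0])
            + params.k_in * g(consts.c_in * d[:, 1])
            + params.k_pc * g(consts.c_pc * d[:, 2]))


def no_lowpass_drive(
    n_series: np.ndarray,
    params: NOCouplingParams,
    dt: float,
    *,
    include_baseline: bool = True,
    initial: tuple[float, float] | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Balloon drive from NO release through the second-order low-pass.

    Solves  u'' + 2 d w u' + w^2 u = gain w^2 (baseline + N(t))  and returns
    ``(u, u')``.  By default the filter starts at its rest equilibrium
    ``u = gain * baseline`` so a constant baseline produces no transient.
    """
    n_series = np.asarray(n_series, dtype=float)
    if dt <= 0:
        raise ValueError("dt must be > 0")
    if params.filt_cutoff * dt > 0.5:
        warnings.warn(
            "sampling too coarse for the low-pass cut-off; expect "
            "integration error", RuntimeWarning, stacklevel=2)
    x = n_series + (params.baseline if include_baseline else 0.0)
    if initial is None:
        u0 = params.filt_gain * params.baseline if include_baseline else 0.0
        du0 = 0.0
    else:
        u0, du0 = initial
    u, du = _kernels.lowpass_second_order(
        np.ascontiguousarray(x), dt, params.filt_gain,
        params.filt_cutoff, params.filt_damping, u0, du0)
    return u, du


def firing_rate_drive(v_pc_soma: np.ndarray, params: FRCouplingParams) -> np.ndarray:
    """Pyramidal firing-rate drive: logistic of the soma potential."""
    return logistic_rate(v_pc_soma, params.fr_vbar, params.fr_r)


def mixture_drive(u_no: np.ndarray, u_fr: np.ndarray, params: MixtureParams) -> np.ndarray:
    """Convex combination of the NO and firing-rate drives."""
    u_no = np.asarray(u_no, dtype=float)
    u_fr = np.asarray(u_fr, dtype=float)
    if u_no.shape != u_fr.shape:
        raise ValueError("component drives must have equal length")
    return params.alpha_no * u_no + params.alpha_fr * u_fr


def no_drive_components(
    traj: ElectricalTrajectory,
    params: NOCouplingParams,
    dt: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Unit-coefficient filtered NO release components.

    Because the low-pass filter is linear, the NO drive decomposes as

        u(t) = gain * baseline + k_in * A_in(t) + k_pc * A_pc(t)

    where ``A_in`` / ``A_pc`` are the filter responses to the interneuron
    and PC release terms with unit energetic factors.  Step 2 of the
    multi-step inversion emits these components once so step 3 can vary
    ``baseline`` and ``k_in`` without re-integrating the neural model.
    """
    consts = traj.constants
    g = lambda x: no_release_function(x, params)
    rel_in = (g(consts.c_in * traj.derivatives[:, 0])
              + g(consts.c_in * traj.derivatives[:, 1]))
    rel_pc = g(consts.c_pc * traj.derivatives[:, 2])
    a_in, _ = no_lowpass_drive(rel_in, params, dt, include_baseline=False,
                               initial=(0.0, 0.0))
    a_pc, _ = no_lowpass_drive(rel_pc, params, dt, include_baseline=False,
                               initial=(0.0, 0.0))
    return a_in, a_pc
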