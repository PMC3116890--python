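"""Cortical-unit neural mass model.

One cortical unit holds two single-compartment layer IV GABAergic
interneurons (a *transmission* IN driven by thalamo-cortical input and a
*feedback* IN driven by pyramidal output) and a layer V pyramidal cell (PC)
with three compartments (soma, basal dendrites, apical tuft).  Every
compartment obeys leaky voltage-source dynamics

    dV/dt = (-V + R * I) / tau_m

where ``I`` collects external input currents, synaptic currents and (for PC
compartments) axial currents between compartments.  Membrane potentials are
expressed as deviations from rest, so the all-zero state is the resting
fixed point; threshold (logistic) nonlinearities are shifted to output zero
at rest.

The EEG-visible quantity is the axial current along the apical dendrite,
``(v_apical - v_soma) / r_axial_apical``: apical dendrites of layer V cells
are parallel and normal to the cortical surface, so their extracellular
currents sum coherently into the scalp signal.

All fixed constants live in :class:`ElectricalConstants`.  The published
description of this model relegates the compartment equations and constant
values to supplementary material that is not available, so the defaults
below are a reconstruction: they implement the stated minimal structure
(connectivity, leaky dynamics, shifted thresholds) with scales chosen once
so that the unit phase-locks to pulse-train input and drives the vascular
model in its sensitive regime.  Every value is configurable.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from . import _kernels
from .stimulus import PulseTrain

__all__ = [
    "ElectricalParams",
    "ElectricalConstants",
    "ElectricalState",
    "ElectricalTrajectory",
    "logistic_rate",
    "shifted_threshold",
    "synaptic_currents",
    "nmm_derivatives",
    "extracellular_current",
    "simulate_electrical",
]


@dataclass(frozen=True)
class ElectricalParams:
    """Free electrical parameters (estimated from EEG in step 1).

    Defaults are the prior means; :meth:`synthetic_truth` returns the values
    used to generate synthetic data in recovery experiments.
    """

    gain1: float = 1.00  #: gain on the transmission-IN input train
    gain2: float = 1.00  #: gain on the PC basal input train
    gain3: float = 1.00  #: gain on the PC apical (cortico-cortical) train
    gaba_factor: float = 0.30  #: GABAergic synaptic scaling (Omega)
    pc_vbar: float = 0.60  #: PC voltage-ampere half-activation potential (mV)
    pc_r: float = 6.00  #: PC voltage-ampere growth rate (1/mV)

    def __post_init__(self) -> None:
        if min(self.gain1, self.gain2, self.gain3) < 0:
            raise ValueError("gains must be >= 0")
        if self.gaba_factor < 0:
            raise ValueError("gaba_factor must be >= 0")
        if self.pc_r <= 0:
            raise ValueError("pc_r must be > 0")

    @classmethod
    def synthetic_truth(cls) -> "ElectricalParams":
        return cls(gain1=0.80, gain2=1.00, gain3=0.50,
                   gaba_factor=0.50, pc_vbar=0.90, pc_r=4.00)


@dataclass(frozen=True)
class ElectricalConstants:
    """Fixed constants of the cortical unit (reconstructed defaults).

    Units: seconds, mV, and arbitrary-but-consistent current/resistance
    units with R = 1 so a unit steady current depolarizes a compartment by
    1 mV.  ``c_in``/``c_pc`` are the effective soma capacitances used by the
    capacitive-current readout of the NO coupling (C = tau_m / R).
    """

    tau_m: float = 0.020  #: membrane time constant (s), shared
    r_in: float = 1.0  #: membrane resistance, interneurons
    r_soma: float = 1.0  #: membrane resistance, PC soma
    r_basal: float = 1.0  #: membrane resistance, PC basal dendrites
    r_apical: float = 1.0  #: membrane resistance, PC apical tuft
    r_axial_basal: float = 0.5  #: axial resistance soma<->basal
    r_axial_apical: float = 0.5  #: axial resistance soma<->apical
    c_in: float = 0.020  #: effective soma capacitance, interneurons
    c_pc: float = 0.020  #: effective soma capacitance, PC
    in_vbar: float = 1.5  #: interneuron threshold half-activation (mV)
    in_r: float = 4.0  #: interneuron threshold growth rate (1/mV)
    w_pc_fb: float = 1.0  #: synaptic gain, PC -> feedback IN

    def __post_init__(self) -> None:
        vals = (self.tau_m, self.r_in, self.r_soma, self.r_basal,
                self.r_apical, self.r_axial_basal, self.r_axial_apical,
                self.c_in, self.c_pc, self.in_r, self.w_pc_fb)
        if any(v <= 0 for v in vals):
            raise ValueError("all electrical constants must be > 0")

    def as_array(self) -> np.ndarray:
        return np.array([
            self.tau_m, self.r_in, self.r_soma, self.r_basal, self.r_apical,
            self.r_axial_basal, self.r_axial_apical, self.in_vbar, self.in_r,
            self.w_pc_fb,
        ])


@dataclass(frozen=True)
class ElectricalState:
    """Membrane potentials (mV, deviations from rest)."""

    v_in_t: float = 0.0  #: transmission interneuron
    v_in_f: float = 0.0  #: feedback interneuron
    v_pc_soma: float = 0.0
    v_pc_basal: float = 0.0
    v_pc_apical: float = 0.0

    def as_array(self) -> np.ndarray:
        return np.array([self.v_in_t, self.v_in_f, self.v_pc_soma,
                         self.v_pc_basal, self.v_pc_apical])


@dataclass(frozen=True)
class ElectricalTrajectory:
    """Simulated electrical states on a fixed time grid.

    ``states`` and ``derivatives`` are (n, 5) arrays with columns
    (v_in_t, v_in_f, v_pc_soma, v_pc_basal, v_pc_apical).
    """

    times: np.ndarray
    states: np.ndarray
    derivatives: np.ndarray
    constants: ElectricalConstants

    @property
    def v_pc_soma(self) -> np.ndarray:
        return self.states[:, 2]

    @property
    def extracellular_current(self) -> np.ndarray:
        return ((self.states[:, 4] - self.states[:, 2])
                / self.constants.r_axial_apical)


def logistic_rate(v, vbar: float, r: float):
    """Normalized logistic activation 1 / (1 + exp(-r (v - vbar)))."""
    if r <= 0:
        raise ValueError("growth rate r must be > 0")
    return 1.0 / (1.0 + np.exp(-r * (np.asarray(v, dtype=float) - vbar)))


def shifted_threshold(v, vbar: float, r: float):
    """Logistic threshold shifted to output zero at rest (v = 0)."""
    return logistic_rate(v, vbar, r) - logistic_rate(0.0, vbar, r)


def synaptic_currents(
    state: ElectricalState,
    params: ElectricalParams,
    consts: ElectricalConstants,
) -> dict[str, float]:
    """Intra-unit synaptic currents at one state.

    Returns the total inhibitory current onto the PC soma (both GABAergic
    interneurons, scaled by the shared factor Omega) and the excitatory
    current from the PC onto the feedback interneuron.  Signs follow the
    convention that the inhibitory entry is subtracted from the PC soma
    current balance.
    """
    inh = params.gaba_factor * (
        shifted_threshold(state.v_in_t, consts.in_vbar, consts.in_r)
        + shifted_threshold(state.v_in_f, consts.in_vbar, consts.in_r)
    )
    exc = consts.w_pc_fb * shifted_threshold(
        state.v_pc_soma, params.pc_vbar, params.pc_r
    )
    return {"pc_inhibitory": float(inh), "fb_excitatory": float(exc)}


def nmm_derivatives(
    state: ElectricalState,
    inputs: tuple[float, float, float],
    params: ElectricalParams,
    consts: ElectricalConstants,
) -> np.ndarray:
    """Right-hand side of the five membrane-potential equations.

    ``inputs`` are the instantaneous values of (psi1, psi2, psi3); the
    per-population gains are already applied by the stimulus builder, so
    they are *not* re-applied here.
    """
    x = state.as_array()
    if not np.all(np.isfinite(x)):
        raise FloatingPointError("non-finite electrical state")
    out = np.empty(5)
    _kernels.electrical_rhs(
        x, float(inputs[0]), float(inputs[1]), float(inputs[2]),
        params.gaba_factor, params.pc_vbar, params.pc_r,
        consts.as_array(), out,
    )
    return out


def extracellular_current(state: ElectricalState, consts: ElectricalConstants) -> float:
    """Axial current along the apical dendrite (EEG-visible quantity)."""
    return (state.v_pc_apical - state.v_pc_soma) / consts.r_axial_apical


def simulate_electrical(
    psi1: PulseTrain | np.ndarray,
    psi2: PulseTrain | np.ndarray,
    psi3: PulseTrain | np.ndarray,
    params: ElectricalParams,
    consts: ElectricalConstants,
    dt: float,
    x0: ElectricalState | None = None,
) -> ElectricalTrajectory:
    """Integrate the unit with RK4 on the fixed input grid.

    Inputs are sampled at ``dt`` (linearly interpolated at RK4 half steps);
    the returned trajectory lives on the same grid.
    """
    def arr(p):
        return p.values if isinstance(p, PulseTrain) else np.asarray(p, float)

    a1, a2, a3 = arr(psi1), arr(psi2), arr(psi3)
    if not (a1.shape == a2.shape == a3.shape):
        raise ValueError("input trains must share one grid")
    x0v = (x0.as_array() if x0 is not None else np.zeros(5))
    states, derivs = _kernels.integrate_electrical(
        a1, a2, a3, x0v,
        params.gaba_factor, params.pc_vbar, params.pc_r,
        consts.as_array(), dt,
    )
    if not np.all(np.isfinite(states)):
        raise FloatingPointError("electrical integration diverged")
    times = np.arange(states.shape[0]) * dt
    return ElectricalTrajectory(times=times, states=states,
                                derivatives=derivs, constants=consts)


def with_params(params: ElectricalParams, **overrides) -> ElectricalParams:
    """Convenience copy-with-overrides for parameter sweeps."""
    return replace(params, **overrides)
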