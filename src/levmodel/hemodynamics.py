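"""Extended Balloon model: from vascular drive u(t) to BOLD signal.

Four hemodynamic states follow the canonical extended Balloon equations:
a vasodilatory signal ``s`` with decay ``kappa`` and autoregulatory flow
feedback ``gamma``; normalized inflow ``f``; blood volume ``v`` with
Grubb's vessel-stiffness exponent ``alpha``; and deoxyhemoglobin content
``q`` with resting oxygen extraction fraction ``E0``:

    ds/dt = u - kappa s - gamma (f - 1)
    df/dt = s
    tau dv/dt = f - v^(1/alpha)
    tau dq/dt = f E(f)/E0 - v^(1/alpha) q / v,   E(f) = 1 - (1 - E0)^(1/f)

Rest is (s, f, v, q) = (0, 1, 1, 1).  Positivity of f, v, q is guaranteed
by integrating their logarithms internally (an implementation device, not a
model change).  The BOLD observation is the standard static nonlinearity
with scanner factors k1 = 7 E0, k2 = 2, k3 = 2 E0 - 0.2 and resting blood
volume fraction V0 = 0.02 (1.5 T, TE 40 ms defaults; all configurable).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _kernels

__all__ = [
    "HemodynamicParams",
    "HemodynamicState",
    "BoldObsParams",
    "balloon_derivatives",
    "bold_observation",
    "simulate_balloon",
]


@dataclass(frozen=True)
class HemodynamicParams:
    """Free vascular parameters (estimated from BOLD in step 3).

    Defaults are the prior means; :meth:`synthetic_truth` gives the
    generating values of the recovery experiments.
    """

    kappa: float = 0.65  #: vasodilatory signal decay rate (1/s)
    gamma_fb: float = 0.41  #: autoregulatory feedback rate (1/s)
    tau_t: float = 0.98  #: mean transit time (s)
    alpha_g: float = 0.32  #: Grubb vessel-stiffness exponent
    e0: float = 0.34  #: resting oxygen extraction fraction

    def __post_init__(self) -> None:
        if min(self.kappa, self.gamma_fb, self.tau_t) <= 0:
            raise ValueError("kappa, gamma_fb, tau_t must be > 0")
        if not (0.0 < self.alpha_g < 1.0):
            raise ValueError("alpha_g must lie in (0, 1)")
        if not (0.0 < self.e0 < 1.0):
            raise ValueError("e0 must lie in (0, 1)")

    @classmethod
    def synthetic_truth(cls) -> "HemodynamicParams":
        return cls(kappa=0.50, gamma_fb=0.28, tau_t=0.78,
                   alpha_g=0.25, e0=0.30)


@dataclass(frozen=True)
class HemodynamicState:
    """Hemodynamic state (rest = (0, 1, 1, 1))."""

    s: float = 0.0
    f: float = 1.0
    v: float = 1.0
    q: float = 1.0

    def __post_init__(self) -> None:
        if min(self.f, self.v, self.q) <= 0:
            raise ValueError("f, v, q must be > 0")

    def as_array(self) -> np.ndarray:
        return np.array([self.s, self.f, self.v, self.q])


@dataclass(frozen=True)
class BoldObsParams:
    """Static BOLD observation factors (scanner dependent).

    By default the field-strength factors are tied to the resting oxygen
    extraction fraction: k1 = 7 E0, k2 = 2, k3 = 2 E0 - 0.2.
    """

    v0: float = 0.02
    k1: float = 7 * 0.34
    k2: float = 2.0
    k3: float = 2 * 0.34 - 0.2

    def __post_init__(self) -> None:
        if not (0.0 < self.v0 < 1.0):
            raise ValueError("v0 must lie in (0, 1)")

    @classmethod
    def for_e0(cls, e0: float, v0: float = 0.02) -> "BoldObsParams":
        return cls(v0=v0, k1=7 * e0, k2=2.0, k3=2 * e0 - 0.2)


def balloon_derivatives(
    state: HemodynamicState,
    u: float,
    params: HemodynamicParams,
) -> np.ndarray:
    """Time derivatives (ds, df, dv, dq) at one state under drive ``u``."""
    s, f, v, q = state.s, state.f, state.v, state.q
    fout = v ** (1.0 / params.alpha_g)
    e_f = 1.0 - (1.0 - params.e0) ** (1.0 / f)
    return np.array([
        u - params.kappa * s - params.gamma_fb * (f - 1.0),
        s,
        (f - fout) / params.tau_t,
        (f * e_f / params.e0 - fout * q / v) / params.tau_t,
    ])


def bold_observation(v, q, params: BoldObsParams):
    """Fractional BOLD signal change from volume and deoxyhemoglobin."""
    v = np.asarray(v, dtype=float)
    q = np.asarray(q, dtype=float)
    if np.any(v <= 0) or np.any(q <= 0):
        raise ValueError("v and q must be > 0")
    return params.v0 * (params.k1 * (1.0 - q)
                        + params.k2 * (1.0 - q / v)
                        + params.k3 * (1.0 - v))


def simulate_balloon(
    u: np.ndarray,
    dt_u: float,
    params: HemodynamicParams,
    dt: float | None = None,
    duration: float | None = None,
    x0: HemodynamicState | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Integrate the Balloon model under a sampled drive.

    ``u`` is sampled at ``dt_u`` and linearly interpolated; the integrator
    runs at ``dt`` (default: the drive grid).  Returns ``(times, states)``
    with ``states`` of shape (n, 4) holding (s, f, v, q).
    """
    u = np.ascontiguousarray(u, dtype=float)
    if dt is None:
        dt = dt_u
    if duration is None:
        duration = (len(u) - 1) * dt_u
    n_out = int(round(duration / dt)) + 1
    if x0 is None:
        x0 = HemodynamicState()
    x0v = np.array([x0.s, np.log(x0.f), np.log(x0.v), np.log(x0.q)])
    states = _kernels.integrate_balloon(
        u, dt_u, dt, n_out, params.kappa, params.gamma_fb,
        params.tau_t, params.alpha_g, params.e0, x0v)
    if not np.all(np.isfinite(states)):
        raise FloatingPointError("balloon integration diverged")
    times = np.arange(n_out) * dt
    return times, states
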