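"""Parameter specifications: priors, transforms, and generating truths.

Free parameters are estimated in an unconstrained space: strictly positive
parameters through a log transform, theta = mean * exp(l - s^2/2) with
prior l ~ N(0, s^2), so the *prior expectation* of theta equals the stated
prior mean exactly; and (0, 1)-bounded parameters (Grubb exponent, resting
O2 extraction, mixing coefficient) through a logit transform.  The prior SD
in the unconstrained space defaults to sqrt(ln 2), which gives a log-normal
coefficient of variation of exactly 1 ("prior variances of the same order
of magnitude as the prior means").  Reported point estimates are exact
posterior means of the natural parameters (integrated through the
transform), so a parameter untouched by the data reports its prior mean.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.special import expit, logit

__all__ = ["ParamSpec", "LOG_PRIOR_SD", "electrical_specs",
           "hemodynamic_specs", "coupling_specs", "step3_specs",
           "to_natural", "prior_moments"]

#: Unconstrained-space prior SD giving CV = 1 for log-transformed parameters.
LOG_PRIOR_SD = math.sqrt(math.log(2.0))


@dataclass(frozen=True)
class ParamSpec:
    """One estimated parameter: prior mean, transform, unconstrained SD."""

    name: str
    prior_mean: float
    transform: str = "log"  # 'log' | 'logit' | 'linear'
    prior_sd: float = LOG_PRIOR_SD

    def __post_init__(self) -> None:
        if self.transform not in ("log", "logit", "linear"):
            raise ValueError(f"unknown transform {self.transform!r}")
        if self.prior_sd <= 0:
            raise ValueError("prior_sd must be > 0")
        if self.transform == "log" and self.prior_mean <= 0:
            raise ValueError("log transform needs a positive prior mean")
        if self.transform == "logit" and not (0 < self.prior_mean < 1):
            raise ValueError("logit transform needs a prior mean in (0, 1)")

    @property
    def lam0(self) -> float:
        """Prior mean in the unconstrained space."""
        if self.transform == "logit":
            return float(logit(self.prior_mean))
        return 0.0

    @property
    def lam_natural(self) -> float:
        """Unconstrained value whose natural image is the stated prior mean."""
        if self.transform == "log":
            return 0.5 * self.prior_sd**2
        return self.lam0

    def natural(self, lam: float) -> float:
        if self.transform == "log":
            return self.prior_mean * math.exp(lam - 0.5 * self.prior_sd**2)
        if self.transform == "logit":
            # clipped away from {0, 1}: downstream models need open-interval
            # values and trial steps can be arbitrarily large
            return float(np.clip(expit(lam), 1e-9, 1 - 1e-9))
        return self.prior_mean + lam

    def posterior_mean(self, lam: float, lam_sd: float) -> float:
        """Exact posterior mean of the natural parameter for a Gaussian
        posterior N(lam, lam_sd^2) in the unconstrained space."""
        if self.transform == "log":
            return self.natural(lam) * math.exp(0.5 * lam_sd**2)
        if self.transform == "logit":
            # Gauss-Hermite quadrature of E[expit(lam)]
            nodes, weights = np.polynomial.hermite_e.hermegauss(31)
            return float(np.sum(weights * expit(lam + lam_sd * nodes))
                         / np.sum(weights))
        return self.natural(lam)

    def natural_sd(self, lam: float, lam_sd: float) -> float:
        """Delta-method SD of the natural parameter."""
        if self.transform == "log":
            return self.natural(lam) * lam_sd
        if self.transform == "logit":
            p = self.natural(lam)
            return p * (1 - p) * lam_sd
        return lam_sd


def to_natural(specs: list[ParamSpec], lam: np.ndarray) -> dict[str, float]:
    return {s.name: s.natural(float(v)) for s, v in zip(specs, lam)}


def prior_moments(specs: list[ParamSpec]) -> tuple[np.ndarray, np.ndarray]:
    """Unconstrained prior mean vector and (diagonal) covariance."""
    m0 = np.array([s.lam0 for s in specs])
    cov = np.diag([s.prior_sd**2 for s in specs])
    return m0, cov


def electrical_specs() -> list[ParamSpec]:
    """Step-1 electrical parameters (six, estimated from EEG)."""
    return [
        ParamSpec("gain1", 1.00),
        ParamSpec("gain2", 1.00),
        ParamSpec("gain3", 1.00),
        ParamSpec("gaba_factor", 0.30),
        ParamSpec("pc_vbar", 0.60),
        ParamSpec("pc_r", 6.00),
    ]


def hemodynamic_specs() -> list[ParamSpec]:
    """Vascular parameters shared by every step-3 model."""
    return [
        ParamSpec("kappa", 0.65),
        ParamSpec("gamma_fb", 0.41),
        ParamSpec("tau_t", 0.98),
        ParamSpec("alpha_g", 0.32, transform="logit"),
        ParamSpec("e0", 0.34, transform="logit"),
    ]


def coupling_specs(model_id: str) -> list[ParamSpec]:
    """Coupling parameters free in step 3 for one model."""
    no = [ParamSpec("baseline", 0.10), ParamSpec("k_in", 1.59e3)]
    fr = [ParamSpec("fr_vbar", 0.78), ParamSpec("fr_r", 5.62)]
    if model_id == "in":
        return no
    if model_id == "out":
        return fr
    if model_id == "mix":
        return no + fr + [ParamSpec("alpha_no", 0.50, transform="logit",
                                    prior_sd=1.0)]
    raise ValueError(f"unknown coupling model {model_id!r}")


def step3_specs(model_id: str) -> list[ParamSpec]:
    """Full step-3 parameter set: 5 vascular + 2 (in/out) or 5 (mix)."""
    return hemodynamic_specs() + coupling_specs(model_id)
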