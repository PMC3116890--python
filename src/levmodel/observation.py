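"""Observation model: lead field, source reconstruction, standardization, noise.

The EEG channel data are the cortical source current multiplied by a lead
field vector (head geometry and conductivity); the source series is
recovered from multichannel data with the Moore-Penrose pseudo-inverse of
that vector.  All fitted series are standardized (mean corrected, divided by
the sample standard deviation), and observation noise is additive i.i.d.
Gaussian.  The default noise convention is an SNR reading on standardized
(unit-SD) signals: SNR 1 for EEG (sigma = 1.0) and SNR 2 for BOLD
(sigma = 0.5); the alternative sigma reading is a matter of passing
different values.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "LeadField",
    "TimeSeries",
    "eeg_forward",
    "source_reconstruct",
    "standardize",
    "add_observation_noise",
    "DEFAULT_SIGMA_EEG",
    "DEFAULT_SIGMA_BOLD",
]

#: Noise SD on standardized EEG (SNR 1 on a unit-SD signal).
DEFAULT_SIGMA_EEG = 1.0
#: Noise SD on standardized BOLD (SNR 2 on a unit-SD signal).
DEFAULT_SIGMA_BOLD = 0.5


@dataclass(frozen=True)
class LeadField:
    """Per-channel gains mapping one cortical source to scalp channels."""

    weights: np.ndarray

    def __post_init__(self) -> None:
        w = np.atleast_1d(np.asarray(self.weights, dtype=float))
        if w.ndim != 1 or w.size == 0:
            raise ValueError("lead field must be a non-empty vector")
        if not np.any(w != 0):
            raise ValueError("lead field needs at least one non-zero weight")
        object.__setattr__(self, "weights", w)

    @property
    def n_channels(self) -> int:
        return self.weights.size


@dataclass(frozen=True)
class TimeSeries:
    """A uniformly sampled series tagged with its modality."""

    values: np.ndarray
    rate: float
    label: str = "eeg"

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if self.rate <= 0:
            raise ValueError("rate must be > 0")
        if not np.all(np.isfinite(v)):
            raise ValueError("time series values must be finite")
        object.__setattr__(self, "values", v)


def eeg_forward(j: np.ndarray, lead: LeadField) -> np.ndarray:
    """Project a source current series to channels: Y[c, t] = w[c] j(t)."""
    j = np.asarray(j, dtype=float)
    return np.outer(lead.weights, j)


def source_reconstruct(y: np.ndarray, lead: LeadField) -> np.ndarray:
    """Least-squares single-source estimate via the lead-field pseudo-inverse."""
    y = np.atleast_2d(np.asarray(y, dtype=float))
    if y.shape[0] != lead.n_channels:
        raise ValueError(
            f"data has {y.shape[0]} channels, lead field {lead.n_channels}")
    pinv = np.linalg.pinv(lead.weights[:, None])  # (1, n_channels)
    return (pinv @ y).ravel()


def standardize(values: np.ndarray) -> np.ndarray:
    """Mean-correct and scale to unit sample SD (n-1 convention)."""
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("need at least 2 samples to standardize")
    sd = np.std(v, ddof=1)
    if sd == 0 or not np.isfinite(sd):
        raise ValueError("cannot standardize a constant series")
    return (v - np.mean(v)) / sd


def add_observation_noise(
    values: np.ndarray,
    sd: float,
    seed: int | np.random.Generator,
) -> np.ndarray:
    """Add zero-mean i.i.d. Gaussian noise, deterministic given the seed."""
    if sd < 0:
        raise ValueError("noise sd must be >= 0")
    v = np.asarray(values, dtype=float)
    if sd == 0:
        return v.copy()
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    return v + rng.normal(0.0, sd, size=v.shape)
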