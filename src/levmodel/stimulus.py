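"""Stimulus protocol and model input pulse trains.

The cortical unit is driven by trains of brief excitatory current pulses,
one pulse per checkerboard reversal.  Each pulse is a Gaussian of fixed
width (the screen refresh interval of a 60 Hz monitor); the train amplitude
is scaled per frequency by the measured luminance of the flickering display,
which fell with increasing reversal frequency.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "StimulusProtocol",
    "PulseTrain",
    "DEFAULT_LUMINANCE",
    "luminance_factor",
    "build_pulse_train",
    "build_protocol_inputs",
]

#: Measured luminance scaling per reversal frequency (low frequencies were
#: brighter); keys in Hz.
DEFAULT_LUMINANCE: dict[float, float] = {
    4.0: 1.00,
    7.5: 0.96,
    10.0: 0.93,
    12.0: 0.91,
    15.0: 0.88,
    20.0: 0.82,
    30.0: 0.74,
}

#: Gaussian pulses are truncated at this many widths from the centre;
#: the neglected mass is < 1e-4 of the pulse.
_TRUNCATE_WIDTHS = 4.0


@dataclass(frozen=True)
class StimulusProtocol:
    """Experimental design: block structure, sampling, and input shape.

    Parameters
    ----------
    frequencies:
        Checkerboard reversal frequencies in Hz, strictly positive, sorted.
    stim_duration, rest_duration:
        Seconds of stimulation and rest per block.  Defaults are 5 fMRI
        scans each (5 x 3.06 s = 15.3 s).
    tr:
        BOLD sampling interval in seconds.
    pulse_width:
        Width (Gaussian sigma) of one input pulse, in seconds.  Default is
        the refresh interval of a 60 Hz monitor.
    delay:
        Lag of the basal-dendrite input relative to the transmission
        interneuron input, in seconds.
    amplitude:
        Base input current amplitude multiplying every train (arbitrary
        current units); per-population gains multiply on top of it.
    luminance_factors:
        Per-frequency multiplicative scaling in (0, 1].
    """

    frequencies: tuple[float, ...] = (4.0, 7.5, 10.0, 12.0, 15.0, 20.0, 30.0)
    stim_duration: float = 15.3
    rest_duration: float = 15.3
    tr: float = 3.06
    pulse_width: float = 1.0 / 60.0
    delay: float = 0.1
    amplitude: float = 3.0
    luminance_factors: dict[float, float] = field(
        default_factory=lambda: dict(DEFAULT_LUMINANCE)
    )

    def __post_init__(self) -> None:
        freqs = tuple(float(f) for f in self.frequencies)
        if len(freqs) == 0:
            raise ValueError("protocol needs at least one frequency")
        if any(f <= 0 for f in freqs):
            raise ValueError("frequencies must be strictly positive")
        if list(freqs) != sorted(freqs):
            raise ValueError("frequencies must be sorted ascending")
        if self.stim_duration <= 0:
            raise ValueError("stim_duration must be > 0")
        if self.rest_duration < 0:
            raise ValueError("rest_duration must be >= 0")
        if self.pulse_width <= 0:
            raise ValueError("pulse_width must be > 0")
        if self.delay < 0:
            raise ValueError("delay must be >= 0")
        missing = [f for f in freqs if f not in self.luminance_factors]
        if missing:
            raise ValueError(f"no luminance factor for frequencies {missing}")
        for f, lum in self.luminance_factors.items():
            if not (0.0 < lum <= 1.0):
                raise ValueError(f"luminance factor for {f} Hz not in (0, 1]")
        object.__setattr__(self, "frequencies", freqs)

    @property
    def block_duration(self) -> float:
        return self.stim_duration + self.rest_duration


@dataclass(frozen=True)
class PulseTrain:
    """A sampled input current train for one population input.

    ``target`` names which input it drives: ``"psi1"`` (transmission
    interneuron), ``"psi2"`` (PC basal dendrites) or ``"psi3"`` (PC apical
    tuft, cortico-cortical).
    """

    times: np.ndarray
    values: np.ndarray
    target: str

    def __post_init__(self) -> None:
        if self.times.shape != self.values.shape:
            raise ValueError("times and values must have equal shape")
        if np.any(self.values < 0):
            raise ValueError("pulse train values must be non-negative")


def luminance_factor(
    freq: float,
    protocol: StimulusProtocol,
    *,
    interpolate: bool = False,
) -> float:
    """Luminance scaling factor for one reversal frequency.

    Unknown frequencies raise ``KeyError`` unless ``interpolate`` is set,
    in which case the factor is linearly interpolated between table entries
    (used only by frequency-response scans on a dense grid).
    """
    table = protocol.luminance_factors
    key = float(freq)
    if key in table:
        return float(table[key])
    if not interpolate:
        raise KeyError(
            f"no luminance factor for {freq} Hz; known: {sorted(table)}"
        )
    known = np.array(sorted(table))
    if not (known[0] <= key <= known[-1]):
        raise KeyError(
            f"{freq} Hz outside luminance table range [{known[0]}, {known[-1]}]"
        )
    vals = np.array([table[f] for f in known])
    return float(np.interp(key, known, vals))


def build_pulse_train(
    freq: float,
    duration: float,
    dt: float,
    amplitude: float,
    pulse_width: float,
    delay: float = 0.0,
    stim_duration: float | None = None,
) -> PulseTrain:
    """Sum of Gaussian pulses at the reversal rate, zero during rest.

    Pulse centres sit at ``k / freq + delay`` for
    ``k = 0 .. floor(freq * stim_duration) - 1``.  Samples outside the
    stimulation block are exactly zero (pulses are truncated at the block
    boundary), and each Gaussian is truncated at +-4 widths.
    """
    if dt <= 0:
        raise ValueError("dt must be > 0")
    if freq <= 0:
        raise ValueError("freq must be > 0")
    if pulse_width <= 0:
        raise ValueError("pulse_width must be > 0")
    if delay < 0:
        raise ValueError("delay must be >= 0")
    n = int(round(duration / dt))
    if abs(n * dt - duration) > 1e-9:
        raise ValueError("dt must divide duration")
    if stim_duration is None:
        stim_duration = duration
    times = np.arange(n) * dt
    values = np.zeros(n)
    n_pulses = int(math.floor(freq * stim_duration))
    half = _TRUNCATE_WIDTHS * pulse_width
    for k in range(n_pulses):
        c = k / freq + delay
        i0 = max(0, int(math.ceil((c - half) / dt)))
        i1 = min(n, int(math.floor((c + half) / dt)) + 1)
        if i0 >= i1:
            continue
        t = times[i0:i1]
        values[i0:i1] += amplitude * np.exp(-0.5 * ((t - c) / pulse_width) ** 2)
    # hard zero outside the stimulation block
    values[times >= stim_duration] = 0.0
    return PulseTrain(times=times, values=values, target="psi1")


def build_protocol_inputs(
    freq: float,
    params,
    protocol: StimulusProtocol,
    dt: float,
    duration: float | None = None,
    *,
    interpolate_luminance: bool = False,
) -> tuple[PulseTrain, PulseTrain, PulseTrain]:
    """Build the three input trains (psi1, psi2, psi3) for one frequency.

    psi1 drives the transmission interneuron with amplitude
    ``gain1 * luminance * protocol.amplitude``; psi2 drives the PC basal
    dendrites with ``gain2 * luminance * protocol.amplitude`` and is delayed
    by ``protocol.delay``.  psi3 (apical, cortico-cortical) is identically
    zero in simulation mode, with ``gain3`` retained for user-supplied
    apical drive.
    """
    lum = luminance_factor(freq, protocol, interpolate=interpolate_luminance)
    if duration is None:
        duration = protocol.block_duration
    base = protocol.amplitude * lum
    p1 = build_pulse_train(
        freq, duration, dt, params.gain1 * base, protocol.pulse_width,
        delay=0.0, stim_duration=protocol.stim_duration,
    )
    p2 = build_pulse_train(
        freq, duration, dt, params.gain2 * base, protocol.pulse_width,
        delay=protocol.delay, stim_duration=protocol.stim_duration,
    )
    p3 = PulseTrain(times=p1.times, values=np.zeros_like(p1.values), target="psi3")
    return (
        PulseTrain(times=p1.times, values=p1.values, target="psi1"),
        PulseTrain(times=p2.times, values=p2.values, target="psi2"),
        p3,
    )
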