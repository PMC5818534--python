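"""Stimulus protocol descriptions and waveform synthesis.

A :class:`StimulusProtocol` is a declarative description of an injected
current waveform (or a voltage-clamp command).  Waveforms are rendered onto
a uniform time grid by :func:`waveform`, so that a protocol stored alongside
a sweep is sufficient to regenerate the exact stimulus.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

VALID_KINDS = ("long_step", "brief_step", "ramp", "pink_noise", "voltage_clamp")


@dataclass(frozen=True)
class StimulusProtocol:
    """Declarative description of a current-clamp (or voltage-clamp) stimulus.

    Parameters
    ----------
    kind
        One of ``long_step``, ``brief_step``, ``ramp``, ``pink_noise``,
        ``voltage_clamp``.
    onset
        Stimulus onset, seconds from sweep start.
    duration
        Stimulus duration in seconds.  Long steps are restricted to the
        1-2 s range used experimentally.
    amplitude
        Step amplitude (pA), ramp plateau cap (pA), or noise mean (pA).
    ramp_rate
        Ramp slope in pA/s (ramp only).
    noise_cv
        Coefficient of variation of the pink-noise stimulus.
    noise_seed
        Seed for the pink-noise synthesis; same seed, same waveform.
    total_duration
        Total sweep duration in seconds (baseline + stimulus + tail).
    """

    kind: str
    onset: float = 0.1
    duration: float = 1.0
    amplitude: float = 0.0
    ramp_rate: float = 25.0
    noise_cv: float = 0.25
    noise_seed: int = 0
    total_duration: float | None = None

    def __post_init__(self):
        if self.kind not in VALID_KINDS:
            raise ValueError(f"unknown stimulus kind {self.kind!r}")
        if self.duration <= 0:
            raise ValueError("stimulus duration must be positive")
        if self.kind == "long_step" and not (1.0 <= self.duration <= 2.0):
            raise ValueError("long_step duration must lie in [1, 2] s")

    @property
    def end(self) -> float:
        return self.onset + self.duration

    def sweep_duration(self) -> float:
        """Total sweep length in seconds (default: stimulus + 0.25 s tail)."""
        if self.total_duration is not None:
            return self.total_duration
        return self.onset + self.duration + 0.25

    def key(self) -> str:
        """Grouping key: protocols identical up to repeat share a key."""
        d = asdict(self)
        return "|".join(f"{k}={d[k]}" for k in sorted(d))

    def to_dict(self) -> dict:
        return asdict(self)

    @staticmethod
    def from_dict(d: dict) -> "StimulusProtocol":
        return StimulusProtocol(**d)


def pink_noise_wave(duration: float, mean_amp: float, cv: float, seed: int,
                    dt: float, f_lo: float = 1.0, f_hi: float = 100.0) -> np.ndarray:
    """Synthesize a band-limited 1/f-power noise current trace.

    Spectral synthesis: Fourier amplitudes scale as ``1/sqrt(f)`` (power
    spectral density ~ 1/f) between ``f_lo`` and ``f_hi`` Hz with uniformly
    random phases, zero outside the band (the upper cutoff is the low-pass
    limit of the stimulus).  The result is rescaled to the requested mean
    and coefficient of variation.

    Parameters
    ----------
    duration : seconds
    mean_amp : pA
    cv : target SD / mean
    seed : RNG seed (identical seed gives an identical trace)
    dt : sample interval, seconds
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    n = int(round(duration / dt))
    rng = np.random.default_rng(seed)
    freqs = np.fft.rfftfreq(n, d=dt)
    amp = np.zeros_like(freqs)
    band = (freqs >= f_lo) & (freqs <= f_hi)
    amp[band] = 1.0 / np.sqrt(freqs[band])
    phases = rng.uniform(0, 2 * np.pi, size=freqs.size)
    spec = amp * np.exp(1j * phases)
    x = np.fft.irfft(spec, n=n)
    sd = x.std()
    if sd > 0:
        x = x / sd * (abs(mean_amp) * cv)
    return x + mean_amp


def waveform(protocol: StimulusProtocol, dt: float) -> np.ndarray:
    """Render a protocol to a current trace (pA) on a grid of step ``dt`` s.

    Voltage-clamp protocols have no current waveform and raise.
    """
    if protocol.kind == "voltage_clamp":
        raise ValueError("voltage_clamp protocols carry a command, not a current")
    n = int(round(protocol.sweep_duration() / dt))
    i = np.zeros(n)
    i0 = int(round(protocol.onset / dt))
    i1 = min(int(round(protocol.end / dt)), n)
    if protocol.kind in ("long_step", "brief_step"):
        i[i0:i1] = protocol.amplitude
    elif protocol.kind == "ramp":
        tt = (np.arange(i0, i1) - i0) * dt
        i[i0:i1] = protocol.ramp_rate * tt
    elif protocol.kind == "pink_noise":
        i[i0:i1] = pink_noise_wave(protocol.duration, protocol.amplitude,
                                   protocol.noise_cv, protocol.noise_seed, dt)[: i1 - i0]
    return i
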