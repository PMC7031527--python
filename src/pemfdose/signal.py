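"""Pulsed drive current: synthesis, harmonic decomposition, reconstruction.

The stimulation device delivers a pulsed current into the coil: a short
active phase (default 1.3 ms) repeated at 75 Hz, with a peak of 240 A.
Only peak, active-phase duration and repetition rate of the clinical
device are published, so the pulse *shape* is configurable; the default
is a trapezoid with short rise/fall ramps.

The quasistatic field problem is solved per frequency, so the periodic
pulse is decomposed into Fourier components on a configurable frequency
grid and per-voxel field time courses are recomposed by superposition:

    x(t) = x_dc + sum_k Re[ a_k * e^{j 2 pi f_k t} ]

The magnetic flux density B is linear in the coil current and in phase
with it, so its reconstruction includes the DC Fourier term; induced
current density J has no DC response (omega = 0 induces nothing) and is
reconstructed from the band harmonics only.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigurationError, InvariantViolation

__all__ = [
    "WaveformShape",
    "PulsedSignalSpec",
    "HarmonicSet",
    "FieldTimeCourse",
    "synthesize_pulse",
    "decompose",
    "native_band",
    "reconstruct_waveform",
    "reconstruct_time_course",
    "peak_magnitude",
]


class WaveformShape(str, enum.Enum):
    TRAPEZOID = "trapezoid"
    RAISED_COSINE = "raised_cosine"
    EXPONENTIAL_DECAY = "exponential_decay"


@dataclass(frozen=True)
class PulsedSignalSpec:
    """One period of the pulsed coil current.

    Parameters
    ----------
    peak_current : float
        Peak of |i(t)| in amperes (device value: 240 A).
    active_phase : float
        Duration of the active phase in seconds (device value: 1.3 ms).
    repetition_frequency : float
        Pulse repetition rate in Hz (device value: 75 Hz).
    waveform_shape : WaveformShape or str
        Pulse shape used within the active phase; the pulse is zero
        outside it.
    rise_fraction : float
        Trapezoid rise/fall ramp duration as a fraction of the active
        phase.  The default (10%, i.e. 130 us ramps) keeps essentially
        all pulse energy below 7.5 kHz, consistent with a drive signal
        that the analysis band can reconstruct faithfully.
    decay_fraction : float
        Time constant of the exponential-decay shape as a fraction of
        the active phase.
    """

    peak_current: float = 240.0
    active_phase: float = 1.3e-3
    repetition_frequency: float = 75.0
    waveform_shape: WaveformShape = WaveformShape.TRAPEZOID
    rise_fraction: float = 0.10
    decay_fraction: float = 0.25

    def __post_init__(self):
        object.__setattr__(
            self, "waveform_shape", WaveformShape(self.waveform_shape)
        )
        if self.repetition_frequency <= 0:
            raise ConfigurationError("repetition_frequency must be positive")
        if self.active_phase <= 0:
            raise ConfigurationError("active_phase must be positive")
        if self.active_phase >= self.period:
            raise ConfigurationError(
                f"active_phase {self.active_phase} s does not fit in one "
                f"period {self.period} s of the {self.repetition_frequency} Hz signal"
            )
        if self.peak_current < 0:
            raise ConfigurationError("peak_current must be non-negative")
        if not (0 <= self.rise_fraction < 0.5):
            raise ConfigurationError("rise_fraction must lie in [0, 0.5)")
        if self.decay_fraction <= 0:
            raise ConfigurationError("decay_fraction must be positive")

    @property
    def period(self) -> float:
        return 1.0 / self.repetition_frequency


def synthesize_pulse(spec: PulsedSignalSpec, n_samples: int = 4096):
    """Sample one period of the pulse.

    Returns ``(times, values)``: ``n_samples`` uniform samples covering
    ``[0, T)`` (right endpoint excluded, as usual for periodic signals).
    The synthesized waveform attains the requested peak within 0.1%.
    """
    if n_samples < 16:
        raise ConfigurationError("n_samples must be at least 16")
    T = spec.period
    t = np.arange(n_samples) * (T / n_samples)
    tau = spec.active_phase
    i = np.zeros(n_samples)
    active = t < tau
    ta = t[active]
    shape = spec.waveform_shape
    if shape is WaveformShape.TRAPEZOID:
        r = spec.rise_fraction * tau
        if r == 0.0:
            i[active] = 1.0
        else:
            up = np.clip(ta / r, 0.0, 1.0)
            down = np.clip((tau - ta) / r, 0.0, 1.0)
            i[active] = np.minimum(up, down)
    elif shape is WaveformShape.RAISED_COSINE:
        i[active] = 0.5 * (1.0 - np.cos(2.0 * np.pi * ta / tau))
    elif shape is WaveformShape.EXPONENTIAL_DECAY:
        i[active] = np.exp(-ta / (spec.decay_fraction * tau))
    else:  # pragma: no cover - enum is closed
        raise ConfigurationError(f"unknown waveform shape {shape}")
    i *= spec.peak_current
    if spec.peak_current > 0:
        peak = np.max(np.abs(i))
        if abs(peak - spec.peak_current) > 1e-3 * spec.peak_current:
            raise InvariantViolation(
                f"sampled waveform peak {peak} deviates from spec peak "
                f"{spec.peak_current} by more than 0.1%"
            )
    return t, i


@dataclass
class HarmonicSet:
    """Complex one-sided harmonic amplitudes on a uniform frequency grid.

    ``values`` holds amplitudes ``a_k`` such that the contribution of
    component ``k`` to the real signal is ``Re[a_k e^{j 2 pi f_k t}]``
    (i.e. twice the usual two-sided Fourier coefficient).  ``dc`` is the
    signal mean, kept separately because the analysis band starts above
    0 Hz.
    """

    frequencies: np.ndarray
    complex_amplitudes: np.ndarray
    band: tuple  # (f_min, f_max, step)
    dc: float = 0.0

    def __post_init__(self):
        self.frequencies = np.asarray(self.frequencies, dtype=float)
        self.complex_amplitudes = np.asarray(
            self.complex_amplitudes, dtype=complex
        )
        f_min, f_max, step = self.band
        n_expected = expected_component_count(f_min, f_max, step)
        if len(self.frequencies) != n_expected:
            raise InvariantViolation(
                f"band {self.band} requires {n_expected} components, "
                f"got {len(self.frequencies)}"
            )
        if len(self.frequencies) != len(self.complex_amplitudes):
            raise InvariantViolation("frequency/amplitude length mismatch")
        if len(self.frequencies) > 1:
            diffs = np.diff(self.frequencies)
            if np.any(diffs <= 0):
                raise InvariantViolation("frequencies must be strictly increasing")
            if not np.allclose(diffs, step, rtol=1e-9, atol=1e-9):
                raise InvariantViolation(
                    f"frequencies must be uniformly spaced by {step} Hz"
                )

    def __len__(self):
        return len(self.frequencies)


def expected_component_count(f_min: float, f_max: float, step: float) -> int:
    """Number of grid frequencies in [f_min, f_max] with spacing ``step``."""
    if step <= 0 or f_min <= 0 or f_max < f_min:
        raise ConfigurationError(f"invalid band ({f_min}, {f_max}, {step})")
    width = f_max - f_min
    n_steps = width / step
    if abs(n_steps - round(n_steps)) > 1e-9 * max(1.0, n_steps):
        raise ConfigurationError(
            f"step {step} Hz does not divide the band width {width} Hz"
        )
    return int(round(n_steps)) + 1


def native_band(spec: PulsedSignalSpec, f_max: float = 7500.0) -> tuple:
    """Frequency band holding the signal's own harmonics up to ``f_max``.

    A ``f0``-periodic signal has spectral lines only at multiples of its
    repetition frequency ``f0``; this returns ``(f0, n*f0, f0)`` with the
    largest ``n*f0 <= f_max``.
    """
    f0 = spec.repetition_frequency
    n = int(np.floor(f_max / f0 + 1e-9))
    if n < 1:
        raise ConfigurationError("f_max below the repetition frequency")
    return (f0, n * f0, f0)


def decompose(times, waveform, band) -> HarmonicSet:
    """Project one period of a waveform onto a uniform frequency grid.

    Amplitudes are Fourier-series coefficients of the periodic signal:
    grid frequencies that are integer multiples of the repetition
    frequency carry ``2 c_k``; frequencies that are not (possible when
    replicating a solve grid whose step does not match the repetition
    rate) are orthogonal to the signal over the common period and get
    exactly zero.
    """
    times = np.asarray(times, dtype=float)
    waveform = np.asarray(waveform, dtype=float)
    if times.ndim != 1 or times.shape != waveform.shape or len(times) < 16:
        raise ConfigurationError("times/waveform must be matching 1-D arrays")
    dt = times[1] - times[0]
    if not np.allclose(np.diff(times), dt, rtol=1e-9):
        raise ConfigurationError("waveform must be uniformly sampled")
    period = times[-1] + dt
    f0 = 1.0 / period
    sample_rate = 1.0 / dt
    f_min, f_max, step = band
    n = expected_component_count(f_min, f_max, step)
    freqs = f_min + step * np.arange(n)
    if f_max > sample_rate / 2:
        raise ConfigurationError(
            f"band top {f_max} Hz exceeds the Nyquist limit "
            f"{sample_rate / 2} Hz of the sampled waveform"
        )
    # FFT gives coefficients at exact multiples of f0.
    spectrum = np.fft.rfft(waveform) / len(waveform)
    amplitudes = np.zeros(n, dtype=complex)
    harmonic_index = freqs / f0
    for i, (f, k) in enumerate(zip(freqs, harmonic_index)):
        k_round = int(round(k))
        if abs(k - k_round) < 1e-6 and 0 < k_round < len(spectrum):
            amplitudes[i] = 2.0 * spectrum[k_round]
        # else: f is not a harmonic of the signal; projection over the
        # common period vanishes and the amplitude stays zero.
    dc = float(spectrum[0].real)
    return HarmonicSet(freqs, amplitudes, (f_min, f_max, step), dc=dc)


def reconstruct_waveform(harmonics: HarmonicSet, times, include_dc: bool = True):
    """Band-limited signal value at ``times`` (superposition of harmonics)."""
    times = np.asarray(times, dtype=float)
    phase = np.exp(
        2j * np.pi * np.outer(times, harmonics.frequencies)
    )  # (n_t, n_f)
    out = (phase @ harmonics.complex_amplitudes).real
    if include_dc:
        out = out + harmonics.dc
    return out


class FieldQuantity(str, enum.Enum):
    B_MAGNITUDE = "B_magnitude"
    J_MAGNITUDE = "J_magnitude"
    J_VECTOR = "J_vector"


@dataclass
class FieldTimeCourse:
    """Field time series at one voxel over exactly one signal period."""

    times: np.ndarray
    values: np.ndarray  # (n_t,) magnitudes or (n_t, 3) vectors
    voxel_index: tuple
    quantity: FieldQuantity

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values)
        if len(self.times) != len(self.values):
            raise InvariantViolation("times/values length mismatch")

    @property
    def magnitudes(self) -> np.ndarray:
        if self.values.ndim == 2:
            return np.linalg.norm(self.values, axis=1)
        return np.abs(self.values)

    @property
    def peak(self) -> float:
        """Maximum field magnitude over the period (the 'signal peak')."""
        return float(np.max(self.magnitudes))

    def to_dataframe(self):
        import pandas as pd

        if self.values.ndim == 2:
            data = {"time_s": self.times}
            for axis, name in enumerate("xyz"):
                data[f"value_{name}"] = self.values[:, axis]
            return pd.DataFrame(data)
        return pd.DataFrame({"time_s": self.times, "value": self.values})


def reconstruct_time_course(
    unit_field_phasors,
    harmonics: HarmonicSet,
    voxel_index=(0, 0, 0),
    quantity: FieldQuantity = FieldQuantity.B_MAGNITUDE,
    n_samples: int = 1024,
    dc_unit_field=None,
) -> FieldTimeCourse:
    """Recombine per-frequency unit-current field phasors into a time series.

    Parameters
    ----------
    unit_field_phasors : array, shape (n_freq,) or (n_freq, 3)
        Complex field phasor per harmonic at one voxel for a 1 A drive;
        each is scaled by the corresponding harmonic amplitude.
    harmonics : HarmonicSet
        Drive-signal decomposition; lengths must match.
    dc_unit_field : scalar or (3,), optional
        Field per ampere at zero frequency.  For B this equals the
        (real) unit field and adds the DC response ``dc * field``; J has
        no DC response, so leave it None.
    """
    phasors = np.atleast_1d(np.asarray(unit_field_phasors, dtype=complex))
    if phasors.shape[0] != len(harmonics):
        raise InvariantViolation(
            f"{phasors.shape[0]} phasors for {len(harmonics)} harmonics"
        )
    period = 1.0 / harmonics.frequencies[0] if harmonics.frequencies[0] > 0 else 1.0
    # Times span exactly one repetition period of the underlying signal:
    # the harmonic grid is uniform with step equal to the fundamental.
    f_min, _, step = harmonics.band
    fundamental = step
    period = 1.0 / fundamental
    times = np.arange(n_samples) * (period / n_samples)
    phase = np.exp(2j * np.pi * np.outer(times, harmonics.frequencies))
    weighted = phasors * harmonics.complex_amplitudes[(...,) + (None,) * (phasors.ndim - 1)]
    values = (phase @ weighted).real
    if dc_unit_field is not None:
        values = values + harmonics.dc * np.asarray(dc_unit_field, dtype=float)
    return FieldTimeCourse(times, values, tuple(voxel_index), FieldQuantity(quantity))


def peak_magnitude(unit_field_phasors, harmonics: HarmonicSet,
                   n_samples: int = 256, dc_unit_field=None,
                   chunk_size: int = 8192) -> np.ndarray:
    """Per-voxel peak field magnitude over one reconstructed period.

    ``unit_field_phasors`` has shape (n_freq, n_voxels) for scalar
    fields or (n_freq, n_voxels, 3) for vector fields (per-ampere
    phasors, scaled internally by the harmonic amplitudes).  Returns
    the max over time of the field magnitude at each voxel - the
    "signal peak" exposure used for thresholding.
    """
    phasors = np.asarray(unit_field_phasors, dtype=complex)
    if phasors.shape[0] != len(harmonics):
        raise InvariantViolation(
            f"{phasors.shape[0]} phasor sets for {len(harmonics)} harmonics"
        )
    _, _, step = harmonics.band
    period = 1.0 / step
    times = np.arange(n_samples) * (period / n_samples)
    phase = np.exp(2j * np.pi * np.outer(times, harmonics.frequencies))
    n_vox = phasors.shape[1]
    out = np.empty(n_vox)
    amps = harmonics.complex_amplitudes
    weighted_all = phasors * amps[(slice(None),) + (None,) * (phasors.ndim - 1)]
    for lo in range(0, n_vox, chunk_size):
        w = weighted_all[:, lo:lo + chunk_size]
        if phasors.ndim == 3:
            vals = np.einsum("tf,fvc->tvc", phase, w).real
            if dc_unit_field is not None:
                vals = vals + harmonics.dc * np.asarray(dc_unit_field)[lo:lo + chunk_size]
            mags = np.linalg.norm(vals, axis=2)
        else:
            vals = (phase @ w).real
            if dc_unit_field is not None:
                vals = vals + harmonics.dc * np.asarray(dc_unit_field)[lo:lo + chunk_size]
            mags = np.abs(vals)
        out[lo:lo + chunk_size] = mags.max(axis=0)
    return out
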