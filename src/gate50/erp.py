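"""Continuous-EEG to averaged-ERP preprocessing chain for the paired-click task.

Stages, applied in order:

1. online artifact flagging (|x| > 100 uV on Cz or EOG in the -100..500 ms
   window around each pair onset);
2. ocular correction (whole-record least-squares regression of Cz on the EOG
   channel(s), subtracting the fitted contribution);
3. epoching from -100 to 923 ms around the first click (1024 samples at
   1 kHz), covering both S1 and S2;
4. offline rejection of epochs containing |x| > 50 uV;
5. point-wise averaging of the retained epochs followed by a 10-50 Hz
   frequency-domain bandpass with raised-cosine transitions.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from .errors import ConfigurationError, PipelineError

__all__ = [
    "RawRecording",
    "EpochSet",
    "ERPAverage",
    "EPOCH_WINDOW_MS",
    "flag_online_artifacts",
    "correct_eog",
    "epoch",
    "reject_epochs",
    "average_and_filter",
    "bandpass_frequency_domain",
    "preprocess",
]

log = logging.getLogger("gate50.erp")

EPOCH_WINDOW_MS = (-100, 923)  # inclusive endpoints at 1 kHz -> 1024 samples
ONLINE_WINDOW_MS = (-100, 500)
ONLINE_THRESHOLD_UV = 100.0
OFFLINE_THRESHOLD_UV = 50.0


@dataclass
class RawRecording:
    """Continuous multichannel EEG in microvolts with pair-onset events.

    ``samples`` has shape (n_channels, n_samples); ``events`` are first-click
    onset times in ms, strictly increasing.  ``meta`` carries free-form
    provenance (the simulator stores its ground truth there).
    """

    samples: np.ndarray
    sampling_rate: float
    channel_names: list[str]
    events: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        self.events = np.asarray(self.events, dtype=float)
        if self.samples.ndim != 2:
            raise ConfigurationError("samples must be 2-D (channels x time)")
        if len(self.channel_names) != self.samples.shape[0]:
            raise ConfigurationError("one channel name per sample row required")
        if self.events.size and np.any(np.diff(self.events) <= 0):
            raise ConfigurationError("events must be strictly increasing")

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    def channel(self, name: str) -> np.ndarray:
        try:
            return self.samples[self.channel_names.index(name)]
        except ValueError:
            raise ConfigurationError(f"channel {name!r} not present") from None

    def eog_channels(self) -> list[str]:
        return [c for c in self.channel_names if "EOG" in c.upper()]


@dataclass
class EpochSet:
    """Cz epochs (trials x time) with per-trial retention bookkeeping."""

    epochs: np.ndarray
    window: tuple[int, int]
    sampling_rate: float
    retained: np.ndarray
    reasons: list

    @property
    def n_retained(self) -> int:
        return int(self.retained.sum())

    def times_ms(self) -> np.ndarray:
        lo, _ = self.window
        step = 1000.0 / self.sampling_rate
        return lo + step * np.arange(self.epochs.shape[1])


@dataclass
class ERPAverage:
    """Averaged, bandpass-filtered evoked response at Cz."""

    waveform: np.ndarray
    window: tuple[int, int]
    sampling_rate: float
    n_trials_used: int
    filter_band: tuple[float, float] = (10.0, 50.0)

    def times_ms(self) -> np.ndarray:
        lo, _ = self.window
        step = 1000.0 / self.sampling_rate
        return lo + step * np.arange(self.waveform.size)

    def value_at(self, t_ms: float) -> float:
        idx = int(round((t_ms - self.window[0]) * self.sampling_rate / 1000.0))
        return float(self.waveform[idx])


def _event_indices(raw: RawRecording) -> np.ndarray:
    return np.round(raw.events * raw.sampling_rate / 1000.0).astype(int)


def flag_online_artifacts(
    raw: RawRecording, threshold_uv: float = ONLINE_THRESHOLD_UV
) -> tuple[np.ndarray, list]:
    """Flag trials whose -100..500 ms window exceeds ±threshold on Cz or EOG.

    Returns (flags, reasons): ``flags[i]`` is True when trial *i* must be
    excluded; ``reasons[i]`` is ``"online_artifact"``, ``"out_of_bounds"`` or
    None.
    """
    if raw.events.size == 0:
        raise PipelineError("recording has no events")
    fs = raw.sampling_rate
    lo = int(round(ONLINE_WINDOW_MS[0] * fs / 1000.0))
    hi = int(round(ONLINE_WINDOW_MS[1] * fs / 1000.0))
    channels = ["Cz"] + raw.eog_channels()
    data = np.vstack([raw.channel(c) for c in channels])
    flags = np.zeros(raw.events.size, dtype=bool)
    reasons: list = [None] * raw.events.size
    for i, idx in enumerate(_event_indices(raw)):
        a, b = idx + lo, idx + hi
        if a < 0 or b >= raw.n_samples:
            flags[i], reasons[i] = True, "out_of_bounds"
            continue
        if np.any(np.abs(data[:, a:b + 1]) > threshold_uv):
            flags[i], reasons[i] = True, "online_artifact"
    return flags, reasons


def correct_eog(raw: RawRecording) -> RawRecording:
    """Remove ocular contamination from Cz by whole-record regression.

    Cz becomes Cz - b . EOG, where b is the least-squares slope of Cz on the
    EOG channel(s) over the whole recording.  A zero-variance EOG channel
    contributes nothing and triggers a warning.  Any DC shift this introduces
    is immaterial downstream (the bandpass removes it).
    """
    eog_names = raw.eog_channels()
    if not eog_names:
        raise ConfigurationError("no EOG channel present for ocular correction")
    cz = raw.channel("Cz")
    eog = np.vstack([raw.channel(c) for c in eog_names])
    centered = eog - eog.mean(axis=1, keepdims=True)
    keep = centered.std(axis=1) > 0
    if not keep.any():
        warnings.warn("EOG channel(s) have zero variance; Cz left unchanged")
        return raw
    X = centered[keep].T
    b, *_ = np.linalg.lstsq(X, cz - cz.mean(), rcond=None)
    corrected = cz - eog[keep].T @ b
    samples = raw.samples.copy()
    samples[raw.channel_names.index("Cz")] = corrected
    return replace(raw, samples=samples, meta={**raw.meta, "eog_slopes": b.tolist()})


def _resample_to_1khz(raw: RawRecording) -> RawRecording:
    if raw.sampling_rate == 1000.0:
        return raw
    n = raw.n_samples
    duration_ms = (n - 1) * 1000.0 / raw.sampling_rate
    old_t = np.arange(n) * 1000.0 / raw.sampling_rate
    new_t = np.arange(int(np.floor(duration_ms)) + 1, dtype=float)
    samples = np.vstack([np.interp(new_t, old_t, ch) for ch in raw.samples])
    return replace(raw, samples=samples, sampling_rate=1000.0)


def epoch(
    raw: RawRecording,
    online_threshold_uv: float = ONLINE_THRESHOLD_UV,
    exclude_trials: list[int] | None = None,
) -> EpochSet:
    """Cut one -100..923 ms Cz epoch per pair onset.

    Trials failing the online ±100 uV screen (or falling outside the
    recording) are kept in the matrix but marked not-retained.
    ``exclude_trials`` mimics manual rejection of individually named trials.
    """
    raw = _resample_to_1khz(raw)
    flags, reasons = flag_online_artifacts(raw, online_threshold_uv)
    if exclude_trials:
        for t in exclude_trials:
            flags[t], reasons[t] = True, "manual"
    lo, hi = EPOCH_WINDOW_MS
    n_time = hi - lo + 1
    cz = raw.channel("Cz")
    idxs = _event_indices(raw)
    epochs = np.zeros((idxs.size, n_time))
    retained = ~flags
    for i, idx in enumerate(idxs):
        a, b = idx + lo, idx + hi
        if a < 0 or b >= raw.n_samples:
            retained[i] = False
            if reasons[i] is None:
                reasons[i] = "out_of_bounds"
            continue
        epochs[i] = cz[a:b + 1]
    if not retained.any():
        raise PipelineError("no_usable_trials")
    log.info("epoched %d trials, %d retained after online screen",
             idxs.size, int(retained.sum()))
    return EpochSet(epochs, EPOCH_WINDOW_MS, 1000.0, retained, list(reasons))


def reject_epochs(
    epochs: EpochSet, threshold_uv: float = OFFLINE_THRESHOLD_UV
) -> EpochSet:
    """Clear the retained flag for epochs containing any |sample| > 50 uV."""
    retained = epochs.retained.copy()
    reasons = list(epochs.reasons)
    exceeding = np.abs(epochs.epochs).max(axis=1) > threshold_uv
    for i in np.nonzero(retained & exceeding)[0]:
        retained[i] = False
        reasons[i] = "offline_artifact"
    if not retained.any():
        raise PipelineError("no_usable_trials")
    log.info("offline rejection: %d of %d epochs retained",
             int(retained.sum()), retained.size)
    return EpochSet(epochs.epochs, epochs.window, epochs.sampling_rate,
                    retained, reasons)


def bandpass_frequency_domain(
    x: np.ndarray,
    fs: float,
    band: tuple[float, float] = (10.0, 50.0),
    transition_hz: float = 2.0,
) -> np.ndarray:
    """Zero-phase bandpass via the DFT: bins outside ``band`` are zeroed,
    with raised-cosine ramps of width ``transition_hz`` outside each edge.

    The gain is 1 inside [f1, f2], 0 below f1 - transition and above
    f2 + transition, and half-cosine in between.  Operating on DFT bins makes
    the output bit-reproducible for identical inputs.
    """
    f1, f2 = band
    if not 0 < f1 < f2:
        raise ConfigurationError("band must satisfy 0 < low < high")
    x = np.asarray(x, dtype=float)
    n = x.shape[-1]
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    gain = np.zeros_like(freqs)
    inside = (freqs >= f1) & (freqs <= f2)
    gain[inside] = 1.0
    lo_ramp = (freqs >= f1 - transition_hz) & (freqs < f1)
    gain[lo_ramp] = 0.5 * (1 - np.cos(np.pi * (freqs[lo_ramp] - (f1 - transition_hz)) / transition_hz))
    hi_ramp = (freqs > f2) & (freqs <= f2 + transition_hz)
    gain[hi_ramp] = 0.5 * (1 + np.cos(np.pi * (freqs[hi_ramp] - f2) / transition_hz))
    return np.fft.irfft(np.fft.rfft(x, axis=-1) * gain, n=n, axis=-1)


def average_and_filter(
    epochs: EpochSet, band: tuple[float, float] = (10.0, 50.0)
) -> ERPAverage:
    """Average the retained epochs, then bandpass in the frequency domain."""
    if epochs.n_retained < 1:
        raise PipelineError("no_usable_trials")
    mean = epochs.epochs[epochs.retained].mean(axis=0)
    filtered = bandpass_frequency_domain(mean, epochs.sampling_rate, band)
    return ERPAverage(filtered, epochs.window, epochs.sampling_rate,
                      epochs.n_retained, band)


def preprocess(
    raw: RawRecording,
    online_threshold_uv: float = ONLINE_THRESHOLD_UV,
    offline_threshold_uv: float = OFFLINE_THRESHOLD_UV,
    band: tuple[float, float] = (10.0, 50.0),
    exclude_trials: list[int] | None = None,
) -> tuple[ERPAverage, EpochSet]:
    """Full chain: ocular correction -> epoching -> rejection -> filtered mean."""
    corrected = correct_eog(raw)
    eps = epoch(corrected, online_threshold_uv, exclude_trials)
    eps = reject_epochs(eps, offline_threshold_uv)
    return average_and_filter(eps, band), eps
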