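"""P50 peak scoring at Cz.

The P50 response to a click is scored as the largest positive deflection
45-75 ms post-stimulus, measured peak-to-preceding-trough, where the trough
is the waveform minimum between 30 ms post-stimulus and the peak.  For the
test click (S2) the peak must fall within ±10 ms of the S1 latency or the S2
response is scored as zero.  Subjects with S1 amplitude < 0.5 uV are invalid.
The gating ratio S2/S1 is capped at 2.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .erp import ERPAverage
from .errors import ConfigurationError, MeasurementError

__all__ = ["PeakMeasure", "P50Result", "detect_peak", "measure_pair",
           "dichotomize_gating"]

PEAK_WINDOW_MS = (45.0, 75.0)
TROUGH_FLOOR_MS = 30.0
S2_LATENCY_TOL_MS = 10.0
S1_MIN_AMPLITUDE_UV = 0.5
RATIO_CAP = 2.0


@dataclass(frozen=True)
class PeakMeasure:
    """One scored deflection: peak, preceding trough, and their difference."""

    latency_ms: float
    peak_uv: float
    trough_uv: float
    trough_latency_ms: float
    amplitude_uv: float
    present: bool = True


@dataclass(frozen=True)
class P50Result:
    """The five P50 parameters for one subject plus validity flags."""

    s1_latency_ms: float
    s1_uv: float
    s2_uv: float
    diff_uv: float
    ratio: float
    valid: bool
    truncated: bool = False
    s2_zeroed: bool = False
    s2_latency_ms: float = float("nan")

    def as_row(self) -> dict:
        return {
            "s1_latency_ms": self.s1_latency_ms,
            "s1_uv": self.s1_uv,
            "s2_uv": self.s2_uv,
            "diff_uv": self.diff_uv,
            "ratio": self.ratio,
            "valid": self.valid,
            "truncated": self.truncated,
            "s2_zeroed": self.s2_zeroed,
        }


def detect_peak(erp: ERPAverage, stimulus_onset_ms: float) -> PeakMeasure:
    """Score the P50 deflection following one stimulus.

    Latency is the time of the maximum sample in [onset+45, onset+75]
    (earliest sample on ties); the trough is the minimum in
    [onset+30, latency).  A window maximum <= 0 is scored as an absent
    response (amplitude 0), since a non-positive "positive deflection" is
    contradictory.
    """
    t = erp.times_ms()
    lo = stimulus_onset_ms + PEAK_WINDOW_MS[0]
    hi = stimulus_onset_ms + PEAK_WINDOW_MS[1]
    floor = stimulus_onset_ms + TROUGH_FLOOR_MS
    if floor < t[0] or hi > t[-1]:
        raise MeasurementError("window_out_of_range")
    win = (t >= lo) & (t <= hi)
    if not win.any():
        raise MeasurementError("window_out_of_range")
    w = erp.waveform[win]
    peak_rel = int(np.argmax(w))  # argmax returns the first maximum
    peak_uv = float(w[peak_rel])
    latency = float(t[win][peak_rel])
    if peak_uv <= 0:
        return PeakMeasure(latency, peak_uv, peak_uv, latency, 0.0, present=False)
    pre = (t >= floor) & (t < latency)
    if not pre.any():
        # peak sits at the very start of its window; no preceding samples
        return PeakMeasure(latency, peak_uv, peak_uv, latency, 0.0, present=True)
    v = erp.waveform[pre]
    trough_rel = int(np.argmin(v))
    trough_uv = float(v[trough_rel])
    trough_latency = float(t[pre][trough_rel])
    return PeakMeasure(latency, peak_uv, trough_uv, trough_latency,
                       peak_uv - trough_uv)


def measure_pair(
    erp: ERPAverage,
    s1_onset_ms: float = 0.0,
    s2_onset_ms: float = 500.0,
) -> P50Result:
    """Score both clicks of a pair and derive the five P50 parameters."""
    if s2_onset_ms <= s1_onset_ms:
        raise ConfigurationError("s2 onset must follow s1 onset")
    s1 = detect_peak(erp, s1_onset_ms)
    s1_lat_post = s1.latency_ms - s1_onset_ms
    if s1.amplitude_uv < S1_MIN_AMPLITUDE_UV:
        return P50Result(s1_lat_post, s1.amplitude_uv, float("nan"),
                         float("nan"), float("nan"), valid=False)
    s2 = detect_peak(erp, s2_onset_ms)
    s2_lat_post = s2.latency_ms - s2_onset_ms
    s2_amp = s2.amplitude_uv
    s2_zeroed = False
    if abs(s2_lat_post - s1_lat_post) > S2_LATENCY_TOL_MS or not s2.present:
        s2_amp, s2_zeroed = 0.0, True
    raw_ratio = s2_amp / s1.amplitude_uv
    truncated = raw_ratio > RATIO_CAP
    ratio = min(raw_ratio, RATIO_CAP)
    return P50Result(
        s1_latency_ms=s1_lat_post,
        s1_uv=s1.amplitude_uv,
        s2_uv=s2_amp,
        diff_uv=s1.amplitude_uv - s2_amp,
        ratio=ratio,
        valid=True,
        truncated=truncated,
        s2_zeroed=s2_zeroed,
        s2_latency_ms=s2_lat_post,
    )


def dichotomize_gating(ratio: float, cutoff: float = 0.4) -> int:
    """1 when the gating ratio strictly exceeds the cutoff (impaired gating)."""
    if not 0.0 <= ratio <= RATIO_CAP:
        raise ConfigurationError(f"gating ratio {ratio} outside [0, {RATIO_CAP}]")
    return int(ratio > cutoff)
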