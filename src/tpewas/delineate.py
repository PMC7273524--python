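"""T-wave delineation on signal-averaged beats.

The Tpeak-to-Tend (Tpe) interval is the temporal difference between the
T-wave apex and the T-wave end, a proxy for dispersion of ventricular
repolarization.  The apex is the absolute extremum of the T wave
(refined by parabolic interpolation); the end is found by the tangent
method — the tangent at the point of steepest post-peak slope is
intersected with the isoelectric baseline.

For a Gaussian T wave of half-width sigma the tangent method has a
closed form: the steepest descent lies at mu + sigma and the tangent
crosses baseline at mu + 2 sigma, so Tpe = 2 sigma.  The synthetic
generator exploits exactly this identity, which makes recovery of the
generating Tpe a sharp end-to-end test of the pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .ecg import AveragedBeat
from .exceptions import QCError

__all__ = ["Fiducials", "delineate_beat", "find_t_peak", "find_t_end", "tpe"]

#: Baseline estimation segment: the 40 ms immediately preceding QRS onset.
BASELINE_SEG_MS = 40.0

#: Default T-search window relative to the QRS fiducial (ms).
T_SEARCH_START_MS = 120.0
T_SEARCH_END_MS = 450.0


@dataclass(frozen=True)
class Fiducials:
    """Beat fiducial times in ms relative to the waveform start."""

    qrs_onset: float
    qrs_offset: float
    t_peak: float
    t_end: float

    def __post_init__(self):
        ordered = (
            self.qrs_onset < self.qrs_offset < self.t_peak
            and self.t_end >= self.t_peak
        )
        if not ordered:
            raise QCError(
                "fiducial_order",
                f"require qrs_onset < qrs_offset < t_peak < t_end, got "
                f"({self.qrs_onset:.1f}, {self.qrs_offset:.1f}, "
                f"{self.t_peak:.1f}, {self.t_end:.1f})",
            )


def tpe(fid: Fiducials) -> float:
    """Tpeak-to-Tend interval in ms; never silently clipped."""
    value = fid.t_end - fid.t_peak
    if value < 0:
        raise QCError("negative_tpe", f"t_end {fid.t_end} < t_peak {fid.t_peak}")
    return value


def _baseline(beat: AveragedBeat, qrs_onset_idx: int) -> float:
    fs = beat.fs
    seg = int(BASELINE_SEG_MS / 1000.0 * fs)
    lo = max(0, qrs_onset_idx - seg)
    if qrs_onset_idx - lo < 2:
        return float(np.median(beat.waveform[: max(qrs_onset_idx, 2)]))
    return float(np.median(beat.waveform[lo:qrs_onset_idx]))


def _qrs_bounds(beat: AveragedBeat) -> tuple[int, int]:
    """Locate QRS onset/offset by amplitude decay around the R apex."""
    x = beat.waveform
    fs = beat.fs
    r = beat.qrs_index
    rough_base = float(np.median(x[: max(int(0.1 * fs), 2)]))
    amp = np.abs(x - rough_base)
    thr = 0.02 * amp[r]
    run = max(2, int(0.008 * fs))

    onset = max(0, r - int(0.08 * fs))
    below = 0
    for i in range(r - 1, -1, -1):
        below = below + 1 if amp[i] < thr else 0
        if below >= run:
            onset = i + run - 1
            break

    offset = min(len(x) - 1, r + int(0.08 * fs))
    below = 0
    for i in range(r + 1, len(x)):
        below = below + 1 if amp[i] < thr else 0
        if below >= run:
            offset = i - run + 1
            break
    return onset, offset


def find_t_peak(
    beat: AveragedBeat,
    search_window: tuple[float, float] | None = None,
    baseline: float | None = None,
) -> float:
    """Locate the T-wave apex (ms from waveform start).

    The apex is the absolute extremum of the baseline-corrected signal
    inside the search window, refined by 3-point parabolic
    interpolation, so inverted T waves are handled identically to
    upright ones.

    Raises
    ------
    QCError
        Flat or monotone segment (extremum on the window edge, or
        amplitude indistinguishable from baseline).
    """
    fs = beat.fs
    r = beat.qrs_index
    if search_window is None:
        end_ms = min(T_SEARCH_END_MS, 0.75 * beat.rr_mean)
        search_window = (
            r / fs * 1000.0 + T_SEARCH_START_MS,
            r / fs * 1000.0 + end_ms,
        )
    lo = int(round(search_window[0] / 1000.0 * fs))
    hi = int(round(search_window[1] / 1000.0 * fs))
    lo = max(lo, 0)
    hi = min(hi, len(beat.waveform))
    if hi - lo < 3:
        raise QCError("t_search_window", "search window shorter than 3 samples")
    if baseline is None:
        onset, _ = _qrs_bounds(beat)
        baseline = _baseline(beat, onset)
    y = beat.waveform[lo:hi] - baseline
    i = int(np.argmax(np.abs(y)))
    if i == 0 or i == len(y) - 1:
        raise QCError("t_peak_on_edge", "no interior extremum in search window")
    if np.abs(y[i]) < 1e-6 or np.ptp(y) < 1e-6:
        raise QCError("flat_t_segment", "no T wave above baseline noise")
    # parabolic refinement on the signed samples around the extremum
    s = np.sign(y[i])
    y0, y1, y2 = s * y[i - 1], s * y[i], s * y[i + 1]
    denom = y0 - 2 * y1 + y2
    delta = 0.5 * (y0 - y2) / denom if abs(denom) > 1e-12 else 0.0
    delta = float(np.clip(delta, -0.5, 0.5))
    return (lo + i + delta) / fs * 1000.0


def find_t_end(
    beat: AveragedBeat,
    t_peak_ms: float,
    baseline: float | None = None,
) -> float:
    """Locate the T-wave end by the tangent method (ms from start).

    The tangent at the point of steepest slope on the descending limb
    (the limb returning toward baseline after the apex) is intersected
    with the isoelectric baseline.

    Raises
    ------
    QCError
        No descending limb after the apex.
    """
    fs = beat.fs
    x = beat.waveform
    if baseline is None:
        onset, _ = _qrs_bounds(beat)
        baseline = _baseline(beat, onset)
    peak_idx = int(round(t_peak_ms / 1000.0 * fs))
    peak_idx = min(max(peak_idx, 0), len(x) - 1)
    pol = np.sign(x[peak_idx] - baseline) or 1.0
    w = pol * (x - baseline)  # polarity-corrected: apex is positive
    peak_amp = w[peak_idx]
    if peak_amp <= 0:
        raise QCError("t_end_polarity", "apex amplitude not above baseline")

    # follow the descending limb while the wave stays above 5% of the
    # apex; stops before any following deflection (next beat's QRS)
    stop = peak_idx + 1
    while stop < len(w) and w[stop] >= 0.05 * peak_amp:
        stop += 1
    if stop - peak_idx < 3:
        raise QCError("no_descending_limb", "T wave does not descend after apex")

    d = np.gradient(w[: stop + 1]) * fs  # mV per second
    seg = d[peak_idx + 1 : stop]
    steep_rel = int(np.argmin(seg))
    slope = float(seg[steep_rel])
    if slope >= 0:
        raise QCError("no_descending_limb", "no negative slope after apex")
    idx = peak_idx + 1 + steep_rel
    t_s = idx / fs
    t_end_s = t_s - float(w[idx]) / slope
    if t_end_s * 1000.0 < t_peak_ms:
        raise QCError("t_end_before_peak", "tangent crossing precedes apex")
    return t_end_s * 1000.0


def delineate_beat(
    beat: AveragedBeat, search_window: tuple[float, float] | None = None
) -> Fiducials:
    """Full delineation of one averaged beat: QRS bounds, T apex, T end."""
    onset_idx, offset_idx = _qrs_bounds(beat)
    base = _baseline(beat, onset_idx)
    t_peak_ms = find_t_peak(beat, search_window=search_window, baseline=base)
    t_end_ms = find_t_end(beat, t_peak_ms, baseline=base)
    fs = beat.fs
    return Fiducials(
        qrs_onset=onset_idx / fs * 1000.0,
        qrs_offset=offset_idx / fs * 1000.0,
        t_peak=t_peak_ms,
        t_end=t_end_ms,
    )
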