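"""PMT fluorescence pulse detection and cross-channel matching.

A labeled cell transiting the field of view produces a broad pulse on the
photomultiplier whose width equals the transit time.  Pulses are found
against a slowly varying baseline: the baseline is a rolling median (span
many transit times, so pulses barely perturb it), the noise scale is the
median absolute deviation (MAD) of the residual, and excursions above
``k_mad`` robust standard deviations that last at least ``min_width_s``
are reported as peaks.  Nearby excursions separated by less than
``merge_gap_s`` are merged, so a noisy pulse top is not split in two.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import uniform_filter1d

from .simulate import PMTTrace

__all__ = ["PeakParams", "FluorPeak", "detect_peaks", "match_channels",
           "score_positivity"]

_MAD_TO_SIGMA = 1.4826   # MAD of a Gaussian -> standard deviation


@dataclass(frozen=True)
class PeakParams:
    """Peak-detection parameters for one PMT channel."""

    expected_transit_s: float = 0.011        # ~5 frames at 450 fps
    baseline_window_s: float | None = None   # default: 50x expected transit
    k_mad: float = 5.0
    min_width_s: float | None = None         # default: expected transit / 4
    merge_gap_s: float | None = None         # default: expected transit / 2

    def __post_init__(self) -> None:
        for name in ("expected_transit_s", "k_mad"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")

    @property
    def baseline_window(self) -> float:
        return self.baseline_window_s or 50.0 * self.expected_transit_s

    @property
    def min_width(self) -> float:
        return self.min_width_s if self.min_width_s is not None \
            else self.expected_transit_s / 4.0

    @property
    def merge_gap(self) -> float:
        return self.merge_gap_s if self.merge_gap_s is not None \
            else self.expected_transit_s / 2.0


@dataclass(frozen=True)
class FluorPeak:
    """One detected fluorescence pulse."""

    channel: str
    t_center_s: float
    width_s: float             # full width at half prominence
    amplitude: float           # height above local baseline
    score: float               # amplitude / (k_mad * robust sigma)

    def __post_init__(self) -> None:
        if self.width_s <= 0 or self.amplitude <= 0:
            raise ValueError("peak width and amplitude must be > 0")


def _rolling_median(values: np.ndarray, window: int) -> np.ndarray:
    """Rolling median via block medians + linear interpolation.

    Exact rolling medians over tens of thousands of samples are O(n*w);
    block medians at ~window/4 spacing interpolate the slow baseline to
    ample accuracy for pulse detection.
    """
    n = values.size
    window = max(min(window, n), 1)
    step = max(window // 4, 1)
    centers = np.arange(0, n, step)
    meds = np.empty(centers.size)
    half = window // 2
    for i, c in enumerate(centers):
        lo, hi = max(c - half, 0), min(c + half + 1, n)
        meds[i] = np.median(values[lo:hi])
    return np.interp(np.arange(n), centers, meds)


def detect_peaks(trace: PMTTrace, params: PeakParams) -> list[FluorPeak]:
    """Detect fluorescence pulses in one channel.

    Returns peaks sorted by time.  Amplitude-shift invariant: adding a
    constant to the whole trace changes nothing.
    """
    v = np.asarray(trace.values, dtype=float)
    if v.size == 0:
        raise ValueError("empty trace")
    sr = trace.sample_rate_hz
    win = int(round(params.baseline_window * sr))
    if v.size <= win:
        baseline = np.full(v.size, np.median(v))
    else:
        baseline = _rolling_median(v, win)
    resid = v - baseline
    # light boxcar smoothing (half the minimum pulse width) so apex and
    # width estimates are not dominated by single noise samples
    smooth_n = max(int(round(params.min_width * sr / 2.0)), 1)
    if smooth_n > 1:
        resid = uniform_filter1d(resid, smooth_n)
    mad = float(np.median(np.abs(resid - np.median(resid))))
    # noise floor: in (near-)noiseless traces the MAD collapses and any
    # threshold derived from it is meaningless; floor the robust scale at
    # 0.1% of the largest excursion so clean pulses are still resolved
    rng_floor = 1e-3 * max(float(resid.max()), 0.0)
    sigma = max(_MAD_TO_SIGMA * mad, rng_floor, 1e-12)
    thresh = params.k_mad * sigma

    above = resid > thresh
    if not above.any():
        return []
    # contiguous runs of above-threshold samples
    idx = np.flatnonzero(above)
    runs: list[list[int]] = []
    run_start = idx[0]
    prev = idx[0]
    for i in idx[1:]:
        if i == prev + 1:
            prev = i
            continue
        runs.append([run_start, prev])
        run_start = prev = i
    runs.append([run_start, prev])
    # merge runs separated by < merge_gap
    gap = int(round(params.merge_gap * sr))
    merged: list[list[int]] = [runs[0]]
    for s, e in runs[1:]:
        if s - merged[-1][1] < gap:
            merged[-1][1] = e
        else:
            merged.append([s, e])

    peaks: list[FluorPeak] = []
    min_w = params.min_width
    for s, e in merged:
        if (e - s + 1) / sr < min_w:
            continue
        seg = resid[s:e + 1]
        pk = int(np.argmax(seg))
        amp = float(seg[pk])
        half = amp / 2.0
        # full width at half prominence, walking out from the apex
        lo = s + pk
        while lo > 0 and resid[lo - 1] > half:
            lo -= 1
        hi = s + pk
        while hi < resid.size - 1 and resid[hi + 1] > half:
            hi += 1
        width = (hi - lo + 1) / sr
        peaks.append(FluorPeak(
            channel=trace.channel,
            t_center_s=(s + pk) / sr,
            width_s=width,
            amplitude=amp,
            score=amp / (params.k_mad * sigma),
        ))
    peaks.sort(key=lambda p: p.t_center_s)
    return peaks


def match_channels(peaks_a: list[FluorPeak], peaks_b: list[FluorPeak],
                   tolerance_s: float) -> list[tuple[FluorPeak | None, FluorPeak | None]]:
    """Greedy one-to-one pairing of peaks across channels by |Δt|.

    The closest admissible pair is committed first; unmatched peaks from
    either channel are carried as singletons.  At the low peak densities
    of rare-cell work this agrees with globally optimal assignment.
    """
    if tolerance_s < 0:
        raise ValueError("tolerance must be >= 0")
    cands = []
    for i, a in enumerate(peaks_a):
        for j, b in enumerate(peaks_b):
            dt = abs(a.t_center_s - b.t_center_s)
            if dt <= tolerance_s:
                cands.append((dt, i, j))
    cands.sort(key=lambda t: (t[0], t[1], t[2]))
    used_a: set[int] = set()
    used_b: set[int] = set()
    pairs: list[tuple[FluorPeak | None, FluorPeak | None]] = []
    for dt, i, j in cands:
        if i in used_a or j in used_b:
            continue
        used_a.add(i)
        used_b.add(j)
        pairs.append((peaks_a[i], peaks_b[j]))
    for i, a in enumerate(peaks_a):
        if i not in used_a:
            pairs.append((a, None))
    for j, b in enumerate(peaks_b):
        if j not in used_b:
            pairs.append((None, b))
    pairs.sort(key=lambda ab: (ab[0] or ab[1]).t_center_s)
    return pairs


def score_positivity(peak: FluorPeak | None, channel: str | None = None) -> bool:
    """Marker status from a (possibly absent) matched peak.

    Positive iff a peak is present with score ≥ 1, i.e. its amplitude
    reached the detection threshold; the boundary is inclusive.
    """
    if peak is None:
        return False
    return peak.score >= 1.0
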