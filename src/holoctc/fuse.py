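"""Dual-modality fusion, CTC gating, and per-mL enumeration.

A candidate cell is counted as a CTC only by the logical conjunction of
the two modalities: its holographic confidence must exceed the operating
threshold (0.5 by default, strict) AND every required immunofluorescence
marker — PSMA alone by default — must be positive.  EpCAM status is
recorded as a phenotypic annotation but never gates, since
epithelial-to-mesenchymal transition downregulates EpCAM in a clinically
important fraction of tumor cells.  Counts are normalized to the initial
whole-blood volume.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

from .detect import Track
from .fluor import FluorPeak, score_positivity

__all__ = ["CellEvent", "SampleResult", "fuse_events", "classify_ctc",
           "enumerate_sample"]

KNOWN_MARKERS = {"PSMA", "EpCAM"}


@dataclass
class CellEvent:
    """One fused per-cell record."""

    t_s: float
    dhm_confidence: float
    psma_positive: bool | None = None   # None: channel absent / unknown
    epcam_positive: bool | None = None
    track_id: int = -1
    psma_peak: FluorPeak | None = None
    epcam_peak: FluorPeak | None = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.dhm_confidence <= 1.0):
            raise ValueError("dhm_confidence must be in [0, 1]")


@dataclass
class SampleResult:
    """Per-sample enumeration summary."""

    n_ctc: int
    whole_blood_volume_ml: float
    dhm_threshold: float
    epcam_positive_fraction: float | None = None
    n_events: int = 0
    unmatched_psma_peaks: int = 0
    unmatched_epcam_peaks: int = 0

    @property
    def ctc_per_ml(self) -> float:
        return self.n_ctc / self.whole_blood_volume_ml


def _greedy_pair(times: list[float], peaks: list[FluorPeak],
                 tolerance_s: float) -> dict[int, int]:
    """Greedy one-to-one pairing: closest (track, peak) |Δt| first."""
    cands = [(abs(p.t_center_s - t), ti, pi)
             for ti, t in enumerate(times)
             for pi, p in enumerate(peaks)
             if abs(p.t_center_s - t) <= tolerance_s]
    cands.sort(key=lambda c: (c[0], c[1], c[2]))
    used_t: set[int] = set()
    used_p: set[int] = set()
    pairing: dict[int, int] = {}
    for dt, ti, pi in cands:
        if ti in used_t or pi in used_p:
            continue
        used_t.add(ti)
        used_p.add(pi)
        pairing[ti] = pi
    return pairing


def fuse_events(tracks: Sequence[Track], psma_peaks: Sequence[FluorPeak],
                epcam_peaks: Sequence[FluorPeak], tolerance_s: float,
                ) -> tuple[list[CellEvent], list[FluorPeak]]:
    """Pair each holographic track with at most one peak per channel.

    Per channel, (track, peak) pairs are committed greedily by smallest
    mid-transit-to-pulse-center |Δt| within ``tolerance_s``; each peak is
    consumed at most once, so a spurious track fragment cannot steal the
    pulse belonging to a better-centred track.  Every track yields exactly
    one event; peaks matched to no track are returned separately as a
    spurious-fluorescence audit list.
    """
    if tolerance_s < 0:
        raise ValueError("tolerance must be >= 0")
    order = sorted(tracks, key=lambda t: t.mid_transit_time_s)
    times = [tr.mid_transit_time_s for tr in order]
    psma = sorted(psma_peaks, key=lambda p: p.t_center_s)
    epcam = sorted(epcam_peaks, key=lambda p: p.t_center_s)
    pair_p = _greedy_pair(times, psma, tolerance_s)
    pair_e = _greedy_pair(times, epcam, tolerance_s)
    events: list[CellEvent] = []
    for ti, tr in enumerate(order):
        p_peak = psma[pair_p[ti]] if ti in pair_p else None
        e_peak = epcam[pair_e[ti]] if ti in pair_e else None
        events.append(CellEvent(
            t_s=tr.mid_transit_time_s,
            dhm_confidence=tr.confidence,
            psma_positive=score_positivity(p_peak, "PSMA"),
            epcam_positive=score_positivity(e_peak, "EpCAM"),
            track_id=tr.track_id,
            psma_peak=p_peak,
            epcam_peak=e_peak,
        ))
    leftovers = [p for i, p in enumerate(psma) if i not in set(pair_p.values())] + \
                [p for i, p in enumerate(epcam) if i not in set(pair_e.values())]
    return events, leftovers


def classify_ctc(event: CellEvent, dhm_threshold: float = 0.5,
                 required_markers: frozenset[str] | set[str] = frozenset({"PSMA"}),
                 ) -> bool:
    """CTC gate: confidence strictly above threshold AND all required
    markers positive.  Unknown marker status counts as negative."""
    for m in required_markers:
        if m not in KNOWN_MARKERS:
            raise ValueError(f"unknown marker {m!r}")
    if not (event.dhm_confidence > dhm_threshold):
        return False
    status = {"PSMA": event.psma_positive, "EpCAM": event.epcam_positive}
    return all(bool(status[m]) for m in required_markers)


def enumerate_sample(events: Sequence[CellEvent], dhm_threshold: float = 0.5,
                     required_markers: frozenset[str] | set[str] = frozenset({"PSMA"}),
                     whole_blood_volume_ml: float = 10.0) -> SampleResult:
    """Count CTCs and normalize to the initial whole-blood volume.

    The EpCAM-positive fraction is computed over classified CTCs only and
    reported as None when no CTC was found.
    """
    if whole_blood_volume_ml <= 0:
        raise ValueError("whole_blood_volume_ml must be > 0")
    ctcs = [e for e in events
            if classify_ctc(e, dhm_threshold, required_markers)]
    if ctcs:
        frac = sum(1 for e in ctcs if e.epcam_positive) / len(ctcs)
    else:
        frac = None
    return SampleResult(
        n_ctc=len(ctcs),
        whole_blood_volume_ml=whole_blood_volume_ml,
        dhm_threshold=dhm_threshold,
        epcam_positive_fraction=frac,
        n_events=len(events),
    )
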