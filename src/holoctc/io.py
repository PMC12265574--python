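"""Session container I/O, run configuration, and the umbrella pipeline.

A *session* (one continuous acquisition) is stored in a single HDF5 file:
frames, the two PMT traces, and — for synthetic data — the ground truth,
all under one root, with the optical metadata as attributes.  Times are
seconds from session start; lengths are μm in metadata and pixels in
arrays.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import yaml

from .detect import Keypoint, SIGMA_UM_DEFAULT, extract_keypoints, link_tracks, predict_heatmap
from .fluor import PeakParams, detect_peaks
from .fuse import SampleResult, classify_ctc, enumerate_sample, fuse_events
from .net import HeatmapNet
from .optics import OpticalConfig
from .preprocess import BackgroundState, NormSpec, subtract_and_normalize, update_background
from .simulate import Frame, PMTTrace

__all__ = ["RunConfig", "write_session", "read_session", "run_pipeline",
           "config_hash", "export_frames_tiff", "import_frames_tiff"]

_OPTICS_FIELDS = ("wavelength_nm", "magnification", "na", "pixel_pitch_um",
                  "frame_rate_hz", "defocus_um")
_TRUTH_COLS = ["frame_index", "cell_id", "x_px", "y_px", "cell_class",
               "psma", "epcam"]


@dataclass
class RunConfig:
    """Everything one pipeline run needs, round-trippable through YAML."""

    optics: OpticalConfig = field(default_factory=OpticalConfig)
    ema_alpha: float = 0.05
    norm_mean: float = 0.0
    norm_std: float = 1.0
    detect_threshold: float = 0.5
    dhm_threshold: float = 0.5
    min_separation_um: float = 2 * SIGMA_UM_DEFAULT
    velocity_prior_um_s: float = 45_000.0
    gate_um: float = 2 * SIGMA_UM_DEFAULT
    max_gap: int = 1
    peaks: PeakParams = field(default_factory=PeakParams)
    fusion_tolerance_s: float | None = None    # default: transit / 2
    required_markers: tuple[str, ...] = ("PSMA",)
    whole_blood_volume_ml: float = 10.0
    abundance_cells_per_ml: float = 10.0
    seed: int = 0

    @property
    def fusion_tolerance(self) -> float:
        if self.fusion_tolerance_s is not None:
            return self.fusion_tolerance_s
        return self.peaks.expected_transit_s / 2.0

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["optics"]["roi_px"] = list(self.optics.roi_px)
        d["required_markers"] = list(self.required_markers)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "optics" in d:
            o = dict(d["optics"])
            o["roi_px"] = tuple(o.get("roi_px", (1440, 256)))
            d["optics"] = OpticalConfig(**o)
        if "peaks" in d:
            d["peaks"] = PeakParams(**d["peaks"])
        if "required_markers" in d:
            d["required_markers"] = tuple(d["required_markers"])
        return cls(**d)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


def config_hash(config: RunConfig) -> str:
    blob = yaml.safe_dump(config.to_dict(), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def write_session(path, frames: list[Frame], optics: OpticalConfig,
                  truth: pd.DataFrame | None = None,
                  traces: dict[str, PMTTrace] | None = None,
                  session_id: str | None = None) -> None:
    """Write one session (frames + optional truth and traces) to HDF5.

    The session id defaults to the one carried by the frames.
    """
    if session_id is None:
        session_id = frames[0].session_id if frames else "s0"
    with h5py.File(path, "w") as f:
        g = f.create_group(f"sessions/{session_id}")
        stack = np.stack([fr.pixels for fr in frames]).astype(np.float32)
        d = g.create_dataset("frames", data=stack)
        d.attrs["n_frames"] = len(frames)
        for name in _OPTICS_FIELDS:
            g.attrs[name] = getattr(optics, name)
        g.attrs["roi_px"] = list(optics.roi_px)
        g.attrs["units"] = "times: s from session start; lengths: um in metadata, px in arrays"
        if truth is not None:
            tg = g.create_group("truth")
            for col in _TRUTH_COLS:
                vals = truth[col].to_numpy()
                if vals.dtype == object:
                    vals = vals.astype("S8")
                tg.create_dataset(col, data=vals)
        if traces:
            for chan, tr in traces.items():
                td = g.create_dataset(f"traces/{chan}", data=tr.values)
                td.attrs["sample_rate_hz"] = tr.sample_rate_hz


def read_session(path) -> tuple[list[Frame], pd.DataFrame | None,
                                dict[str, PMTTrace] | None, OpticalConfig]:
    """Read a session written by :func:`write_session`.

    Frames come back ordered by frame index; absent truth or traces are
    returned as None (absent, not empty).  Inconsistent metadata raises
    with the offending field named.
    """
    with h5py.File(path, "r") as f:
        if "sessions" not in f:
            raise ValueError("not a session file: missing 'sessions' group")
        sid = sorted(f["sessions"])[0]
        g = f[f"sessions/{sid}"]
        for name in _OPTICS_FIELDS + ("roi_px",):
            if name not in g.attrs:
                raise ValueError(f"session metadata missing field {name!r}")
        optics = OpticalConfig(
            **{name: float(g.attrs[name]) for name in _OPTICS_FIELDS},
            roi_px=tuple(int(v) for v in g.attrs["roi_px"]),
        )
        stack = g["frames"][...]
        n_expected = int(g["frames"].attrs.get("n_frames", stack.shape[0]))
        if stack.shape[0] != n_expected:
            raise ValueError(
                f"truncated frame data: expected {n_expected} frames, "
                f"found {stack.shape[0]} (last good frame_index "
                f"{stack.shape[0] - 1})")
        fps = optics.frame_rate_hz
        frames = [Frame(pixels=stack[k], session_id=sid, frame_index=k,
                        time_s=k / fps) for k in range(stack.shape[0])]
        truth = None
        if "truth" in g:
            cols = {}
            for col in _TRUTH_COLS:
                v = g[f"truth/{col}"][...]
                if v.dtype.kind == "S":
                    v = v.astype(str)
                cols[col] = v
            truth = pd.DataFrame(cols)
        traces = None
        if "traces" in g:
            traces = {}
            for chan in g["traces"]:
                td = g[f"traces/{chan}"]
                traces[chan] = PMTTrace(
                    channel=chan, sample_rate_hz=float(td.attrs["sample_rate_hz"]),
                    values=td[...], session_id=sid)
        return frames, truth, traces, optics


def export_frames_tiff(path, frames: list[Frame]) -> None:
    """Export a frame stack as a multi-page TIFF (interchange format).

    HDF5 remains the canonical session container; TIFF export drops the
    traces, truth and optics metadata.
    """
    import tifffile
    stack = np.stack([fr.pixels for fr in frames]).astype(np.float32)
    tifffile.imwrite(path, stack)


def import_frames_tiff(path, optics: OpticalConfig,
                       session_id: str = "s0") -> list[Frame]:
    """Read a multi-page TIFF stack back into ordered frames."""
    import tifffile
    stack = tifffile.imread(path)
    if stack.ndim == 2:
        stack = stack[None]
    fps = optics.frame_rate_hz
    return [Frame(pixels=stack[k], session_id=session_id, frame_index=k,
                  time_s=k / fps) for k in range(stack.shape[0])]


def run_pipeline(config: RunConfig, frames: list[Frame],
                 traces: dict[str, PMTTrace] | None,
                 model: HeatmapNet,
                 out_dir: str | Path | None = None,
                 ) -> tuple[SampleResult, dict]:
    """Chain preprocessing → detection → linking → peaks → fusion → counts.

    Returns the :class:`SampleResult` and an artifacts dict (detections,
    tracks, peaks, events tables plus a log of per-stage counts).  With
    ``out_dir`` set, artifacts are also written as CSV/JSON, each stamped
    with the config hash.
    """
    optics = config.optics
    norm = NormSpec(mean=config.norm_mean, std=config.norm_std)
    state = BackgroundState(alpha=config.ema_alpha)
    detections: list[Keypoint] = []
    for fr in frames:
        if state.mean_image is None:
            state = update_background(state, fr)
            continue
        img = subtract_and_normalize(fr, state, norm)
        state = update_background(state, fr)
        hm = predict_heatmap(model, img, frame_index=fr.frame_index)
        detections.extend(extract_keypoints(
            hm, config.detect_threshold, optics, config.min_separation_um))
    tracks = link_tracks(detections, optics, config.velocity_prior_um_s,
                         config.gate_um, config.max_gap)
    psma_peaks = detect_peaks(traces["PSMA"], config.peaks) if traces and "PSMA" in traces else []
    epcam_peaks = detect_peaks(traces["EpCAM"], config.peaks) if traces and "EpCAM" in traces else []
    events, leftover_peaks = fuse_events(
        tracks, psma_peaks, epcam_peaks, config.fusion_tolerance)
    result = enumerate_sample(events, config.dhm_threshold,
                              set(config.required_markers),
                              config.whole_blood_volume_ml)

    chash = config_hash(config)
    log = {
        "config_hash": chash, "seed": config.seed,
        "n_frames": len(frames), "n_detections": len(detections),
        "n_tracks": len(tracks), "n_psma_peaks": len(psma_peaks),
        "n_epcam_peaks": len(epcam_peaks), "n_events": len(events),
        "n_unmatched_peaks": len(leftover_peaks), "n_ctc": result.n_ctc,
    }
    det_df = pd.DataFrame(
        [{"session_id": frames[0].session_id if frames else "s0",
          "frame_index": k.frame_index, "x_px": k.x_px, "y_px": k.y_px,
          "confidence": k.confidence} for k in detections])
    trk_df = pd.DataFrame(
        [{"track_id": t.track_id, "mid_transit_time_s": t.mid_transit_time_s,
          "confidence": t.confidence, "n_frames": t.n_frames}
         for t in tracks])
    peak_df = pd.DataFrame(
        [{"channel": p.channel, "t_center_s": p.t_center_s,
          "width_s": p.width_s, "amplitude": p.amplitude, "score": p.score}
         for p in psma_peaks + epcam_peaks])
    ev_df = pd.DataFrame(
        [{"t_s": e.t_s, "dhm_confidence": e.dhm_confidence,
          "psma": bool(e.psma_positive), "epcam": bool(e.epcam_positive),
          "is_ctc": classify_ctc(e, config.dhm_threshold,
                                 set(config.required_markers))}
         for e in events])
    artifacts = {"detections": det_df, "tracks": trk_df, "peaks": peak_df,
                 "events": ev_df, "log": log}
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        header = f"# config_hash: {chash}\n"
        for name in ("detections", "tracks", "peaks", "events"):
            with open(out / f"{name}.csv", "w") as fh:
                fh.write(header)
                artifacts[name].to_csv(fh, index=False)
        result_json = {
            "config_hash": chash,
            "n_ctc": result.n_ctc,
            "ctc_per_ml": result.ctc_per_ml,
            "epcam_positive_fraction": result.epcam_positive_fraction,
            "dhm_threshold": result.dhm_threshold,
            "whole_blood_volume_ml": result.whole_blood_volume_ml,
            "log": log,
        }
        (out / "result.json").write_text(
            json.dumps(result_json, sort_keys=True, indent=1))
    return result, artifacts
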