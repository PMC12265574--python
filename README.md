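# holoctc

Desk-scale toolkit for **in-flow circulating tumor cell (CTC) detection
by digital holographic microscopy (DHM) with immunofluorescence (IF)
confirmation**. It is written for people building or studying
dual-modality rare-cell instruments: a label-free in-line (Gabor)
hologram stream gives every transiting cell a morphological confidence,
two photomultiplier (PMT) channels give PSMA/EpCAM marker readouts, and
a cell is counted as a CTC only by the conjunction of the two.

CTCs are brutally rare — a millilitre of blood holds ~10⁶ white cells,
~10⁹ red cells, and often fewer than ten tumor cells — so the package
centres on the statistics and machinery that rarity forces:

- **Simulation** (`holoctc.simulate`): physically plausible in-line
  holograms by angular-spectrum propagation of phase-object cells
  (RBC/WBC/CTC-like classes), constant-velocity transits across the
  field of view, and synchronized PMT traces whose pulse width equals
  the transit time. Every downstream stage is testable without
  instrument data.
- **Detection** (`holoctc.detect`, `holoctc.net`): cells as Gaussian
  keypoints (σ = 2.8 μm) on a probability heatmap from a compact
  multi-resolution convolutional network; strict-local-maxima
  extraction; cross-frame track linking so one cell is counted once.
- **Training** (`holoctc.train`): the asymmetric cross-entropy
  L = −A·[y·log p + (1−y)·log(1−p)] with A = 0.1 for apparent false
  positives on cell-line (positive-stream) images and A = 1 otherwise —
  tolerant of pseudo-label omissions, strict on healthy blood; hard-
  sample mining (confidence-0.3 prefilter, loss-weighted session
  sampling); leakage-free 80:20 session-level splits; Adam at lr 0.01
  with 0.85/epoch decay.
- **Fluorescence** (`holoctc.fluor`): pulse detection against a rolling-
  median baseline with a MAD-scaled threshold, and cross-channel peak
  matching.
- **Fusion & enumeration** (`holoctc.fuse`): track–peak fusion, the CTC
  gate (confidence > 0.5 **and** PSMA+; EpCAM recorded but never
  gating), per-mL counts.
- **Validation statistics** (`holoctc.validate`): proximity-based
  detection matching, recovery (TPR) vs threshold, FPR per mL, and
  PPV = TPR·a / (TPR·a + FPR) at an assumed abundance a.

## Worked example

```python
import holoctc as h

# a small imaging session: 256x96 px field, 30 um defocus, 450 fps
optics = h.OpticalConfig(roi_px=(256, 96), defocus_um=30.0)
scene = h.random_scene(rate_per_s=40, duration_s=0.2, optics=optics,
                       seed=1, velocity_um_s=8000.0, noise=0.01)
frames, truth = h.simulate_session(scene, optics)
print(f"{len(frames)} frames, {truth.cell_id.nunique()} cells transited")

# PSMA channel: one broad pulse per marker-positive transit
trace = h.simulate_pmt(truth, optics,
                       h.ChannelConfig(channel="PSMA", noise_sigma=0.01),
                       duration_s=0.2)
transit = optics.fov_um[0] / 8000.0
peaks = h.detect_peaks(trace, h.PeakParams(expected_transit_s=transit))
n_psma = truth.groupby("cell_id").psma.first().sum()
print(f"{len(peaks)} PSMA pulses detected ({n_psma} marker-positive cells)")
for p in peaks[:3]:
    print(f"  t = {p.t_center_s*1e3:6.1f} ms  width = {p.width_s*1e3:.1f} ms"
          f"  score = {p.score:.1f}")

# validation statistics at the clinical operating point
fpr = h.fpr_per_ml(5, 55.0)
print(f"FPR = {fpr:.4f} /mL")
print(f"PPV at 10 cells/mL, TPR 0.6: {h.ppv(0.6, fpr, 10.0):.4f}")
```

prints

```
90 frames, 9 cells transited
1 PSMA pulses detected (1 marker-positive cells)
  t =   35.6 ms  width = 11.1 ms  score = 124.0
FPR = 0.0909 /mL
PPV at 10 cells/mL, TPR 0.6: 0.9851
```

Nine cells crossed the field in 0.2 s; exactly one was PSMA-positive
(this mixed session is mostly blood-like cells), and the detected pulse
width of 11.1 ms equals the field-of-view transit time at 8 mm/s. Five
false positives spread over 55 mL of blood is under 0.1/mL, and at a
clinically representative abundance of 10 CTCs/mL with 60% recovery the
positive predictive value is ≈0.98 — nearly every reported detection is
a real tumor cell.

Training and the full pipeline follow the same pattern; see
`holoctc.train.train_detector`, `holoctc.io.run_pipeline`, and the CLI:

```
holoctc simulate --out session.h5 --seed 1
holoctc train --data session.h5 --out model.npz
holoctc detect --model model.npz --frames session.h5 --threshold 0.5 --out det.csv
holoctc run --session session.h5 --model model.npz --out results/
```

## Layout

- `src/holoctc/` — library (`simulate`, `preprocess`, `net`, `detect`,
  `train`, `fluor`, `fuse`, `validate`, `io`, `cli`)
- `tests/` — pytest suite, including the end-to-end trained fixture
- `docs/methods.md` — the model, parameter choices, numerical details,
  and what the synthetic fixture does and does not demonstrate
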