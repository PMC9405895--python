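# rtpcflow

Real-time phase-contrast (RT-PC) MRI venous flow analysis: from
phase/magnitude image series to per-vessel flow-rate signals, respiratory and
cardiac spectral modulation indices, and nonparametric group comparisons
across breathing modes.

## The problem

Cerebral venous drainage — through the internal jugular veins (IJV) in the
neck and the superior sagittal sinus (SSS) inside the skull — is driven by
the heartbeat and modulated by breathing (the thoracic pump). Conventional
cardiac-gated cine PC-MRI averages many heartbeats into one reconstructed
cycle and cannot see respiratory effects. Real-time PC-MRI acquires a full
velocity-encoded frame every ~58.5 ms for 60 s, so a single acquisition
yields a flow-rate time series Q(t) containing both oscillations: a
high-frequency (HF) spectral peak at the breathing rate (~0.2 Hz) and a
very-high-frequency (VHF) peak at the heart rate (~1.2 Hz), with cardiac
harmonics above 2 Hz.

This package implements the complete measurement chain and quantifies how
much of the flow variance each driver explains, under three breathing
conditions: free (F), paced-normal (PN) and paced-deep (PD) breathing.

## The measurement chain

1. **Segmentation** (`rtpcflow.segmentation`) — seeded region growing on a
   magnitude frame: threshold τ = ½ · mean of the 25 brightest pixels in a
   user box, mask = 4-connected supra-threshold component containing the
   seed. A dilation ring of static tissue (the no-flow area, NFA) is placed
   around the vessel.
2. **Flow quantification** (`rtpcflow.flow`) — per-frame background phase
   offset from the NFA is subtracted inside the ROI; phase maps to velocity
   as v = VENC·φ/π; velocity-aliased pixels are unwrapped by ±2·VENC toward
   the ROI median; Q(t) [mL/s] = −mean(v)·area/100 (venous sign convention).
3. **Physio alignment** (`rtpcflow.physio`) — the 400 Hz belt and
   pulse-oximeter traces are trimmed to the acquisition window; average
   breathing/heart rates come from peak intervals.
4. **Spectral analysis** (`rtpcflow.spectral`) — 4th-order polynomial
   detrend; Hann periodogram normalized so ∫PSD df = Var(Q); HF and VHF
   peaks located (optionally guided by the measured rates); band powers
   integrated over the respiratory band [0.15, 0.35] Hz and the cardiac band
   (0.5 Hz wide, centered at the VHF peak). Indices:

   - AUC(R), AUC(C): band powers, (mL/s)²;
   - NAUC(R) = AUC(R)/Var(Q), NAUC(C) = AUC(C)/Var(Q) ∈ [0, 1];
   - respiratory-to-cardiac power ratio = AUC(R)/AUC(C) (> 1 means
     breathing modulates flow more than the heartbeat).
5. **Group statistics** (`rtpcflow.stats`) — Friedman tests over complete
   subject × mode blocks, Durbin–Conover post-hoc pairwise comparisons,
   Benjamini–Hochberg FDR adjustment, median [range] descriptives.
6. **Synthetic ground truth** (`rtpcflow.simulate`) — flow waveforms with
   known harmonic/respiratory structure, matched physio traces, and full
   image phantoms (parabolic-profile circular vessel at the acquisition
   geometry: 96×128 matrix, 0.7×0.7 mm pixels, 58.5 ms frames) with
   closed-form expected indices, so every stage is testable end to end.

`rtpcflow.pipeline.run_subject` / `run_group` orchestrate the chain; the
numbered scripts under `analysis/` drive a complete synthetic study.

## Worked example

```sh
python analysis/01_simulate_acquisitions.py   # image phantoms + physio
python analysis/02_process_acquisitions.py    # image pipeline -> results/acquisitions.csv
python analysis/03_cohort_indices.py          # 16-subject cohort -> results/cohort_indices.csv
python analysis/04_group_statistics.py        # Friedman/Conover/FDR -> results/group_stats.csv
```

Step 02 prints recovered vs generated values for each acquisition, e.g.

```
acq                Q est  Q true  NAUC(R) est   true
S01_F           4.81    5.00        0.321  0.313
S01_PD          3.36    3.50        0.637  0.645
```

— the ~4% flow underestimate is the rasterized-disk boundary (pixels whose
centres fall inside the circle carry near-zero parabolic velocities), and
the modulation indices match the generator's closed form to ~0.01.

Step 03 summarizes the cohort (paced-deep breathing doubles the respiratory
drive and lowers mean flow):

```
median NAUC(R) per breathing mode:
F     0.224
PN    0.331
PD    0.552
median respiratory/cardiac power ratio per mode:
F     0.392
PN    0.619
PD    1.490
```

Step 04 then shows the F-vs-PD contrast of NAUC(R) significant after FDR
(p ≪ 0.05), while mean flow differs between PD and the other modes but not
F vs PN — the pattern the pipeline is designed to detect.

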