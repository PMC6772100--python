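# ringmrsi

Reconstruction toolkit for **concentric-ring MR spectroscopic imaging
(MRSI)** with **hybrid through-time/through-k-space (tt/tk) GRAPPA**
parallel-imaging acceleration and **interleaved water-reference coil
combination** — plus a synthetic study generator and a quantitative
evaluation suite (pseudo-replica g-factor maps, %RMSE, residual-lipid
maps), so the whole method can be exercised and validated without scanner
data.

It is written for MR-physics and image-reconstruction researchers working
on fast spatial-spectral encoding at ultra-high field: people who want to
study how ring undersampling, GRAPPA geometry, and the quality of the
calibration data propagate into metabolite maps.

## The method

Spatial-spectral MRSI samples k-space along nested circles — `n` equidistant
rings with the first at half the Nyquist spacing, `radius_i = (i + ½)/FOV` —
re-traversing each ring every spectral dwell so that space and spectrum are
encoded simultaneously.  Scan time is proportional to the number of rings,
so rings are undersampled: the innermost five are kept (they carry the image
contrast) and only every R-th outer ring is measured, giving effective
accelerations R_eff = 32/18 = 1.78 and 32/11 = 2.91 for the full 32-ring
geometry.

Missing rings are synthesized with GRAPPA: each absent sample is a learned
linear combination of 3 × 2 neighboring measured samples across all coils.
Because shift invariance holds only locally on a non-Cartesian trajectory,
the weights are calibrated from kernel repetitions gathered **through
k-space** (a 15 × 4 segment slid around the target, 13 × 3 = 39 positions)
and **through time** (21 calibration FID points), 819 equations per target —
comfortably above the overdetermination threshold of 6 source points × 32
coils = 192.  Four- and eight-fold patterns can be reconstructed as chains
of two-fold stages.  The calibration data come from a short water-unsuppressed
reference acquired either interleaved within the parent sequence (sharing
its head position exactly) or as a standalone prescan; the same reference
provides per-voxel complex coil-combination weights
`w_c = conj(U_c) / Σ|U_c|²` that phase every combined spectrum to zero at
t = 0.

Reconstruction quality is quantified against the retrospectively fully
sampled gold standard: pseudo-replica noise propagation and the g-factor
`g = SNR_full / (SNR_PI · √R_total)`, percent RMSE of band-integrated
metabolite maps (tNAA, tCr, tCho), and lipid contamination integrated over
0.2–2.3 ppm.

See `docs/methods.md` for the full model description, parameter defaults,
and known limitations.

## Worked example

```python
import numpy as np
import ringmrsi as rm
from ringmrsi.config import preset
from ringmrsi.pipeline import (simulate_study, reconstruct_combined,
                               evaluate_reconstruction, g_factor_map)

cfg = preset("desk")                      # 32x32, 16 rings, 8 coils
study = simulate_study(cfg, seed=1)

pattern = rm.make_pattern(16, 2, 5)       # two-fold variable density
print(f"effective R = {pattern.effective_R}")

refs = {m: reconstruct_combined(study, None, m) for m in ("imusical", "static")}
for mode, ref in (("imusical", refs["imusical"]), ("moved", refs["static"])):
    recon = reconstruct_combined(study, pattern, mode)
    ev = evaluate_reconstruction(study, recon, ref)
    rmse = np.mean(list(ev["percent_rmse"].values()))
    print(f"{mode:9s} mean %RMSE = {rmse:5.2f}   "
          f"lipid/tCr in brain = {ev['lipid_mean_in_brain']:.2f}")

g = g_factor_map(study, pattern, "imusical", n_replicas=50)
mask = study.phantom.brain_mask
print(f"mean g-factor (imusical, R={pattern.effective_R}) = "
      f"{np.nanmean(g.g[mask]):.2f}")
```

prints

```
effective R = 1.6
imusical  mean %RMSE =  6.09   lipid/tCr in brain = 4.76
moved     mean %RMSE = 26.41   lipid/tCr in brain = 5.77
mean g-factor (imusical, R=1.6) = 1.03
```

Read: at the desk scale's two-fold variable-density acceleration, a
matched (interleaved) water reference reconstructs the metabolite maps to
~6% of the fully sampled reference with a mean g-factor of 1.03 — i.e.
almost no SNR penalty beyond the unavoidable √R — while calibrating from a
15°-rotated prescan quadruples the map error and raises both the g-factor
and the lipid leakage into the brain.

## Command line

The same pipeline is available as a CLI operating on self-describing HDF5
containers (every stage embeds the config and seed that produced it):

```bash
ringmrsi simulate   --preset desk --seed 1 --out study.h5
ringmrsi undersample --in study.h5 --out under.h5 --pattern 16:2:5
ringmrsi reconstruct --in under.h5 --out recon.h5 --calib imusical
ringmrsi combine     --in recon.h5 --out comb.h5
ringmrsi evaluate    --in comb.h5  --out eval.h5
ringmrsi report      --in eval.h5
```

Cartesian maps can be exported as NIfTI via
`ringmrsi.container.export_nifti`.

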