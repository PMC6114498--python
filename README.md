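# vasctree

Semi-automatic measurement and mathematical description of vascular-tree
geometry from 3-D angiographic volumes (CTA-style, values in Hounsfield
Units). The package covers the full chain from a raw volume to numbers a
morphometry study needs:

1. **Preprocessing** — volume-of-interest crop, tricubic resampling to a
   0.2 mm auxiliary grid, HU threshold segmentation (lower level in
   [100, 150] HU), and the map of minimal distance from the vessel wall
   (exact Euclidean distance transform), whose ridge encodes the vessel
   axes and local radii.
2. **Cross-sections** — a measuring plane oriented perpendicular to the
   vessel, the intensity-weighted core centroid `P_sc`, a border traced by
   `n` rays with valley detection between abutting vessels, and the
   metrics `d_min`, `d_max`, `area_PPP` and `d_avg = sqrt(4·PPP/π)`.
3. **Centerlines** — ridge crawling on the distance map `M(P)` with step
   `Δd = M(P)·f` (crawl rate `f ∈ [0.5, 1]`), a forward cone that prevents
   reversals, endpoint steering at divisions, and cumulative arc length
   `Ł_i = Σ |p_{n−1} p_n|`.
4. **Bifurcation zones** — split point `T0` where two centerlines separate
   by more than `d = 0.2 mm`, trunk/branch points `Tr_k`/`Br_k` at
   radius-scaled spacing, the division plane through the three 0-points,
   the branching angle `BA`, vessel angles `VA`, and coplanarity indices
   `CoI = 1 − ∠(VDV, DPN)/(π/2)`.
5. **Spline geometry** — degree-6 Bézier splines with C3 joints fitted to
   centerlines (C3 keeps the torsion continuous), and Frénet statistics
   `Kmax`, `Kav`, `Tav` from `κ = |r′×r″|/|r′|³`,
   `τ = ((r′×r″)·r‴)/|r′×r″|²`.

No clinical data is required: the `phantoms` module generates torus, helix
and artificial-bifurcation volumes with the sigmoid cross-profile

    HU(r) = C + C·(1/2 − 1/(1 + exp(−a(r − R))))

(C = 150 HU at the wall, slope a = 10 by default) together with analytic
ground truth, and the `validation` module reruns the three accuracy
studies (diameters, centerlines, bifurcation zones) end to end.

## Worked example

```python
import numpy as np
from vasctree import (make_bifurcation, sample_abz, extract_voi,
                      resample_tricubic, segment_threshold, distance_map,
                      track_centerline, refine_centerline, zone_from_curves,
                      analyze_zone, TrackingConfig)
from vasctree.volume_ops import largest_component

params = sample_abz(1, seed=7)[0]            # anatomy-plausible geometry
vol, truth = make_bifurcation(params)        # 0.6 mm voxel phantom

pts = np.vstack([truth.trunk_start, truth.apex,
                 truth.branch_end(0), truth.branch_end(1)])
voi = extract_voi(vol, (pts.min(0) - 5, pts.max(0) + 5))
aux = resample_tricubic(voi, 0.2)            # auxiliary resolution
mask = largest_component(segment_threshold(aux, 150.0),
                         containing=truth.apex)
dmap = distance_map(mask)

# branch take-offs reach 80 degrees: widen the crawl's forward cone
cfg = TrackingConfig(f=0.5, dA=1.2, turn_adaptive=False)
start = truth.trunk_start + truth.trunk_dir * 2
curves = [refine_centerline(dmap, track_centerline(
              dmap, start,
              truth.branch_end(i) - truth.branch_dirs[i] * 2, cfg=cfg))
          for i in range(2)]
zone = analyze_zone(zone_from_curves(*curves))
print(f"BA  measured {zone.BA:6.2f}  true {truth.ba:6.2f}")
print(f"VA1 measured {zone.VA[0]:6.2f}  true {truth.va[0]:6.2f}")
print(f"VA2 measured {zone.VA[1]:6.2f}  true {truth.va[1]:6.2f}")
```

prints

```
BA  measured 130.10  true 129.52
VA1 measured  56.54  true  56.04
VA2 measured  73.59  true  73.50
```

i.e. the branching angle and both vessel angles recovered from the
voxelized phantom agree with the construction values to a fraction of a
degree.

The same toolchain is exposed on the command line:

```sh
vasctree phantom torus --D 4 --R1 20 -o torus.nii.gz
vasctree preprocess torus.nii.gz --resample 0.2 --threshold 150 -o torus
vasctree validate zones --seed 1 --out results/
```

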