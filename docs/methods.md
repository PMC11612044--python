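# Methods

## Model

The package treats each marked vascular endpoint as the seed of a perfusion
territory and partitions the segmented parenchyma by the nearest-seed rule:
voxel `v` belongs to endpoint `e*` where

```
e* = argmin_e ‖ world(v) − position(e) ‖₂ ,
world(i, j, k) = origin + direction · (spacing ⊙ (i, j, k)) .
```

Distances are straight-line Euclidean in world millimetres, never in voxel
index units: CTA voxels are anisotropic (sub-millimetre in-plane, ~1 mm
slices) and an index-space metric would bias territories along the coarse
axis. The assignment is *unconstrained* — a shortest line between a voxel and
an endpoint may leave the organ (relevant across the horseshoe isthmus). A
parenchyma-constrained (geodesic) variant would model intrarenal anatomy more
faithfully but is a different estimator with different validation needs; it is
deliberately out of scope.

Assumptions worth stating plainly:

- Endpoints stand in for the distal arterial tree; territory boundaries are
  equidistance surfaces, not true perfusion watersheds. No intrarenal
  anastomoses or collateral flow are modelled.
- The mask is authoritative: cysts, caliceal systems, proximal vessels and
  fat are excluded upstream, and the mask is not edited here.
- Ties (a voxel exactly equidistant from two endpoints) are broken toward the
  smaller endpoint id, i.e. file order. The choice is arbitrary but
  deterministic and reader-reproducible; tie voxels are a measure-zero set
  for generic endpoint positions.

Volumes are integer voxel counts times the voxel volume from the image
header, converted to cm³; per-artery volumes are sums over that artery's
endpoints. Every foreground voxel is assigned, so territory volumes conserve
the total exactly in integer arithmetic.

## Planning quantities

- `Vol_Tot_pre`, `Vol_Tot_post` — total mask volume per scan (cm³).
- `KVLS = Vol_Tot_pre − Vol_Tot_post` — the actual loss across surgery.
  Negative values are accepted with a warning (cross-scan measurement noise).
- `PKVL = Σ volume(territory(e)) over lost endpoints e` — the prediction.
  "Lost" endpoints come either from a plan file or from exact-name matching
  of pre/post landmark sets (the scans are not registered, so matching is
  name-based; the visual criterion for "no longer visible" stays with the
  reader). The assumption embedded here is that a vanished ending takes its
  entire territory with it.
- All percentages use `Vol_Tot_pre` as the sole denominator.

PKVL is defined as the lost-territory sum rather than any subtraction of scan
totals: it must be computable from the preoperative scan alone to be useful
for planning, and the sum form is what the validation cohort's per-patient
figures are consistent with.

## Agreement statistics

Sample SD (n−1) is used everywhere. Pearson correlation takes the two-sided
p from the exact t distribution with n−2 degrees of freedom, which is
appropriate at the n = 5 cohort scale. Bland–Altman agreement is computed
over per-artery territory volumes matched by artery label between two
readers; bias = mean(a−b), limits of agreement = bias ± 1.96·SD(a−b). No
proportional-bias regression, ICC, or >2-reader generalisation is offered.

## Implementation notes

- **Two assignment routes.** `assign_territories` queries a KD-tree over
  endpoint positions; `brute_force_assign` evaluates all voxel×endpoint
  distances. The KD-tree result cannot be trusted blindly at exact ties, so
  voxels whose two nearest endpoints differ by < 1e-6 mm are re-resolved with
  the same squared-distance argmin the brute-force path uses; the two routes
  are then bit-identical, which the tests assert on random phantoms.
- **Geometry conventions.** Internal world frame is LPS mm; RAS point lists
  (the common markups dialect) are negated on read. Voxel-centre convention
  as in the formula above, 0-based indices. The markups reader accepts a
  compatible superset of the Slicer point-list schema (top-level or
  `markups[0]` object with `coordinateSystem` + `controlPoints`); the dialect
  version is not pinned.
- **Degenerate inputs.** Empty masks and endpoint-free landmark sets are
  errors; two endpoints closer than 1e-6 mm are rejected as clinically
  ambiguous; endpoints outside the mask are accepted with a warning (marked
  endings can sit at the border after partial-volume segmentation); empty
  territories are reported at volume 0, not dropped.
- **Reports.** CSV prints volumes to 1 decimal (cm³) and fractions to 3
  decimals; JSON keeps full precision. Reports carry no timestamps, so CLI
  reruns are byte-identical; a run log records tool version, configuration
  and input checksums.

## Phantom generator

`generate_phantom` builds a horseshoe-shaped binary mask — two lateral
ellipsoids joined by a midline cylinder whose radius is bisected so the
bridge holds a requested share of the volume (`isthmus_fraction`, default
0.15, the scale of central-bridge volume a typical isthmus division removes).
Defaults: 64×64×48 voxels at 0.9×0.9×1.0 mm, four arteries (a realistic mean
artery count for horseshoe kidneys), 4–7 endpoints per artery sampled
uniformly inside the mask with ≥1 mm separation and grouped by nearest
ostium; ostia sit on a simulated aortic axis anterior to the mask. Options
punch spherical "cyst" holes and place a fraction of endpoints just outside
the surface to exercise the boundary-endpoint warning path.

`simulate_postop` emulates isthmus division: foreground voxels are removed in
order of distance from the midline plane until the requested volume fraction
is gone, so the pair's KVLS equals the removed volume exactly. Endpoints
whose whole territory is removed are dropped from the postoperative landmark
set (`lost_truth`). Because Voronoi cells of medial endpoints extend
laterally, a moderate central cut usually removes *parts* of many territories
and *all* of none — reproducing the predicted-vs-actual discrepancy a real
resection shows when it crosses territory boundaries. `resect_territories`
removes whole named territories instead, the positive control where
PKVL = KVLS to machine precision.

What the phantom does **not** emulate: CT intensities and contrast phases,
pelvis/calyces, realistic vascular trees, segmentation error. Passing tests
therefore validate the geometry and accounting math — assignment, volumetry,
planning arithmetic — not anatomical realism or reader variability.

## Problem sizes and numerics

Property tests run the dual-route equivalence on 100 random phantoms (grids
16–32 voxels per axis, spacings drawn from 0.5–3 mm, up to 9 endpoints) plus
a handful of larger seeded cases (up to 64×64×48); these sizes give full
coverage of the anisotropy and tie-handling behaviour while keeping the suite
fast. Exactness claims (conservation, planted-volume recovery, PKVL = KVLS
under whole-territory resection) are integer-voxel identities and are
asserted exactly or at 1e-9 cm³; floating-point identities across different
summation orders are asserted at 1e-12. NIfTI headers store spacing at
float32, so geometry round-trips are compared at 1e-6 mm.

## Known limitations

- Nearest-endpoint territories ignore vessel topology; a territory can, in
  principle, be assigned across the isthmus to an endpoint of the other
  moiety if endpoints are sparse there.
- PKVL inherits the all-or-nothing loss assumption; partial territory loss
  and collateral revascularisation are not modelled.
- Endpoint matching across scans is by exact name; renamed landmarks surface
  as a warning plus a spurious loss, not as a fuzzy match.
- DICOM series are not read; convert to NIfTI/NRRD first.
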