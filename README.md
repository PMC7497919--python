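# vmatgeo

Plan-geometry optimization for multi-lesion cranial stereotactic
radiosurgery (SRS) delivered with volumetric modulated arc therapy (VMAT).

When several brain metastases are treated with VMAT, planners must decide
which lesions share an isocenter, where each isocenter goes, and which
collimator angle each arc should use. Done by hand this takes 20–60 minutes
per case and different planners reach different answers. `vmatgeo`
automates the three decisions and emits a machine-readable plan-geometry
report; it computes no dose — the output is the geometric scaffold a dose
optimizer builds on.

## Method

1. **Lesion grouping.** Lesions are clustered to minimize the number of
   isocenters subject to a beam's-eye-view (BEV) reach constraint. For
   n ≤ 7 lesions every set partition into k = 1, 2, 3 blocks is enumerated
   and, at the smallest feasible k, the partition minimizing the total
   SSED — Σ<sub>clusters</sub> Σ<sub>lesions</sub> ‖c<sub>i</sub> − iso‖² over lesion
   centroids — is selected. Larger cases use k-means++ on the centroids
   (best of n seeded runs, the same SSED objective), escalating k until
   every cluster is feasible.
2. **Isocenter placement.** Each cluster's isocenter starts at the centroid
   of the equally weighted lesion centroids and is then shifted until the
   projected outer boundary (POB) of the group is symmetric about it in the
   gantry-0° and gantry-270° BEVs. A group is feasible when its POB stays
   within D<sub>max</sub> = 50 mm per X side and 40 mm per Y side (HD120 MLC;
   50/50 mm for Millennium 120) at gantry 0°, 45°, 270° and 315°.
3. **Collimator angles.** For each arc, candidate collimator angles
   0–165° are scored by the MLC opening area fitted to the POB, summed over
   the gantry samples of the arc; the smallest sum wins. Because one leaf
   pair cannot close between two targets it spans ("island blocking"),
   this favours angles that align target separations with leaf travel.
   Jaws are fitted to the arc's POBs, Y-capped at ±40 mm on HD120.

See `docs/methods.md` for conventions, tolerances and limitations.

## Worked example

Two 10×10 mm targets 30 mm apart along BEV X
(`examples/03_collimator_scan.py`):

```text
aperture area at collimator   0 deg:  500.0 mm^2
aperture area at collimator  90 deg:  200.0 mm^2
optimal collimator angle: 90 deg (smallest summed MLC opening area)
```

At collimator 0° four 2.5 mm leaf pairs each span the full 50 mm
(2 × 100 mm² of target plus 300 mm² of unblockable gap); at 90° the
separation lies along leaf travel, the gap closes, and only the
2 × 100 mm² of target stays open — so 90° is optimal.

End-to-end on a synthetic six-lesion case
(`examples/02_cluster_lesions.py`):

```text
method: exhaustive, isocenters: 3, total SSED: 390.4 mm^2
  isocenter 0: ( -47.1,   49.0,   47.6) mm  lesions ['PTV_c0_l0', 'PTV_c0_l1']  SSED 57.4 mm^2
  isocenter 1: (   0.0,  -77.3,   28.2) mm  lesions ['PTV_c1_l0', 'PTV_c1_l1']  SSED 235.3 mm^2
  isocenter 2: (  30.4,   46.7,  -58.9) mm  lesions ['PTV_c2_l0', 'PTV_c2_l1']  SSED 97.7 mm^2
planted grouping recovered: True
```

Three well-separated planted pairs cannot share an isocenter within the
50/40 mm reach, so the minimum is three isocenters and the SSED-optimal
grouping is the planted one.

## Command line

```bash
vmatgeo simulate --seed 42 --out case.json
vmatgeo optimize --lesions case.json --machine HD120 --out report.json
vmatgeo optimize --rtstruct rs.dcm --select-ptvs --out report.json
vmatgeo collimator --lesions case.json --iso 0,0,0 --arc 0,181,179,CW --out scan.csv
```

Inputs are DICOM RT Structure Sets or a documented JSON lesion format;
`--select-ptvs` filters structures by a configurable PTV naming convention
(dose parsed from the name, >100 read as cGy) and optimizes each
prescription group independently. Exit codes: 0 ok, 2 infeasible input,
3 format error.

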