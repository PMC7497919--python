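"""Group lesions into the minimum number of feasible isocenters.

Runs the exhaustive set-partition search (n <= 7 lesions) under the HD120
distance criteria (50 mm X / 40 mm Y per side in the beam's-eye view) and
prints the chosen grouping, the symmetrized isocenters and the SSED
objective.
"""

from vmatgeo import SyntheticSpec, generate_case, get_machine, optimize_isocenters

# well-separated planted groups, so the minimum-isocenter solution is the
# planted one (with closer groups the optimizer may legitimately merge them)
structure_set, truth = generate_case(SyntheticSpec(
    seed=42, min_center_spacing_mm=120.0, cluster_center_box_mm=180.0,
    skull_radius_mm=120.0))
machine = get_machine("HD120")

result = optimize_isocenters(structure_set.lesions, machine.default_criteria)

print(f"method: {result.method}, isocenters: {result.n_isocenters}, "
      f"total SSED: {result.total_ssed:.1f} mm^2")
for i, cluster in enumerate(result.clusters):
    iso = cluster.isocenter
    print(f"  isocenter {i}: ({iso[0]:6.1f}, {iso[1]:6.1f}, {iso[2]:6.1f}) mm  "
          f"lesions {cluster.lesion_ids}  SSED {cluster.ssed:.1f} mm^2")
# The SSED (sum of squared distances isocenter -> lesion centroids) is the
# clustering objective; every printed cluster passed the projection distance
# check at gantry 0/45/270/315.
recovered = {frozenset(c.lesion_ids) for c in result.clusters} == {
    frozenset(lid for lid, lab in truth.labels.items() if lab == j)
    for j in range(3)}
print(f"planted grouping recovered: {recovered}")
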