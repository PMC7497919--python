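"""Generate a synthetic multi-metastasis case and save it as lesion JSON.

The generator plants cluster structure (here 3 groups of 2 lesions) inside
a cranial sphere; the printed labels are the ground truth the clustering
stage should recover.
"""

from vmatgeo import SyntheticSpec, generate_case, write_lesions_json

spec = SyntheticSpec(n_clusters=3, lesions_per_cluster=2, seed=42)
structure_set, truth = generate_case(spec)

write_lesions_json(structure_set, "case42.json")
print(f"wrote case42.json with {len(structure_set.lesions)} lesions")
for lesion in structure_set.lesions:
    c = lesion.centroid
    print(f"  {lesion.id}: centroid ({c[0]:7.1f}, {c[1]:7.1f}, {c[2]:7.1f}) mm, "
          f"planted cluster {truth.labels[lesion.id]}")
# Each lesion is a Fibonacci-lattice sphere surface; same spec+seed
# reproduces these coordinates bit for bit.
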