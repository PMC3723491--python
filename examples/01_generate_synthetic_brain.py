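"""Generate a synthetic voxelized brain with planted co-expression cliques.

Builds the default study conditions — a 10x10x10 voxel grid partitioned
into 12 main regions with two leaf subregions each, 380 exchangeable
background genes, two planted cliques localized to a cerebellar and a
thalamic leaf, and a 26-gene designated set — and writes the dataset in
tabular form.
"""

from voxcoex import SyntheticSpec, generate_synthetic_brain, write_dataset_tabular

spec = SyntheticSpec(seed=0)
dataset, atlas, designated, truth = generate_synthetic_brain(spec)

print(f"genes: {dataset.n_genes}  masked voxels: {dataset.n_voxels}")
print(f"regions: {len(atlas.region_ids)} (12 main groups, 24 leaves)")
print(f"designated set: {len(designated)} genes")
for i, (members, host) in enumerate(
    zip(truth.clique_memberships, truth.host_regions)
):
    acronym = atlas.region_row(host)["acronym"]
    print(f"planted clique {i + 1}: {len(members)} genes hosted in region "
          f"{host} ({acronym})")

write_dataset_tabular(dataset, "scratch/example_brain")
print("dataset written to scratch/example_brain.*")
# Every quantity above is ground truth the analysis scripts try to recover:
# the clique memberships, their host regions and the designated overlap.
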