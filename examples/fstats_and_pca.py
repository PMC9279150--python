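"""f-statistics and the outgroup-f3 drift PCA on a simulated tree.

Simulates (A,B) sister populations with an outgroup O, computes f-statistics
with block-jackknife errors, and builds the "PCA on 1 - f3 distances" that
places individuals by shared drift.
"""

import paleotempo as pt
from paleotempo.fstats import estimates_matrix, f3, group_freqs

cfg = pt.SimConfig(
    n_chromosomes=5, chrom_length_bp=3e6, mu=1.25e-8, rec=1e-8,
    populations=[(n, 10_000) for n in ["A", "B", "AB", "O", "ROOT"]],
    events=[pt.Split(800, ["A", "B"], "AB"), pt.Split(4000, ["AB", "O"], "ROOT")],
    sampling=[pt.SampleSpec(p, 0, 6) for p in ["A", "B", "O"]],
    seed=21,
)
sim = pt.simulate_dataset(cfg)
ds = sim.dataset
blocks = pt.assign_blocks(ds, 1e6)
freqs = group_freqs(ds)

r = f3("O", "A", "B", freqs, blocks)
print(r)  # shared drift of A and B relative to O: positive on a clean tree

# per-individual outgroup-f3 matrix -> distances -> PCA
individuals = [s for s in ds.samples.sample_id if not s.startswith("O")]
grouping = {s: [s] for s in individuals}
grouping["O"] = [s for s in ds.samples.sample_id if s.startswith("O")]
mat = pt.outgroup_f3_matrix(individuals, "O", ds, blocks, grouping=grouping)
dd = pt.f3_distance_matrix(estimates_matrix(mat))
pca = pt.pca_fit_project(dd, individuals, n_components=2)
print(pca.coords.round(4).to_string())
# PC1 separates the A and B clusters; explained[0] is its variance share.
print("explained variance shares:", pca.explained.round(3))
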