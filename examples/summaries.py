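"""Summary statistics: conditional heterozygosity, temporal FST, sexing.

Demonstrates the coverage-robust two-read heterozygosity estimator, Hudson
FST between time-stratified pools of a panmictic population, and the
X/autosome coverage sex caller with the cohort binomial test.
"""

import numpy as np
import pandas as pd

import paleotempo as pt
from paleotempo.popsum import simulate_reads

cfg = pt.SimConfig(
    n_chromosomes=6, chrom_length_bp=2e6, mu=1e-8, rec=1e-8,
    populations=[("pop0", 10_000)],
    sampling=[
        pt.SampleSpec("pop0", 0.0, 6, group="modern"),
        pt.SampleSpec("pop0", 30_000, 6, group="anc30"),
    ],
    seed=41,
)
sim = pt.simulate_dataset(cfg)
ds = sim.dataset

# conditional heterozygosity of one modern genome at its segregating sites
sample = ds.samples.sample_id[0]
reads = simulate_reads(ds, sample, mean_coverage=5, seed=42)
allowed = {(r.chrom, r.pos): {r.ref, r.alt} for r in ds.sites.itertuples()}
het = pt.conditional_het(reads, ds.sites[["chrom", "pos"]], allowed,
                         sample_id=sample, seed=43)
print(f"conditional het of {sample}: {het.het:.4f} +- {het.se:.4f} "
      f"({het.n_sites} sites)")  # expectation = half the true het fraction

# FST: two contemporaneous halves of the modern sample are undifferentiated
# (~0), while the modern vs 30-ka pair accumulates temporal drift over the
# 10,000 generations separating them even though the population is panmictic
blocks = pt.assign_blocks(ds, 1e6)
grp = ds.samples.groupby("group")["sample_id"].apply(list).to_dict()
pools = {"modernA": grp["modern"][:3], "modernB": grp["modern"][3:],
         "anc30": grp["anc30"]}
for r in pt.pairwise_fst(ds, pools, blocks, seed=44):
    print(f"FST({r.pool_a},{r.pool_b}) = {r.fst:.4f} +- {r.se:.4f}")

# molecular sexing: X/autosome coverage ratio, 50 males / 22 females
cov = pd.DataFrame({
    "sample_id": [f"w{i}" for i in range(72)],
    "x_coverage": np.r_[np.full(50, 0.52), np.full(22, 0.98)],
    "autosome_coverage": 1.0,
})
rep = pt.sex_and_ratio(cov)
print(f"males: {rep.n_male}/{rep.n_assigned} "
      f"({100 * rep.male_fraction:.0f}%; 95% CI "
      f"{100 * rep.ci_low:.0f}-{100 * rep.ci_high:.0f}%; "
      f"P = {rep.p_binomial:.2g}, binomial test)")
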