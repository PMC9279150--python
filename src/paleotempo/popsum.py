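"""Population summary statistics for mixed ancient/modern panels.

* Conditional heterozygosity: at sites ascertained heterozygous in an
  external individual, two reads are sampled and the mismatch fraction
  recorded — a coverage-robust diversity proxy (a true heterozygous site
  yields mismatching reads half the time, so the expectation is h/2).
* Pairwise FST: Hudson-type ratio-of-averages estimator. Pools mixing
  pseudohaploid and diploid genomes are haploidised consistently (one
  random allele per diploid individual) so that no within-individual
  heterozygosity enters the between/within bookkeeping.
* Molecular sexing from the X/autosome coverage ratio, with the exact
  binomial test of the cohort sex ratio against 1:1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sstats

from .genodata import MISSING, BlockAssignment, GenotypeDataset
from .fstats import jackknife_from_blocks


@dataclass
class HetResult:
    sample_id: str
    het: float
    se: float
    n_sites: int
    n_chromosomes: int


@dataclass
class FstResult:
    pool_a: str
    pool_b: str
    age_mid_a: float
    age_mid_b: float
    fst: float
    se: float
    n_sites: int


@dataclass
class SexReport:
    per_sample: pd.DataFrame  # sample_id, ratio, sex
    n_assigned: int
    n_male: int
    male_fraction: float
    ci_low: float
    ci_high: float
    p_binomial: float


# ---------------------------------------------------------------------------
# conditional heterozygosity
# ---------------------------------------------------------------------------

def conditional_het(reads_per_site: dict, ascertained: pd.DataFrame,
                    allowed_alleles: dict, sample_id: str = "",
                    seed: int = 0) -> HetResult:
    """Two-read mismatch fraction at ascertained sites.

    ``reads_per_site`` maps (chrom, pos) -> list of base calls;
    ``ascertained`` is a site table with chrom/pos; ``allowed_alleles`` maps
    (chrom, pos) -> the two alleles observed in the ascertainment
    individual (other alleles are ignored). Sites with fewer than two
    allowed reads are excluded. The SE is a delete-one-chromosome jackknife.
    """
    rng = np.random.default_rng(seed)
    per_chrom_pairs: dict = {}
    per_chrom_mismatch: dict = {}
    for _, row in ascertained.iterrows():
        key = (row["chrom"], row["pos"])
        reads = [b for b in reads_per_site.get(key, ()) if b in allowed_alleles[key]]
        if len(reads) < 2:
            continue  # "if available"
        pick = rng.choice(len(reads), size=2, replace=False)
        a, b = reads[pick[0]], reads[pick[1]]
        per_chrom_pairs[row["chrom"]] = per_chrom_pairs.get(row["chrom"], 0) + 1
        per_chrom_mismatch[row["chrom"]] = per_chrom_mismatch.get(row["chrom"], 0) + (a != b)
    chroms = sorted(per_chrom_pairs)
    if not chroms:
        raise ValueError("zero usable ascertained sites")
    sums = np.array([float(per_chrom_mismatch[c]) for c in chroms])
    counts = np.array([per_chrom_pairs[c] for c in chroms], dtype=np.int64)
    est, se, n_sites, n_blocks = jackknife_from_blocks(sums, counts)
    return HetResult(sample_id=sample_id, het=float(est), se=se,
                     n_sites=n_sites, n_chromosomes=n_blocks)


def simulate_reads(dataset: GenotypeDataset, sample_id: str,
                   mean_coverage: float, seed: int = 0) -> dict:
    """Draw error-free reads from a sample's true diploid genotypes.

    Read depth is Poisson(mean_coverage) per site; each read carries one of
    the individual's two alleles at random. Returns the
    (chrom, pos) -> [bases] mapping used by :func:`conditional_het`.
    """
    rng = np.random.default_rng(seed)
    j = dataset.sample_index(sample_id)
    calls = dataset.calls[:, j]
    out = {}
    depths = rng.poisson(mean_coverage, dataset.n_sites)
    refs = dataset.sites["ref"].to_numpy()
    alts = dataset.sites["alt"].to_numpy()
    chroms = dataset.sites["chrom"].to_numpy()
    poss = dataset.sites["pos"].to_numpy()
    for i in range(dataset.n_sites):
        if calls[i] == MISSING or depths[i] == 0:
            continue
        p_alt = calls[i] / 2.0
        n_alt = rng.binomial(depths[i], p_alt)
        out[(chroms[i], poss[i])] = [alts[i]] * int(n_alt) + [refs[i]] * int(depths[i] - n_alt)
    return out


# ---------------------------------------------------------------------------
# FST
# ---------------------------------------------------------------------------

def _haploidise(calls: np.ndarray, ploidy_mode: np.ndarray, rng) -> np.ndarray:
    """One allele per individual: diploid dosage 1 becomes a fair coin flip,
    0/2 stay; pseudohaploid calls are already single-allele."""
    out = calls.astype(np.int8).copy()
    dip = ploidy_mode == "diploid"
    hets = (out == 1) & dip[None, :]
    flips = rng.integers(0, 2, size=hets.sum()) * 2
    out[hets] = flips.astype(np.int8)
    return out


def hudson_fst_sums(p1, n1, p2, n2):
    """Per-site Hudson numerator/denominator (sample-size corrected)."""
    num = (p1 - p2) ** 2 - p1 * (1 - p1) / (n1 - 1) - p2 * (1 - p2) / (n2 - 1)
    den = p1 * (1 - p2) + p2 * (1 - p1)
    return num, den


def pairwise_fst(dataset: GenotypeDataset, pools: dict,
                 blocks: BlockAssignment | None = None,
                 mode: str = "pseudohaploid_aware",
                 max_age_gap: float | None = None,
                 seed: int = 0) -> list:
    """Hudson FST (ratio of averages) for every pool pair.

    ``pools`` maps pool name -> list of sample ids (each pool >= 2 genomes).
    In ``pseudohaploid_aware`` mode all individuals are reduced to one
    allele per site so mixed-ploidy pools are comparable (the
    pseudohaploid-data analogue of treating every genome as inbred).
    ``max_age_gap`` optionally restricts the output to pool pairs whose age
    midpoints differ by at most that many years.
    """
    rng = np.random.default_rng(seed)
    for name, ids in pools.items():
        if len(ids) < 2:
            raise ValueError(f"pool {name!r} has fewer than two genomes")
    ploidy = dataset.samples["ploidy_mode"].to_numpy()
    if mode == "pseudohaploid_aware":
        calls = _haploidise(dataset.calls, ploidy, rng)
        weights = np.ones(dataset.n_samples)
    elif mode == "diploid":
        calls = dataset.calls
        weights = np.where(ploidy == "diploid", 2.0, 1.0)
    else:
        raise ValueError(f"unknown mode {mode!r}")

    ages = dataset.samples.set_index("sample_id")["age_bp"]
    idx = {name: [dataset.sample_index(s) for s in ids] for name, ids in pools.items()}
    mids = {name: float(np.mean([ages[s] for s in ids])) for name, ids in pools.items()}

    def pool_freqs(members):
        sub = calls[:, members].astype(float)
        w = weights[members][None, :]
        ok = sub != MISSING
        n = (w * ok).sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            p = np.where(ok, sub * (w / 2.0), 0.0).sum(axis=1) / n
        return p, n

    results = []
    names = list(pools)
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            if max_age_gap is not None and abs(mids[a] - mids[b]) > max_age_gap:
                continue
            p1, n1 = pool_freqs(idx[a])
            p2, n2 = pool_freqs(idx[b])
            ok = (n1 >= 2) & (n2 >= 2)
            if not ok.any():
                raise ValueError(f"pools {a!r}/{b!r} share no site with >= 2 alleles each")
            with np.errstate(invalid="ignore", divide="ignore"):
                num, den = hudson_fst_sums(p1, n1, p2, n2)
            informative = ok & (den > 0)
            if blocks is not None:
                sb = blocks.site_block
                usable = informative & (sb >= 0)
                nsum = np.bincount(sb[usable], weights=num[usable], minlength=blocks.n_blocks)
                dsum = np.bincount(sb[usable], weights=den[usable], minlength=blocks.n_blocks)
                cnts = np.bincount(sb[usable], minlength=blocks.n_blocks)
                est = nsum.sum() / dsum.sum()
                nz = cnts > 0
                if nz.sum() >= 2:
                    theta_b = (nsum.sum() - nsum[nz]) / (dsum.sum() - dsum[nz])
                    c_b, M = cnts[nz], cnts.sum()
                    Bn = nz.sum()
                    h = M / c_b
                    theta_J = Bn * est - np.sum((1 - c_b / M) * theta_b)
                    tau = h * est - (h - 1) * theta_b
                    se = float(np.sqrt(np.sum((tau - theta_J) ** 2 / (h - 1)) / Bn))
                else:
                    se = np.nan
                n_sites = int(usable.sum())
            else:
                est = num[informative].sum() / den[informative].sum()
                se = np.nan
                n_sites = int(informative.sum())
            results.append(
                FstResult(pool_a=a, pool_b=b, age_mid_a=mids[a], age_mid_b=mids[b],
                          fst=float(est), se=se, n_sites=n_sites)
            )
    return results


# ---------------------------------------------------------------------------
# molecular sexing
# ---------------------------------------------------------------------------

def sex_and_ratio(coverages: pd.DataFrame, ratio_threshold: float = 0.75) -> SexReport:
    """Call sex from the X/autosome coverage ratio and test the cohort ratio.

    Males are hemizygous for X (expected ratio 0.5), females diploid
    (expected 1.0); the threshold sits midway. ``coverages`` needs columns
    sample_id, x_coverage, autosome_coverage. Samples without X coverage are
    left unassigned and excluded from cohort statistics. The cohort male
    fraction gets a Clopper-Pearson 95% CI and an exact two-sided binomial
    test against 0.5.
    """
    df = coverages.copy()
    if (df["autosome_coverage"] <= 0).any():
        raise ValueError("autosome coverage must be > 0")
    with np.errstate(invalid="ignore", divide="ignore"):
        df["ratio"] = df["x_coverage"] / df["autosome_coverage"]
    df["sex"] = np.where(
        df["ratio"].isna(), "unassigned",
        np.where(df["ratio"] < ratio_threshold, "male", "female"),
    )
    assigned = df[df["sex"] != "unassigned"]
    n = len(assigned)
    k = int((assigned["sex"] == "male").sum())
    if n == 0:
        raise ValueError("no sample could be assigned a sex")
    test = sstats.binomtest(k, n, 0.5)
    ci = test.proportion_ci(confidence_level=0.95, method="exact")
    return SexReport(
        per_sample=df[["sample_id", "ratio", "sex"]],
        n_assigned=n,
        n_male=k,
        male_fraction=k / n,
        ci_low=float(ci.low),
        ci_high=float(ci.high),
        p_binomial=float(test.pvalue),
    )


def binomial_sex_test(n_male: int, n_total: int) -> dict:
    """Exact two-sided binomial test of a male count against a 1:1 ratio."""
    test = sstats.binomtest(n_male, n_total, 0.5)
    ci = test.proportion_ci(confidence_level=0.95, method="exact")
    return {
        "male_fraction": n_male / n_total,
        "p": float(test.pvalue),
        "ci_low": float(ci.low),
        "ci_high": float(ci.high),
    }
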