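"""Allele-frequency tables and f-statistics with block-jackknife errors.

f-statistics are moments of allele-frequency differences measuring shared
genetic drift: f4(A,B;C,D) = E[(pA-pB)(pC-pD)] is ~0 when (A,B) and (C,D)
are separated by the tree and non-zero under gene flow; f3(A;B,C) =
E[(pA-pB)(pA-pC)] measures shared drift of B and C "through" A, with an
optional finite-sample correction for the sampling noise of pA. Standard
errors come from a delete-one-block jackknife across genomic blocks, weighted
by per-block usable-site counts (block occupancy is unequal after
filtering). Frequencies are alt-allele dosages throughout: f-statistics are
invariant to polarisation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genodata import MISSING, BlockAssignment, GenotypeDataset


@dataclass
class FreqTable:
    """Per-site per-group alt-allele frequency and observed allele count.

    Pseudohaploid individuals contribute one allele each, diploid two.
    ``p`` is NaN where a group has no calls.
    """

    groups: list
    p: np.ndarray  # n_sites x n_groups
    n: np.ndarray  # n_sites x n_groups (allele counts)
    sites: pd.DataFrame

    def gi(self, name: str) -> int:
        try:
            return self.groups.index(name)
        except ValueError:
            raise KeyError(f"unknown group {name!r}") from None

    def het(self, name: str) -> np.ndarray:
        """Unbiased per-site heterozygosity estimate p(1-p) n/(n-1)."""
        g = self.gi(name)
        n = self.n[:, g].astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            return self.p[:, g] * (1 - self.p[:, g]) * n / (n - 1)

    def restrict(self, mask: np.ndarray) -> "FreqTable":
        return FreqTable(self.groups, self.p[mask], self.n[mask], self.sites.loc[mask].reset_index(drop=True))


@dataclass
class FStatResult:
    kind: str
    pops: tuple
    estimate: float
    se: float
    z: float
    n_sites: int
    n_blocks: int

    def __repr__(self) -> str:
        pops = ",".join(self.pops)
        return (
            f"{self.kind}({pops}) = {self.estimate:.6g} +- {self.se:.3g} "
            f"(Z={self.z:.2f}, {self.n_sites} sites, {self.n_blocks} blocks)"
        )


def group_freqs(dataset: GenotypeDataset, grouping=None) -> FreqTable:
    """Compute the per-group frequency table.

    ``grouping`` may be None (use the metadata ``group`` column), a dict
    mapping group name -> list of sample ids, or the name of a metadata
    column.
    """
    samples = dataset.samples
    if grouping is None or isinstance(grouping, str):
        col = grouping or "group"
        mapping = {}
        for g, sub in samples.groupby(col, sort=False):
            mapping[g] = list(sub["sample_id"])
    else:
        mapping = grouping
    groups = list(mapping)
    S = dataset.n_sites
    p = np.full((S, len(groups)), np.nan)
    n = np.zeros((S, len(groups)), dtype=np.int64)
    ploidy = np.where(samples["ploidy_mode"].to_numpy() == "diploid", 2, 1)
    for g_idx, g in enumerate(groups):
        idx = [dataset.sample_index(s) for s in mapping[g]]
        if not idx:
            raise ValueError(f"group {g!r} is empty")
        calls = dataset.calls[:, idx].astype(float)
        w = ploidy[idx][None, :].astype(float)
        ok = calls != MISSING
        alleles = (w * ok).sum(axis=1)
        alt = np.where(ok, calls * (w / 2.0), 0.0).sum(axis=1)
        n[:, g_idx] = alleles.astype(np.int64)
        with np.errstate(invalid="ignore", divide="ignore"):
            p[:, g_idx] = np.where(alleles > 0, alt / alleles, np.nan)
    return FreqTable(groups=groups, p=p, n=n, sites=dataset.sites)


# ---------------------------------------------------------------------------
# jackknife machinery
# ---------------------------------------------------------------------------

def block_reduce(terms: np.ndarray, usable: np.ndarray, site_block: np.ndarray,
                 n_blocks: int):
    """Per-block sums and usable-site counts of a per-site statistic."""
    usable = usable & (site_block >= 0)
    t = np.where(usable, terms, 0.0)
    sums = np.bincount(site_block[usable], weights=t[usable], minlength=n_blocks)
    counts = np.bincount(site_block[usable], minlength=n_blocks)
    return sums, counts


def jackknife_from_blocks(sums: np.ndarray, counts: np.ndarray):
    """Weighted delete-one-block jackknife (Busing et al. 1999).

    Returns (estimate, se, n_sites, n_nonempty_blocks).
    """
    total, M = sums.sum(), counts.sum()
    if M == 0:
        raise ValueError("zero usable sites")
    est = total / M
    nz = counts > 0
    if nz.sum() < 2:
        return est, np.nan, int(M), int(nz.sum())
    s_b, c_b = sums[nz], counts[nz]
    B = len(s_b)
    theta_b = (total - s_b) / (M - c_b)
    h = M / c_b
    theta_J = B * est - np.sum((1 - c_b / M) * theta_b)
    tau = h * est - (h - 1) * theta_b
    var = np.sum((tau - theta_J) ** 2 / (h - 1)) / B
    return est, float(np.sqrt(var)), int(M), int(B)


def _result(kind, pops, sums, counts) -> FStatResult:
    est, se, n_sites, n_blocks = jackknife_from_blocks(sums, counts)
    z = est / se if se and np.isfinite(se) and se > 0 else np.nan
    return FStatResult(kind, tuple(pops), float(est), se, float(z), n_sites, n_blocks)


# ---------------------------------------------------------------------------
# statistics
# ---------------------------------------------------------------------------

def _site_terms_f4(freqs: FreqTable, a, b, c, d):
    p = freqs.p
    ia, ib, ic, id_ = (freqs.gi(x) for x in (a, b, c, d))
    terms = (p[:, ia] - p[:, ib]) * (p[:, ic] - p[:, id_])
    usable = np.isfinite(p[:, [ia, ib, ic, id_]]).all(axis=1)
    return terms, usable


def f4(a, b, c, d, freqs: FreqTable, blocks: BlockAssignment,
       site_mask: np.ndarray | None = None) -> FStatResult:
    """f4(A,B;C,D) = mean over usable sites of (pA-pB)(pC-pD).

    By default every site where all four groups have calls is used
    ("allsnps" semantics); pass ``site_mask`` to impose a global
    intersection or ascertainment instead.
    """
    if len({a, b, c, d}) < 4:
        raise ValueError("f4 requires four distinct groups")
    terms, usable = _site_terms_f4(freqs, a, b, c, d)
    if site_mask is not None:
        usable = usable & site_mask
    if not usable.any():
        raise ValueError("zero usable sites for f4")
    sums, counts = block_reduce(terms, usable, blocks.site_block, blocks.n_blocks)
    return _result("f4", (a, b, c, d), sums, counts)


def f3(a, b, c, freqs: FreqTable, blocks: BlockAssignment, corrected: bool = False,
       site_mask: np.ndarray | None = None) -> FStatResult:
    """f3(A;B,C) = mean of (pA-pB)(pA-pC), optionally bias-corrected.

    The correction subtracts pA(1-pA)/(nA-1) per site (the sampling noise of
    pA, which enters both factors); it requires nA >= 2 at contributing
    sites.
    """
    p, n = freqs.p, freqs.n
    ia, ib, ic = (freqs.gi(x) for x in (a, b, c))
    terms = (p[:, ia] - p[:, ib]) * (p[:, ia] - p[:, ic])
    usable = np.isfinite(p[:, [ia, ib, ic]]).all(axis=1)
    if corrected:
        usable = usable & (n[:, ia] >= 2)
        if not usable.any():
            raise ValueError(f"corrected f3 requires allele count >= 2 in {a}")
        with np.errstate(invalid="ignore", divide="ignore"):
            corr = p[:, ia] * (1 - p[:, ia]) / (n[:, ia] - 1.0)
        terms = terms - np.where(usable, corr, 0.0)
    if site_mask is not None:
        usable = usable & site_mask
    if not usable.any():
        raise ValueError("zero usable sites for f3")
    sums, counts = block_reduce(terms, usable, blocks.site_block, blocks.n_blocks)
    return _result("f3", (a, b, c), sums, counts)


def f2(a, b, freqs: FreqTable, blocks: BlockAssignment, corrected: bool = False,
       site_mask: np.ndarray | None = None) -> FStatResult:
    """f2(A,B) = mean of (pA-pB)^2, optionally with both sampling-noise terms
    subtracted."""
    p, n = freqs.p, freqs.n
    ia, ib = freqs.gi(a), freqs.gi(b)
    terms = (p[:, ia] - p[:, ib]) ** 2
    usable = np.isfinite(p[:, [ia, ib]]).all(axis=1)
    if corrected:
        usable = usable & (n[:, ia] >= 2) & (n[:, ib] >= 2)
        with np.errstate(invalid="ignore", divide="ignore"):
            corr = (
                p[:, ia] * (1 - p[:, ia]) / (n[:, ia] - 1.0)
                + p[:, ib] * (1 - p[:, ib]) / (n[:, ib] - 1.0)
            )
        terms = terms - np.where(usable, corr, 0.0)
    if site_mask is not None:
        usable = usable & site_mask
    if not usable.any():
        raise ValueError("zero usable sites for f2")
    sums, counts = block_reduce(terms, usable, blocks.site_block, blocks.n_blocks)
    return _result("f2", (a, b), sums, counts)


def heterozygous_site_mask(dataset: GenotypeDataset, sample_id: str) -> np.ndarray:
    """Sites where the (diploid) ascertainment individual is heterozygous."""
    j = dataset.sample_index(sample_id)
    if dataset.samples.loc[j, "ploidy_mode"] != "diploid":
        raise ValueError(f"ascertainment individual {sample_id!r} is not diploid")
    mask = dataset.calls[:, j] == 1
    if not mask.any():
        raise ValueError(f"{sample_id!r} is heterozygous nowhere; cannot ascertain")
    return mask


def outgroup_f3_matrix(
    targets: list,
    outgroup: str,
    dataset: GenotypeDataset,
    blocks: BlockAssignment,
    ascertainment_individual: str | None = None,
    grouping=None,
) -> pd.DataFrame:
    """Symmetric matrix of outgroup-f3 shared-drift statistics.

    Sites are optionally restricted to those heterozygous in an
    ascertainment individual (an outgroup-polymorphism ascertainment that
    makes the statistic comparable across coverages). Entries are
    :class:`FStatResult`; the diagonal holds f3(O; X, X) = f2-based
    self-affinity.
    """
    mask = (
        heterozygous_site_mask(dataset, ascertainment_individual)
        if ascertainment_individual
        else None
    )
    freqs = group_freqs(dataset, grouping)
    out = pd.DataFrame(index=targets, columns=targets, dtype=object)
    for i, x in enumerate(targets):
        for y in targets[i:]:
            if x == y:
                r = f3_self(outgroup, x, freqs, blocks, site_mask=mask)
            else:
                r = f3(outgroup, x, y, freqs, blocks, site_mask=mask)
            out.loc[x, y] = r
            out.loc[y, x] = r
    return out


def f3_self(a, b, freqs: FreqTable, blocks: BlockAssignment,
            site_mask: np.ndarray | None = None) -> FStatResult:
    """f3(A;B,B): the B=C collapse, equal to f2(A,B) uncorrected."""
    p = freqs.p
    ia, ib = freqs.gi(a), freqs.gi(b)
    terms = (p[:, ia] - p[:, ib]) ** 2
    usable = np.isfinite(p[:, [ia, ib]]).all(axis=1)
    if site_mask is not None:
        usable = usable & site_mask
    if not usable.any():
        raise ValueError("zero usable sites")
    sums, counts = block_reduce(terms, usable, blocks.site_block, blocks.n_blocks)
    return _result("f3", (a, b, b), sums, counts)


def estimates_matrix(results: pd.DataFrame) -> pd.DataFrame:
    """Extract the point-estimate matrix from a matrix of FStatResult."""
    return results.map(lambda r: r.estimate).astype(float)


# ---------------------------------------------------------------------------
# joint block statistics (for qpWave/qpAdm covariance)
# ---------------------------------------------------------------------------

def f4_block_table(stat_list, freqs: FreqTable, blocks: BlockAssignment,
                   site_mask: np.ndarray | None = None):
    """Per-block sums/counts for a list of f4 definitions (tuples A,B,C,D).

    Returns (estimates, block_sums, block_counts) with one row per statistic;
    each statistic uses its own usable sites ("allsnps") unless a global
    ``site_mask`` is provided.
    """
    K, B = len(stat_list), blocks.n_blocks
    sums = np.zeros((K, B))
    counts = np.zeros((K, B), dtype=np.int64)
    for k, (a, b, c, d) in enumerate(stat_list):
        terms, usable = _site_terms_f4(freqs, a, b, c, d)
        if site_mask is not None:
            usable = usable & site_mask
        if not usable.any():
            raise ValueError(f"zero usable sites for f4{(a, b, c, d)}")
        sums[k], counts[k] = block_reduce(
            terms, usable, blocks.site_block, blocks.n_blocks
        )
    est = sums.sum(axis=1) / counts.sum(axis=1)
    return est, sums, counts


def jackknife_cov(sums: np.ndarray, counts: np.ndarray) -> np.ndarray:
    """Delete-one-block jackknife covariance of a vector of block statistics.

    Blocks empty for every statistic are dropped; the classic unweighted
    delete-one formula is used (cross-weighting between statistics with
    different block occupancy has no standard weighted form).
    """
    nz = counts.sum(axis=0) > 0
    s, c = sums[:, nz], counts[:, nz]
    total, M = sums.sum(axis=1), counts.sum(axis=1)
    B = s.shape[1]
    with np.errstate(invalid="ignore", divide="ignore"):
        theta_b = (total[:, None] - s) / (M[:, None] - c)
    theta_b = np.where(np.isfinite(theta_b), theta_b, (total / M)[:, None])
    dev = theta_b - theta_b.mean(axis=1, keepdims=True)
    return (B - 1) / B * dev @ dev.T
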