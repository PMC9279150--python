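"""Temporal selection scan on a time-stamped genotype matrix.

Each variant is tested for an association between genotype and sample age by
ordinary least squares with the sample's age (years BP, modern = 0) as the
response and allele dosage as the predictor — the time-series analogue of a
GWAS in which age is the phenotype. Because neutral genetic drift alone
produces temporal allele-frequency change, the per-site chi-square (squared
t-statistic) is inflated genome-wide; genomic control divides every
chi-square by the inflation factor lambda = median(chi2)/0.4549 before
P-values are taken from the 1-dof chi-square upper tail. Candidate sites are
then filtered on ancient call counts, ancient minor-allele frequency and a
neighbourhood criterion requiring coherent evidence across nearby sites, and
merged into candidate regions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sstats

from .genodata import MISSING, GenotypeDataset

#: median of the 1-dof chi-square distribution
CHI2_1_MEDIAN = float(sstats.chi2.ppf(0.5, 1))

REASON_OK = "ok"
REASON_LOW_CALLS = "low_calls"
REASON_LOW_MAF = "low_maf"
REASON_NEIGHBOURHOOD = "neighbourhood_fail"
REASON_MONOMORPHIC = "monomorphic"


@dataclass
class GCResult:
    lam: float
    median_raw_chi2: float


def site_regression(dataset: GenotypeDataset, ages: np.ndarray | None = None,
                    chunk: int = 200_000) -> pd.DataFrame:
    """Per-site OLS of age (response) on dosage (predictor).

    Returns a DataFrame with chrom, pos, n_calls, n_ancient_calls,
    maf_ancient, beta, t, chi2, p_raw and a reason column (monomorphic sites
    are skipped with reason recorded). The two-sided P comes from the
    t-distribution with n-2 dof; chi2 is the squared t-statistic (1-dof
    large-sample equivalence, as genomic control presumes).
    """
    if ages is None:
        ages = dataset.samples["age_bp"].to_numpy(dtype=float)
    ages = np.asarray(ages, dtype=float)
    if np.ptp(ages) == 0:
        raise ValueError("all sample ages identical; design is degenerate")
    ancient = dataset.samples["is_ancient"].to_numpy()
    S = dataset.n_sites
    out = {
        k: np.full(S, np.nan)
        for k in ("beta", "t", "chi2", "p_raw", "maf_ancient")
    }
    n_calls = np.zeros(S, dtype=np.int64)
    n_anc = np.zeros(S, dtype=np.int64)
    for lo in range(0, S, chunk):
        hi = min(S, lo + chunk)
        x = dataset.calls[lo:hi].astype(np.float64)
        m = x != MISSING
        x[~m] = 0.0
        n = m.sum(axis=1)
        sx = x.sum(axis=1)
        st = (m * ages).sum(axis=1)
        sxx = (x * x).sum(axis=1)
        stt = (m * ages**2).sum(axis=1)
        sxt = (x * ages).sum(axis=1)
        vx = n * sxx - sx**2
        vt = n * stt - st**2
        cxt = n * sxt - sx * st
        ok = (n >= 3) & (vx > 0) & (vt > 0)
        with np.errstate(invalid="ignore", divide="ignore"):
            beta = cxt / vx
            r2 = cxt**2 / (vx * vt)
            r2 = np.clip(r2, 0.0, 1.0)
            tstat = np.sign(cxt) * np.sqrt(
                np.where(r2 < 1, r2 * (n - 2) / (1 - r2), np.inf)
            )
        out["beta"][lo:hi] = np.where(ok, beta, np.nan)
        out["t"][lo:hi] = np.where(ok, tstat, np.nan)
        out["chi2"][lo:hi] = np.where(ok, tstat**2, np.nan)
        pr = 2.0 * sstats.t.sf(np.abs(tstat), np.maximum(n - 2, 1))
        out["p_raw"][lo:hi] = np.where(ok, pr, np.nan)
        n_calls[lo:hi] = n
        ma = m[:, ancient]
        xa = x[:, ancient]
        n_anc[lo:hi] = ma.sum(axis=1)
        # ancient alt-allele frequency from dosages (pseudohaploid-safe)
        with np.errstate(invalid="ignore", divide="ignore"):
            pa = xa.sum(axis=1) / (2.0 * ma.sum(axis=1))
        out["maf_ancient"][lo:hi] = np.minimum(pa, 1 - pa)
    sites = dataset.sites[["chrom", "pos"]].copy()
    sites["n_calls"] = n_calls
    sites["n_ancient_calls"] = n_anc
    for k, v in out.items():
        sites[k] = v
    sites["reason"] = np.where(np.isfinite(sites["chi2"]), REASON_OK, REASON_MONOMORPHIC)
    return sites


def genomic_control(sites: pd.DataFrame, clip: bool = False,
                    min_sites: int = 100):
    """Divide chi-squares by lambda = median(chi2)/0.4549 and recompute P.

    ``clip`` floors lambda at 1 (common practice); by default deflation is
    retained so that calibration experiments see the raw value.
    """
    chi2 = sites["chi2"].to_numpy()
    ok = np.isfinite(chi2)
    if ok.sum() < min_sites:
        raise ValueError(f"genomic control needs >= {min_sites} sites with chi2")
    med = float(np.median(chi2[ok]))
    lam = med / CHI2_1_MEDIAN
    if clip:
        lam = max(lam, 1.0)
    adj = chi2 / lam
    out = sites.copy()
    out["chi2_gc"] = adj
    out["p_gc"] = sstats.chi2.sf(adj, 1)
    return GCResult(lam=lam, median_raw_chi2=med), out


def scan_filters(sites: pd.DataFrame, min_ancient_calls: int = 40,
                 min_maf_ancient: float = 0.05) -> pd.DataFrame:
    """Apply the ancient-call-count and ancient-MAF thresholds (inclusive)."""
    out = sites.copy()
    reason = out["reason"].to_numpy(dtype=object)
    ok = reason == REASON_OK
    low_calls = ok & (out["n_ancient_calls"].to_numpy() < min_ancient_calls)
    reason[low_calls] = REASON_LOW_CALLS
    maf = out["maf_ancient"].to_numpy()
    low_maf = (reason == REASON_OK) & ~(maf >= min_maf_ancient)
    reason[low_maf] = REASON_LOW_MAF
    out["reason"] = reason
    return out


def neighbourhood_filter(sites: pd.DataFrame, window_bp: int = 50_000,
                         min_neighbours: int = 7, frac: float = 0.9,
                         p_column: str = "p_gc", centered: bool = True,
                         candidates: np.ndarray | None = None) -> pd.DataFrame:
    """Require coherent evidence from nearby sites.

    A site is retained iff at least ``min_neighbours`` other sites within
    the window have -log10(P) >= ``frac`` * -log10(P_site). ``centered``
    reads "within a window" as +-window/2 around the focal site (an
    alternative +-window mode is available). Only sites currently flagged
    ``ok`` count as neighbours and are assessed; ``candidates`` (boolean
    mask) restricts which sites are assessed — retention of other sites is
    then left untouched — without changing any verdict.
    """
    out = sites.copy()
    reason = out["reason"].to_numpy(dtype=object)
    ok = reason == REASON_OK
    half = window_bp / 2 if centered else float(window_bp)
    pvals = out[p_column].to_numpy()
    assess = ok if candidates is None else (ok & np.asarray(candidates))
    with np.errstate(divide="ignore"):
        logp = -np.log10(pvals)
    for chrom, idx in out.groupby("chrom", sort=False).indices.items():
        idx = np.asarray(idx)
        sub_ok = ok[idx]
        pool = idx[sub_ok]  # neighbour pool: ok sites on this chromosome
        pos = out["pos"].to_numpy()[pool].astype(float)
        lp = logp[pool]
        targets = idx[assess[idx]]
        tpos = out["pos"].to_numpy()[targets].astype(float)
        lo = np.searchsorted(pos, tpos - half, side="left")
        hi = np.searchsorted(pos, tpos + half, side="right")
        for k, t in enumerate(targets):
            seg = lp[lo[k]:hi[k]]
            need = frac * logp[t]
            count = int((seg >= need).sum())
            # the focal site itself is in the pool and always qualifies
            if pool[lo[k]:hi[k]].size and (pool[lo[k]:hi[k]] == t).any():
                count -= 1
            if count < min_neighbours:
                reason[t] = REASON_NEIGHBOURHOOD
    out["reason"] = reason
    return out


def call_regions(sites: pd.DataFrame, alpha: float = 5e-8,
                 merge_bp: int = 50_000, p_column: str = "p_gc") -> pd.DataFrame:
    """Merge significant retained sites into regions; drop single-site ones.

    Significant = retained (reason ok) and P < alpha. Sites within
    ``merge_bp`` on one chromosome join a region; regions with a single
    significant variant are excluded.
    """
    sig = sites[(sites["reason"] == REASON_OK) & (sites[p_column] < alpha)]
    rows = []
    for chrom, grp in sig.groupby("chrom", sort=False):
        pos = grp["pos"].to_numpy()
        pv = grp[p_column].to_numpy()
        order = np.argsort(pos)
        pos, pv = pos[order], pv[order]
        start = 0
        for i in range(1, len(pos) + 1):
            if i == len(pos) or pos[i] - pos[i - 1] > merge_bp:
                if i - start >= 2:  # single-variant regions are dropped
                    lead = start + int(np.argmin(pv[start:i]))
                    rows.append(
                        {
                            "chrom": chrom,
                            "start": int(pos[start]),
                            "end": int(pos[i - 1]),
                            "n_sites": i - start,
                            "lead_pos": int(pos[lead]),
                            "lead_p": float(pv[lead]),
                        }
                    )
                start = i
    cols = ["chrom", "start", "end", "n_sites", "lead_pos", "lead_p"]
    return pd.DataFrame(rows, columns=cols).sort_values(
        ["chrom", "start"], ignore_index=True
    )


def run_scan(dataset: GenotypeDataset, *, alpha: float = 5e-8,
             min_ancient_calls: int = 40, min_maf_ancient: float = 0.05,
             window_bp: int = 50_000, min_neighbours: int = 7,
             frac: float = 0.9, merge_bp: int = 50_000,
             neighbourhood_all_sites: bool = False, clip_lambda: bool = False):
    """The full scan: regression, genomic control, filters, region calling.

    By default the (quadratic) neighbourhood filter is evaluated only for
    sites that could enter a region (P below alpha), which leaves the region
    list identical to the all-sites evaluation; set
    ``neighbourhood_all_sites`` for complete per-site retention flags.
    Returns (GCResult, per-site table, region table).
    """
    sites = site_regression(dataset)
    gc, sites = genomic_control(sites, clip=clip_lambda)
    sites = scan_filters(
        sites, min_ancient_calls=min_ancient_calls,
        min_maf_ancient=min_maf_ancient,
    )
    candidates = None
    if not neighbourhood_all_sites:
        candidates = (sites["p_gc"].to_numpy() < alpha)
    sites = neighbourhood_filter(
        sites, window_bp=window_bp, min_neighbours=min_neighbours, frac=frac,
        candidates=candidates,
    )
    regions = call_regions(sites, alpha=alpha, merge_bp=merge_bp)
    return gc, sites, regions


def calibrate_neutral(sim, **scan_kwargs):
    """Run the full scan on a neutral simulation and report calibration.

    Requires a truth record without sweeps; returns a dict with lambda, the
    number of significant regions, and QQ data (sorted adjusted P against
    uniform quantiles).
    """
    from .simdata import SimDataset

    if isinstance(sim, SimDataset):
        if sim.truth.get("sweep"):
            raise ValueError("dataset contains an injected sweep; not a neutral calibration")
        dataset = sim.dataset
    else:
        dataset = sim
    gc, sites, regions = run_scan(dataset, **scan_kwargs)
    pv = np.sort(sites["p_gc"].to_numpy())
    pv = pv[np.isfinite(pv)]
    qq = pd.DataFrame(
        {"expected": (np.arange(1, len(pv) + 1) - 0.5) / len(pv), "observed": pv}
    )
    return {
        "lambda": gc.lam,
        "n_regions": len(regions),
        "regions": regions,
        "sites": sites,
        "qq": qq,
    }
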