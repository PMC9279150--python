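"""qpWave rank tests and qpAdm admixture-weight estimation.

The machinery asks how many independent "streams" of ancestry relate a set of
*left* populations to a set of *right* (reference) populations. The
(|L|-1) x (|R|-1) matrix X of f4-statistics f4(l0, li; r0, rj) has rank at
most r when the left set traces back to r+1 ancestry streams; the test
minimises the quadratic form (X - Xhat)' Omega^-1 (X - Xhat) over rank-r
matrices Xhat, with Omega the block-jackknife covariance of the f4 vector,
and refers the minimum to a chi-square with (|L|-1-r)(|R|-1-r) degrees of
freedom.

qpAdm models a target T as a mixture of n sources with weights summing to 1.
Because f4 is linear in the target's allele frequency, the target's
f4-profile against the rights must be the same mixture of the sources'
profiles; weights are estimated by generalised least squares under the
sum-to-one constraint (which also cancels the sampling-noise bias of the
shared right-basis population), and their standard errors come from a
delete-one-block jackknife of the whole fit. The model's P-value is the
qpWave rank test at r = n-1 on left = {T, sources}.

The rotating model search enumerates all 1..max_sources source subsets of a
candidate set; candidates unused as sources form the right set, so every
candidate is always either a source or a reference.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sstats

from .fstats import FreqTable, f4_block_table, jackknife_cov
from .genodata import BlockAssignment

_COND_LIMIT = 1e12


@dataclass
class AdmixtureModel:
    target: str
    sources: tuple
    right: tuple
    p_value: float
    weights: np.ndarray
    weight_se: np.ndarray
    status: str  # pass | fail_p | fail_bounds
    n_sites: int
    n_blocks: int
    regularised: bool = False

    def __repr__(self) -> str:
        w = ", ".join(
            f"{s}={wi:.3f}+-{se:.3f}"
            for s, wi, se in zip(self.sources, self.weights, self.weight_se)
        )
        return (
            f"qpAdm[{self.target} ~ {w}; P={self.p_value:.3g}; {self.status}]"
        )


@dataclass
class ModelSearchReport:
    target: str
    candidate_set: tuple
    models: list = field(default_factory=list)  # ranked AdmixtureModel list
    winner: AdmixtureModel | None = None


def _regularise(omega: np.ndarray):
    """Add lambda*I when the covariance is near-singular (small right sets on
    reduced genomes); returns (matrix, flagged)."""
    cond = np.linalg.cond(omega)
    if not np.isfinite(cond) or cond > _COND_LIMIT:
        lam = 1e-5 * np.trace(omega) / omega.shape[0]
        return omega + lam * np.eye(omega.shape[0]), True
    return omega, False


def _rank_quadratic(x: np.ndarray, omega_inv: np.ndarray, L1: int, R1: int,
                    r: int) -> float:
    """Minimise (x - vec(AB'))' W (x - vec(AB')) over rank-r AB' by
    alternating generalised least squares; x is the row-major vec of X."""
    if r == 0:
        return float(x @ omega_inv @ x)
    X = x.reshape(L1, R1)
    U, s, Vt = np.linalg.svd(X, full_matrices=False)
    A = U[:, :r] * np.sqrt(s[:r])
    B = (Vt[:r, :].T) * np.sqrt(s[:r])

    def q_of(A, B):
        res = x - (A @ B.T).reshape(-1)
        return float(res @ omega_inv @ res)

    q_prev = q_of(A, B)
    for _ in range(200):
        # solve for A given B: design (I_L1 kron B)
        M = np.kron(np.eye(L1), B)
        MtW = M.T @ omega_inv
        A = np.linalg.solve(MtW @ M, MtW @ x).reshape(L1, r)
        # solve for B given A: rows of design are (I_R1 kron A_i)
        M = np.vstack([np.kron(np.eye(R1), A[i][None, :]) for i in range(L1)])
        MtW = M.T @ omega_inv
        B = np.linalg.solve(MtW @ M, MtW @ x).reshape(R1, r)
        q = q_of(A, B)
        if q_prev - q < 1e-10 * (1 + abs(q)):
            q_prev = q
            break
        q_prev = q
    return q_prev


def qpwave_rank_p(left, right, freqs: FreqTable, blocks: BlockAssignment,
                  rank: int = 0, site_mask=None, f_correction: bool = True):
    """P-value for 'the left set descends from <= rank+1 ancestry streams'.

    Returns (p_value, details dict). With ``f_correction`` (default) the
    minimised quadratic form q is referred to an F distribution,
    q (B - dof) / (dof (B - 1)) ~ F(dof, B - dof) with B the number of
    jackknife blocks — the Hotelling-type finite-sample reference for a
    covariance estimated from B block pseudo-replicates. It converges to
    the chi-square reference as B grows (at the genome-wide 225-block scale
    the two are nearly identical) but stays calibrated on reduced genomes
    with few blocks; pass ``f_correction=False`` for the plain chi-square
    convention.
    """
    left, right = list(left), list(right)
    if len(left) < 2:
        raise ValueError("need at least two left populations")
    if len(right) < len(left):
        raise ValueError("need |right| >= |left|")
    L1, R1 = len(left) - 1, len(right) - 1
    dof = (L1 - rank) * (R1 - rank)
    if dof <= 0:
        raise ValueError(f"rank {rank} leaves no degrees of freedom")
    stat_list = [
        (left[0], li, right[0], rj) for li in left[1:] for rj in right[1:]
    ]
    est, sums, counts = f4_block_table(stat_list, freqs, blocks, site_mask)
    omega = jackknife_cov(sums, counts)
    omega, flagged = _regularise(omega)
    q = _rank_quadratic(est, np.linalg.inv(omega), L1, R1, rank)
    B = int((counts.sum(axis=0) > 0).sum())
    if f_correction and B > dof + 1:
        p = float(sstats.f.sf(q * (B - dof) / (dof * (B - 1)), dof, B - dof))
    else:
        p = float(sstats.chi2.sf(q, dof))
    details = {
        "chi2": q,
        "dof": dof,
        "n_sites": int(counts.sum(axis=1).mean()),
        "n_blocks": int((counts.sum(axis=0) > 0).sum()),
        "regularised": flagged,
    }
    return p, details


# ---------------------------------------------------------------------------
# weight estimation
# ---------------------------------------------------------------------------

def qpadm_fit(target, sources, right, freqs: FreqTable, blocks: BlockAssignment,
              p_threshold: float = 0.01, site_mask=None) -> AdmixtureModel:
    """Fit the n-source qpAdm model for ``target``."""
    sources, right = list(sources), list(right)
    if not 1 <= len(sources) <= 3:
        raise ValueError("qpAdm supports 1-3 sources")
    pops = [target] + sources + right
    if len(set(pops)) != len(pops):
        raise ValueError("target, sources and right must be disjoint (population reuse)")
    p_value, details = qpwave_rank_p(
        [target] + sources, right, freqs, blocks, rank=len(sources) - 1,
        site_mask=site_mask,
    )
    if len(sources) == 1:
        w = np.array([1.0])
        se = np.array([0.0])
    else:
        w, se, details_w = _estimate_weights(
            target, sources, right, freqs, blocks, site_mask
        )
        details["n_sites"] = details_w["n_sites"]
    if np.any(w > 1.1) or np.any(w < -0.1):
        status = "fail_bounds"
    elif p_value < p_threshold:
        status = "fail_p"
    else:
        status = "pass"
    return AdmixtureModel(
        target=target,
        sources=tuple(sources),
        right=tuple(right),
        p_value=p_value,
        weights=w,
        weight_se=se,
        status=status,
        n_sites=details["n_sites"],
        n_blocks=details["n_blocks"],
        regularised=details["regularised"],
    )


def _estimate_weights(target, sources, right, freqs, blocks, site_mask=None):
    p = freqs.p
    it = freqs.gi(target)
    isrc = [freqs.gi(s) for s in sources]
    ir0 = freqs.gi(right[0])
    irj = [freqs.gi(r) for r in right[1:]]
    R1, n_src = len(irj), len(sources)
    B = blocks.n_blocks

    # per-j block sums for target and each source: stat rows ordered
    # [y_1..y_R1, A_1,1..A_1,R1, ..., A_n,1..A_n,R1]
    lefts = [it] + isrc
    sums = np.zeros((len(lefts), R1, B))
    counts = np.zeros((R1, B), dtype=np.int64)
    for j, ij in enumerate(irj):
        cols = lefts + [ir0, ij]
        usable = np.isfinite(p[:, cols]).all(axis=1)
        if site_mask is not None:
            usable = usable & site_mask
        usable = usable & (blocks.site_block >= 0)
        if not usable.any():
            raise ValueError(f"zero usable sites for right pair ({right[0]},{right[j+1]})")
        sb = blocks.site_block[usable]
        rfac = p[usable, ij] - p[usable, ir0]
        counts[j] = np.bincount(sb, minlength=B)
        for li, il in enumerate(lefts):
            term = (p[usable, il] - p[usable, ir0]) * rfac
            sums[li, j] = np.bincount(sb, weights=term, minlength=B)

    cnt_tot = counts.sum(axis=1)

    def stats_from(mask_blocks=None):
        if mask_blocks is None:
            s, c = sums.sum(axis=2), cnt_tot
        else:
            s = sums[:, :, mask_blocks].sum(axis=2)
            c = counts[:, mask_blocks].sum(axis=1)
        vals = s / c[None, :]
        return vals[0], vals[1:]  # y (R1,), A (n_src, R1)

    y, A = stats_from()

    def solve(y, A, W):
        # w_n = 1 - sum(w_free); GLS on the reduced system
        y_adj = y - A[-1]
        D = (A[:-1] - A[-1][None, :]).T  # R1 x (n_src-1)
        DtW = D.T @ W
        w_free = np.linalg.solve(DtW @ D, DtW @ y_adj)
        return np.concatenate([w_free, [1.0 - w_free.sum()]])

    # iterate: start with identity weighting, then re-weight with the
    # jackknife covariance of the residual statistic at the current weights
    W = np.eye(R1)
    w = solve(y, A, W)
    for _ in range(2):
        res_sums = sums[0] - np.tensordot(w, sums[1:], axes=(0, 0))
        omega = jackknife_cov(res_sums, counts)
        omega, _flag = _regularise(omega)
        W = np.linalg.inv(omega)
        w = solve(y, A, W)

    # delete-one-block jackknife of the whole fit (fixed weighting matrix)
    keep_blocks = np.flatnonzero(counts.sum(axis=0) > 0)
    w_b = []
    m_b = []
    all_blocks = np.ones(B, dtype=bool)
    for b in keep_blocks:
        mask = all_blocks.copy()
        mask[b] = False
        yb, Ab = stats_from(mask)
        w_b.append(solve(yb, Ab, W))
        m_b.append(counts[:, b].sum())
    w_b = np.array(w_b)
    m_b = np.array(m_b, dtype=float)
    M = m_b.sum()
    nB = len(w_b)
    h = M / m_b
    theta_J = nB * w - ((1 - m_b / M)[:, None] * w_b).sum(axis=0)
    tau = h[:, None] * w[None, :] - (h - 1)[:, None] * w_b
    var = ((tau - theta_J[None, :]) ** 2 / (h - 1)[:, None]).sum(axis=0) / nB
    se = np.sqrt(var)
    details = {"n_sites": int(cnt_tot.mean())}
    return w, se, details


# ---------------------------------------------------------------------------
# rotating model search
# ---------------------------------------------------------------------------

def rotate_models(target, candidate_set, freqs: FreqTable,
                  blocks: BlockAssignment, max_sources: int = 3,
                  p_threshold: float = 0.01, site_mask=None) -> ModelSearchReport:
    """Enumerate all 1..max_sources source models from ``candidate_set``.

    Candidates unused as sources become the right set of each model. Models
    are ranked by parsimony first (any simpler model with P > threshold
    outranks every more complex one), then by P descending; equal P ties
    break on lexicographic source labels. Out-of-bounds-weight models are
    failed regardless of P.
    """
    candidates = sorted(candidate_set)
    if len(candidates) < max_sources + 2:
        raise ValueError("candidate set too small for the requested model sizes")
    models = []
    for k in range(1, max_sources + 1):
        for srcs in itertools.combinations(candidates, k):
            rights = tuple(c for c in candidates if c not in srcs)
            try:
                m = qpadm_fit(
                    target, list(srcs), list(rights), freqs, blocks,
                    p_threshold=p_threshold, site_mask=site_mask,
                )
            except ValueError:
                continue
            models.append(m)

    def sort_key(m: AdmixtureModel):
        ok = m.status == "pass"
        return (0 if ok else 1, len(m.sources), -m.p_value, m.sources)

    models.sort(key=sort_key)
    winner = next((m for m in models if m.status == "pass"), None)
    return ModelSearchReport(
        target=target,
        candidate_set=tuple(candidates),
        models=models,
        winner=winner,
    )


def report_table(report: ModelSearchReport):
    """Model report rows: target, sources, right_n, p, weights, ses, status."""
    import pandas as pd

    rows = []
    for m in report.models:
        row = {
            "target": m.target,
            "sources": "+".join(m.sources),
            "right_n": len(m.right),
            "p": m.p_value,
            "status": m.status,
        }
        for i in range(3):
            row[f"w{i+1}"] = m.weights[i] if i < len(m.weights) else np.nan
            row[f"se{i+1}"] = m.weight_se[i] if i < len(m.weight_se) else np.nan
        rows.append(row)
    return pd.DataFrame(rows)
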