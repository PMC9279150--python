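"""Drift-based PCA constructions on f-statistic distance matrices.

Two distance constructions are supported:

* outgroup-f3 distances, d = 1 - f3(O; X, Y): shared drift converted to a
  dissimilarity;
* f4-profile distances, d = sqrt(2 (1 - r)) where r is the Pearson
  correlation of two individuals' vectors of f4-statistics against a fixed
  reference set — individuals with similar relationships to the references
  land close together.

The PCA treats each individual's vector of distances to the *fit* set as its
feature vector ("PCA on a distance matrix"), centres features on the fit
set, and takes components from the fit set only; held-out individuals are
projected one at a time through the stored centring vector and loadings, so
the embedding of ancient individuals is never influenced by the projected
(e.g. modern or dog) samples. Missing entries in the fit matrix are filled
by an iterative expectation-maximisation low-rank completion.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass
class DriftDistanceMatrix:
    labels: list
    d: np.ndarray
    provenance: str  # "f3" | "f4profile"

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.labels)
        if self.d.shape != (n, n):
            raise ValueError("distance matrix shape does not match labels")
        finite = np.isfinite(self.d)
        sym = finite & finite.T
        if not np.allclose(self.d[sym].reshape(-1), self.d.T[sym].reshape(-1), atol=1e-9):
            raise ValueError("distance matrix asymmetric beyond 1e-9")

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.d, index=self.labels, columns=self.labels)


@dataclass
class PCAResult:
    fit_labels: list
    projected_labels: list
    loadings: np.ndarray  # n_features(=n_fit) x k
    coords: pd.DataFrame  # label x pc1..pck with a 'role' column
    explained: np.ndarray  # variance shares, non-increasing


def f3_distance_matrix(f3_results: pd.DataFrame) -> DriftDistanceMatrix:
    """d = 1 - f3 elementwise from a complete matrix of outgroup-f3 results.

    Accepts either a matrix of FStatResult objects or a numeric frame. The
    diagonal (self-affinity, maximal per row) is forced to the row minimum
    of the off-diagonal distances, so each individual is closest to itself
    without the self-comparison dominating the scale.
    """
    mat = f3_results.copy()
    if mat.isna().any().any():
        raise ValueError("f3 matrix has missing entries")
    vals = np.array(
        [[getattr(v, "estimate", v) for v in row] for row in mat.to_numpy()],
        dtype=float,
    )
    if np.isnan(vals).any():
        raise ValueError("f3 matrix has missing entries")
    d = 1.0 - vals
    n = d.shape[0]
    off = d + np.diag(np.full(n, np.inf))
    np.fill_diagonal(d, off.min(axis=1))
    dd = DriftDistanceMatrix(labels=list(mat.index), d=d, provenance="f3")
    return dd


def f4_profile_distance(profiles: pd.DataFrame,
                        min_complete: int = 3) -> DriftDistanceMatrix:
    """d = sqrt(2 (1 - r)) from per-individual f4-statistic profiles.

    ``profiles``: rows = individuals, columns = f4 statistics (NaN where a
    statistic could not be computed for that individual). r is the Pearson
    correlation over pairwise-complete entries; each pair needs at least
    ``min_complete`` shared entries and non-constant profiles.
    """
    labels = list(profiles.index)
    X = profiles.to_numpy(dtype=float)
    n = len(labels)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            ok = np.isfinite(X[i]) & np.isfinite(X[j])
            if ok.sum() < min_complete:
                raise ValueError(
                    f"pair ({labels[i]}, {labels[j]}): fewer than {min_complete} shared entries"
                )
            xi, xj = X[i, ok], X[j, ok]
            if xi.std() == 0 or xj.std() == 0:
                raise ValueError(
                    f"pair ({labels[i]}, {labels[j]}): constant profile, correlation undefined"
                )
            r = float(np.corrcoef(xi, xj)[0, 1])
            d[i, j] = d[j, i] = float(np.sqrt(max(2.0 * (1.0 - r), 0.0)))
    return DriftDistanceMatrix(labels=labels, d=d, provenance="f4profile")


def _em_complete(F: np.ndarray, k: int, tol: float = 1e-6,
                 max_iter: int = 500, seed: int = 0) -> np.ndarray:
    """EM low-rank completion: fill missing entries, iterate rank-k SVD
    reconstruction of the column-centred matrix until the imputations
    settle."""
    miss = ~np.isfinite(F)
    if not miss.any():
        return F
    X = F.copy()
    col_mean = np.nanmean(F, axis=0)
    col_mean = np.where(np.isfinite(col_mean), col_mean, np.nanmean(F))
    X[miss] = np.broadcast_to(col_mean, F.shape)[miss]
    rng = np.random.default_rng(seed)
    X[miss] += 1e-10 * rng.standard_normal(miss.sum())  # break exact ties
    k = min(k, min(X.shape) - 1)
    for _ in range(max_iter):
        mu = X.mean(axis=0)
        C = X - mu
        U, s, Vt = np.linalg.svd(C, full_matrices=False)
        recon = (U[:, :k] * s[:k]) @ Vt[:k] + mu
        delta = np.max(np.abs(recon[miss] - X[miss]))
        X[miss] = recon[miss]
        if delta < tol:
            break
    return X


def pca_fit_project(dist: DriftDistanceMatrix, fit_labels, project_labels=(),
                    n_components: int = 2, completion_rank: int = 10,
                    seed: int = 0) -> PCAResult:
    """PCA of distance-row feature vectors, fitted on ``fit_labels`` only.

    Every individual is described by its distances to the fit individuals;
    the PCA is computed on the fit set (features centred on fit means) and
    each projected individual is mapped one at a time by
    (features - centre) @ loadings — so projections are mutually
    independent. Missing fit entries are EM-completed at
    ``completion_rank``. Component signs are fixed so the largest-magnitude
    loading is positive.
    """
    labels = list(dist.labels)
    fit_labels = list(fit_labels)
    project_labels = list(project_labels)
    unknown = (set(fit_labels) | set(project_labels)) - set(labels)
    if unknown:
        raise ValueError(f"labels not in distance matrix: {sorted(unknown)}")
    if n_components > len(fit_labels):
        raise ValueError("fit set smaller than requested number of components")
    pos = {l: i for i, l in enumerate(labels)}
    fit_idx = [pos[l] for l in fit_labels]
    F = dist.d[np.ix_(fit_idx, fit_idx)]
    F = _em_complete(F, completion_rank, seed=seed)
    centre = F.mean(axis=0)
    C = F - centre
    U, s, Vt = np.linalg.svd(C, full_matrices=False)
    k = n_components
    loadings = Vt[:k].T  # n_fit_features x k
    # sign convention: largest-|loading| positive per component
    for c in range(k):
        j = int(np.argmax(np.abs(loadings[:, c])))
        if loadings[j, c] < 0:
            loadings[:, c] = -loadings[:, c]
    scores_fit = C @ loadings
    with np.errstate(invalid="ignore", divide="ignore"):
        var = s**2
        explained = var[:k] / var.sum() if var.sum() > 0 else np.zeros(k)

    rows = []
    for l, sc in zip(fit_labels, scores_fit):
        rows.append({"label": l, **{f"pc{c+1}": sc[c] for c in range(k)}, "role": "fitted"})
    for l in project_labels:
        feats = dist.d[pos[l], fit_idx].astype(float)
        if not np.isfinite(feats).all():
            raise ValueError(f"projected individual {l!r} lacks distances to the fit set")
        sc = (feats - centre) @ loadings
        rows.append({"label": l, **{f"pc{c+1}": sc[c] for c in range(k)}, "role": "projected"})
    coords = pd.DataFrame(rows).set_index("label")
    return PCAResult(
        fit_labels=fit_labels,
        projected_labels=project_labels,
        loadings=loadings,
        coords=coords,
        explained=np.asarray(explained),
    )


def f4_profiles_for_individuals(
    individuals, reference_set, dataset, blocks, grouping=None,
) -> pd.DataFrame:
    """All f4(X, A; B, C) with A, B, C drawn from the reference set.

    Rows = individuals X, columns = the reference triples; used as input to
    :func:`f4_profile_distance`. References typically predate the period of
    interest so the profile reflects old, stable structure.
    """
    import itertools

    from .fstats import f4, group_freqs

    freqs = group_freqs(dataset, grouping)
    triples = [
        (a, b, c)
        for a, b, c in itertools.combinations(reference_set, 3)
    ]
    cols = {}
    for a, b, c in triples:
        key = f"f4(X,{a};{b},{c})"
        vals = []
        for x in individuals:
            try:
                vals.append(f4(x, a, b, c, freqs, blocks).estimate)
            except (ValueError, KeyError):
                vals.append(np.nan)
        cols[key] = vals
    return pd.DataFrame(cols, index=list(individuals))
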