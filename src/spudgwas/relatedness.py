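"""Genomic relatedness and population structure from dosage data.

The relationship matrix is the Gower similarity of dosage vectors,
S_ij = mean over shared markers of (1 - |d_i - d_j| / ploidy), a [0, 1]
similarity used directly as the kinship K of the mixed GWAS model.
Structure covariates (the Q of Q/QK models) come either from a PCA of the
(centred) relationship matrix or from non-metric multidimensional scaling of
the derived dissimilarities; externally estimated membership matrices can be
loaded as well.  Differentiation between supplied subpopulation assignments
is measured by Hudson-style Fst (ratio of averages) and Nei's standard
genetic distance.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import pdist, squareform
from sklearn.manifold import smacof

from .panel import DosagePanel, PanelError

log = logging.getLogger(__name__)


@dataclass
class RelationshipMatrix:
    """Symmetric samples x samples Gower-similarity kinship."""

    sample_ids: np.ndarray
    S: np.ndarray

    def __post_init__(self) -> None:
        self.sample_ids = np.asarray(self.sample_ids, dtype=object)
        self.S = np.asarray(self.S, dtype=float)
        n = len(self.sample_ids)
        if self.S.shape != (n, n):
            raise PanelError("relationship matrix shape does not match sample ids")

    def subset(self, sample_ids: Sequence[str]) -> "RelationshipMatrix":
        pos = {s: i for i, s in enumerate(self.sample_ids)}
        idx = np.array([pos[s] for s in sample_ids], dtype=int)
        return RelationshipMatrix(np.asarray(list(sample_ids), dtype=object),
                                  self.S[np.ix_(idx, idx)])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.S, index=self.sample_ids, columns=self.sample_ids)


@dataclass
class StructureCovariates:
    """Samples x k covariate matrix Q entering the GWAS fixed effects."""

    sample_ids: np.ndarray
    Q: np.ndarray
    source: str  # PCA | NMDS | EXTERNAL
    k: int

    def __post_init__(self) -> None:
        self.sample_ids = np.asarray(self.sample_ids, dtype=object)
        self.Q = np.atleast_2d(np.asarray(self.Q, dtype=float))
        if self.Q.shape[0] != len(self.sample_ids):
            raise PanelError("covariate rows do not match sample ids")
        if not np.isfinite(self.Q).all():
            raise PanelError("covariates must be finite")
        if not (1 <= self.k <= len(self.sample_ids) - 1):
            raise PanelError("k must satisfy 1 <= k <= n_samples - 1")

    def subset(self, sample_ids: Sequence[str]) -> "StructureCovariates":
        pos = {s: i for i, s in enumerate(self.sample_ids)}
        idx = np.array([pos[s] for s in sample_ids], dtype=int)
        return StructureCovariates(np.asarray(list(sample_ids), dtype=object),
                                   self.Q[idx], self.source, self.k)

    def to_frame(self) -> pd.DataFrame:
        cols = [f"q{i + 1}" for i in range(self.Q.shape[1])]
        df = pd.DataFrame(self.Q, index=self.sample_ids, columns=cols)
        df.index.name = "sample_id"
        return df


@dataclass
class NmdsResult:
    """One non-metric MDS solution with its Kruskal stress-1."""

    configuration: np.ndarray
    stress: float
    k: int


# ---------------------------------------------------------------------------
# kinship


def gower_kinship(panel: DosagePanel) -> RelationshipMatrix:
    """Gower similarity over markers non-missing in both samples of a pair.

    Pairs with zero shared markers get NaN similarity (and a warning); the
    diagonal is exactly 1 for any sample with at least one call.
    """
    if panel.n_samples < 2:
        raise PanelError("kinship needs at least 2 samples")
    X = panel.values.T  # samples x markers
    n, m = X.shape
    rng_norm = float(panel.ploidy)
    if not panel.missing.any():
        D = squareform(pdist(X, metric="cityblock"))
        S = 1.0 - D / (rng_norm * m)
    else:
        M = ~np.isnan(X)
        S = np.empty((n, n))
        for i in range(n):
            diff = np.abs(X[i] - X)  # NaN where either is missing
            sim = 1.0 - diff / rng_norm
            shared = (M[i] & M).sum(axis=1)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                S[i] = np.nanmean(np.where(np.isnan(sim), np.nan, sim), axis=1)
            S[i, shared == 0] = np.nan
        if np.isnan(S[np.triu_indices(n, 1)]).any():
            warnings.warn("sample pairs with zero shared markers: similarity is NaN",
                          stacklevel=2)
    called = (~panel.missing).any(axis=0)
    S[np.arange(n), np.arange(n)] = np.where(called, 1.0, np.nan)
    S = np.clip(S, 0.0, 1.0, out=S, where=~np.isnan(S))
    return RelationshipMatrix(panel.sample_ids.copy(), S)


# ---------------------------------------------------------------------------
# PCA covariates


def pca_covariates(
    K: RelationshipMatrix, n: int = 20, center: bool = True
) -> tuple[StructureCovariates, np.ndarray]:
    """Leading eigenvectors of the (centred) relationship matrix.

    Returns the covariate object and the full eigenvalue spectrum sorted
    non-increasing (for a screeplot).
    """
    S = K.S
    if not np.allclose(S, S.T, atol=1e-8, equal_nan=True):
        raise PanelError("relationship matrix must be symmetric")
    if np.isnan(S).any():
        raise PanelError("relationship matrix contains missing similarities")
    ns = S.shape[0]
    if not (1 <= n < ns):
        raise PanelError("need 1 <= n < n_samples eigenvectors")
    A = S
    if center:
        C = np.eye(ns) - np.full((ns, ns), 1.0 / ns)
        A = C @ S @ C
    vals, vecs = np.linalg.eigh(A)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    # fix eigenvector sign for reproducibility: largest-magnitude entry positive
    j = np.argmax(np.abs(vecs), axis=0)
    vecs = vecs * np.sign(vecs[j, np.arange(vecs.shape[1])])
    cov = StructureCovariates(K.sample_ids.copy(), vecs[:, :n], "PCA", n)
    return cov, vals


# ---------------------------------------------------------------------------
# dissimilarity + non-metric MDS


def similarity_to_dissimilarity(K: RelationshipMatrix, kind: str = "sqrt") -> np.ndarray:
    """Dissimilarity matrix from a similarity matrix.

    kind='sqrt' (default): D_ij = sqrt(S_ii + S_jj - 2 S_ij), the Euclidean
    embedding distance, a valid metric whenever S is positive semi-definite.
    kind='one_minus': D = 1 - S.
    """
    S = K.S
    if kind == "sqrt":
        d = np.diag(S)
        D2 = d[:, None] + d[None, :] - 2.0 * S
        D = np.sqrt(np.clip(D2, 0.0, None))
    elif kind == "one_minus":
        D = 1.0 - S
    else:
        raise ValueError(f"unknown dissimilarity kind {kind!r}")
    np.fill_diagonal(D, 0.0)
    return (D + D.T) / 2.0


def classical_mds(D: np.ndarray, k: int) -> np.ndarray:
    """Torgerson's classical scaling, used to initialise the nMDS majorization."""
    n = D.shape[0]
    J = np.eye(n) - np.full((n, n), 1.0 / n)
    B = -0.5 * J @ (D**2) @ J
    vals, vecs = np.linalg.eigh(B)
    order = np.argsort(vals)[::-1][:k]
    lam = np.clip(vals[order], 0.0, None)
    return vecs[:, order] * np.sqrt(lam)


def nmds(
    D: np.ndarray,
    k: int,
    max_iter: int = 300,
    tol: float = 1e-9,
    seed: int | None = None,
    n_restarts: int = 0,
) -> NmdsResult:
    """Non-metric MDS by SMACOF majorization with isotonic regression on ranks.

    Initialised from the classical (metric) MDS solution, so the result is
    deterministic; random restarts (seeded) are only tried when requested and
    the best (lowest Kruskal stress-1) configuration is kept.
    """
    D = np.asarray(D, dtype=float)
    n = D.shape[0]
    if not np.allclose(D, D.T, atol=1e-10):
        raise PanelError("dissimilarity matrix must be symmetric")
    if not np.allclose(np.diag(D), 0.0):
        raise PanelError("dissimilarity diagonal must be zero")
    if k >= n:
        raise PanelError("k must be smaller than the number of samples")
    init = classical_mds(D, k)
    conf, stress = smacof(
        D, metric=False, n_components=k, init=init, n_init=1,
        max_iter=max_iter, eps=tol, normalized_stress=True, random_state=0,
    )
    for r in range(n_restarts):
        rng = np.random.default_rng(None if seed is None else seed + r)
        alt_init = rng.normal(size=(n, k))
        alt, alt_stress = smacof(
            D, metric=False, n_components=k, init=alt_init, n_init=1,
            max_iter=max_iter, eps=tol, normalized_stress=True, random_state=0,
        )
        if alt_stress < stress:
            conf, stress = alt, alt_stress
    return NmdsResult(conf, float(stress), k)


def nmds_scan(
    D: np.ndarray, k_max: int = 20, **kwargs
) -> tuple[pd.DataFrame, int | None]:
    """Stress per dimension 1..k_max (screeplot table) plus an elbow suggestion.

    The suggestion is the interior k with the largest second difference of
    the stress curve; the final dimension choice is left to the user.
    """
    ks = list(range(1, k_max + 1))
    stresses = [nmds(D, k, **kwargs).stress for k in ks]
    table = pd.DataFrame({"k": ks, "stress": stresses})
    suggestion: int | None = None
    if len(ks) >= 3:
        s = np.array(stresses)
        curv = s[:-2] - 2 * s[1:-1] + s[2:]
        suggestion = int(ks[1 + int(np.argmax(curv))])
    return table, suggestion


# ---------------------------------------------------------------------------
# genetic distance, clustering, differentiation


def nei_distance(freqs_a: np.ndarray, freqs_b: np.ndarray) -> float:
    """Nei's (1972) standard genetic distance between two populations.

    Inputs are per-locus alternative-allele frequencies of biallelic markers.
    Returns +inf (with a warning) when the populations share no alleles.
    """
    pa = np.asarray(freqs_a, dtype=float)
    pb = np.asarray(freqs_b, dtype=float)
    if pa.shape != pb.shape:
        raise ValueError("frequency vectors must have equal length")
    ok = ~(np.isnan(pa) | np.isnan(pb))
    pa, pb = pa[ok], pb[ok]
    if pa.size == 0:
        raise ValueError("no loci with defined frequencies in both populations")
    jab = np.mean(pa * pb + (1 - pa) * (1 - pb))
    jaa = np.mean(pa**2 + (1 - pa) ** 2)
    jbb = np.mean(pb**2 + (1 - pb) ** 2)
    identity = jab / np.sqrt(jaa * jbb)
    if identity <= 0:
        warnings.warn("zero genetic identity: Nei distance is infinite", stacklevel=2)
        return float("inf")
    return float(-np.log(identity))


@dataclass
class Dendrogram:
    """Agglomerative merge history: scipy-convention linkage plus leaf labels."""

    labels: np.ndarray
    merges: np.ndarray  # (n-1, 2) int cluster indices, scipy convention
    heights: np.ndarray  # (n-1,) merge heights, non-decreasing for Ward

    def to_newick(self) -> str:
        n = len(self.labels)

        def node(i: int, parent_h: float) -> str:
            if i < n:
                return f"{self.labels[i]}:{parent_h:.6g}"
            j = i - n
            h = self.heights[j]
            a = node(int(self.merges[j, 0]), h)
            b = node(int(self.merges[j, 1]), h)
            return f"({a},{b}):{max(parent_h - h, 0.0):.6g}"

        root = 2 * n - 2
        h = self.heights[-1]
        a = node(int(self.merges[-1, 0]), h)
        b = node(int(self.merges[-1, 1]), h)
        return f"({a},{b});"


def hierarchical_clusters(
    D: np.ndarray,
    labels: Sequence[str] | None = None,
    method: str = "ward.d2",
) -> Dendrogram:
    """Agglomerative clustering of a dissimilarity matrix.

    'ward.d2' follows the R hclust convention: the Ward variance criterion
    applied to the supplied distances themselves (scipy's 'ward' on a
    condensed distance matrix).  Merge heights are non-decreasing.
    """
    D = np.asarray(D, dtype=float)
    n = D.shape[0]
    if labels is None:
        labels = [str(i) for i in range(n)]
    scipy_method = {"ward.d2": "ward"}.get(method, method)
    Z = linkage(squareform(D, checks=False), method=scipy_method)
    return Dendrogram(
        np.asarray(list(labels), dtype=object),
        Z[:, :2].astype(int),
        Z[:, 2].astype(float),
    )


def _subpop_freq_counts(
    panel: DosagePanel, assignments: Mapping[str, str] | pd.Series
) -> tuple[list[str], np.ndarray, np.ndarray]:
    """Per-subpopulation allele frequencies and allele counts per marker."""
    if isinstance(assignments, pd.Series):
        assignments = assignments.to_dict()
    pops = sorted({assignments[s] for s in panel.sample_ids if s in assignments})
    X = panel.values
    freqs = np.empty((len(pops), panel.n_markers))
    counts = np.empty((len(pops), panel.n_markers))
    for k, pop in enumerate(pops):
        cols = [i for i, s in enumerate(panel.sample_ids) if assignments.get(s) == pop]
        sub = X[:, cols]
        called = ~np.isnan(sub)
        counts[k] = panel.ploidy * called.sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            freqs[k] = np.nansum(sub, axis=1) / counts[k]
    return pops, freqs, counts


def fst_pairwise(
    panel: DosagePanel, assignments: Mapping[str, str] | pd.Series
) -> pd.DataFrame:
    """Hudson-style pairwise Fst between subpopulations (ratio of averages).

    Allele frequencies are estimated from dosages (allele count = ploidy x
    called samples); per pair, numerator and denominator are averaged over
    markers before taking the ratio, which keeps the estimator nearly
    unbiased under Balding-Nichols divergence.
    """
    pops, freqs, counts = _subpop_freq_counts(panel, assignments)
    npop = len(pops)
    out = np.zeros((npop, npop))
    for a in range(npop):
        for b in range(a + 1, npop):
            p1, p2 = freqs[a], freqs[b]
            n1, n2 = counts[a], counts[b]
            ok = (~np.isnan(p1)) & (~np.isnan(p2)) & (n1 > 1) & (n2 > 1)
            p1, p2, n1, n2 = p1[ok], p2[ok], n1[ok], n2[ok]
            num = (p1 - p2) ** 2 - p1 * (1 - p1) / (n1 - 1) - p2 * (1 - p2) / (n2 - 1)
            den = p1 * (1 - p2) + p2 * (1 - p1)
            fst = num.sum() / den.sum() if den.sum() > 0 else np.nan
            out[a, b] = out[b, a] = fst
    return pd.DataFrame(out, index=pops, columns=pops)


def nei_pairwise(
    panel: DosagePanel, assignments: Mapping[str, str] | pd.Series
) -> pd.DataFrame:
    """Nei (1972) standard distance between each pair of subpopulations."""
    pops, freqs, _ = _subpop_freq_counts(panel, assignments)
    npop = len(pops)
    out = np.zeros((npop, npop))
    for a in range(npop):
        for b in range(a + 1, npop):
            out[a, b] = out[b, a] = nei_distance(freqs[a], freqs[b])
    return pd.DataFrame(out, index=pops, columns=pops)


# ---------------------------------------------------------------------------
# covariate I/O


def read_covariates(path: str | Path, source: str = "EXTERNAL") -> StructureCovariates:
    df = pd.read_csv(path, sep="\t", index_col=0)
    Q = df.to_numpy(dtype=float)
    return StructureCovariates(df.index.to_numpy(dtype=object), Q, source, Q.shape[1])


def write_covariates(cov: StructureCovariates, path: str | Path) -> None:
    cov.to_frame().to_csv(path, sep="\t")


def read_kinship(path: str | Path) -> RelationshipMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return RelationshipMatrix(df.index.to_numpy(dtype=object), df.to_numpy(dtype=float))


def write_kinship(K: RelationshipMatrix, path: str | Path) -> None:
    K.to_frame().to_csv(path, sep="\t")
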