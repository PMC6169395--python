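"""Mixed-model GWAS on tetraploid allele dosages.

The model is the single-marker linear mixed model

    y = X beta + s alpha + Q v + u + e,   u ~ N(0, sigma_g^2 K),  e ~ N(0, sigma_e^2 I)

where y are trait BLUEs, s the additive dosage (0..4) of the tested marker,
Q optional population-structure covariates, and K a Gower-similarity kinship.
Four variants are fitted: Naive (no Q, no K), K, Q and QK.

Estimation follows the EMMA/P3D approach: the kinship is eigendecomposed
once, the ratio delta = sigma_e^2 / sigma_g^2 is profiled out of the
restricted likelihood on that spectrum under the no-marker null, and each
marker is then tested by generalized least squares with the null variance
components held fixed ("population parameters previously determined").
Per-marker inference is a two-sided Wald t test with df = n - rank(X) - 1.

Model fit per trait is judged by the genomic-control inflation factor
lambda_GC (median 1-df chi-square statistic over its null median 0.4549...),
with Q-Q coordinates for plotting and Bonferroni hit calling.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from enum import Enum
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .panel import DosagePanel, MarkerMap, PanelError
from .relatedness import RelationshipMatrix, StructureCovariates

log = logging.getLogger(__name__)

#: median of the chi-square distribution with 1 df (qchisq(0.5, 1))
CHI2_1_MEDIAN = 0.4549364231


class ModelKind(str, Enum):
    NAIVE = "naive"
    K = "k"
    Q = "q"
    QK = "qk"


@dataclass
class GwasModelSpec:
    """Which confounder corrections enter the model."""

    kind: ModelKind
    covariates: StructureCovariates | None = None
    kinship: RelationshipMatrix | None = None

    def __post_init__(self) -> None:
        self.kind = ModelKind(self.kind)
        if self.kind in (ModelKind.K, ModelKind.QK) and self.kinship is None:
            raise PanelError(f"model {self.kind.value!r} requires a kinship matrix")
        if self.kind in (ModelKind.Q, ModelKind.QK) and self.covariates is None:
            raise PanelError(f"model {self.kind.value!r} requires structure covariates")

    @property
    def uses_kinship(self) -> bool:
        return self.kind in (ModelKind.K, ModelKind.QK)

    @property
    def uses_covariates(self) -> bool:
        return self.kind in (ModelKind.Q, ModelKind.QK)


@dataclass
class VarianceComponents:
    """REML variance components of the no-marker null model."""

    sigma_g2: float
    sigma_e2: float
    reml_loglik: float

    @property
    def h2(self) -> float:
        tot = self.sigma_g2 + self.sigma_e2
        return self.sigma_g2 / tot if tot > 0 else np.nan


# ---------------------------------------------------------------------------
# REML on the kinship spectrum


def _reml_neg_loglik(log_delta: float, d: np.ndarray, Xt: np.ndarray,
                     yt: np.ndarray, logdet_xtx: float) -> float:
    delta = np.exp(log_delta)
    n, p = Xt.shape
    w = 1.0 / (d + delta)
    XtW = Xt * w[:, None]
    B = Xt.T @ XtW
    try:
        cf = np.linalg.cholesky(B)
    except np.linalg.LinAlgError:
        return np.inf
    beta = np.linalg.solve(B, XtW.T @ yt)
    r = yt - Xt @ beta
    ypy = float(r @ (w * r))
    if ypy <= 0:
        return np.inf
    sigma_g2 = ypy / (n - p)
    logdet_b = 2.0 * np.log(np.diag(cf)).sum()
    ll = -0.5 * (
        (n - p) * (np.log(2 * np.pi * sigma_g2) + 1.0)
        + np.log(d + delta).sum()
        + logdet_b
        - logdet_xtx
    )
    return -ll


def reml_null_fit(
    trait: np.ndarray,
    fixed: np.ndarray,
    K: RelationshipMatrix | np.ndarray,
    n_grid: int = 81,
) -> VarianceComponents:
    """Profile REML of (sigma_g^2, sigma_e^2) for y = X beta + u + e.

    The restricted likelihood is profiled over delta = sigma_e^2/sigma_g^2
    on the spectral decomposition of K (grid over log delta in [-10, 10]
    followed by bounded local refinement), so the fit is deterministic.
    Tiny negative eigenvalues of K are clipped to zero; a K that is
    indefinite beyond tolerance is an error, as is a constant trait.
    """
    y = np.asarray(trait, dtype=float)
    X = np.atleast_2d(np.asarray(fixed, dtype=float))
    S = K.S if isinstance(K, RelationshipMatrix) else np.asarray(K, dtype=float)
    n = y.size
    if n < 10:
        raise PanelError("need at least 10 phenotyped samples")
    if np.ptp(y) == 0:
        raise PanelError("trait is constant")
    if X.shape[0] != n or S.shape != (n, n):
        raise PanelError("trait, fixed effects and kinship are not aligned")
    d, U = np.linalg.eigh((S + S.T) / 2.0)
    if d.min() < -1e-6 * max(d.max(), 1.0):
        raise PanelError("kinship matrix is not positive semi-definite")
    d = np.clip(d, 0.0, None)
    Xt, yt = U.T @ X, U.T @ y
    sign, logdet_xtx = np.linalg.slogdet(X.T @ X)
    if sign <= 0:
        raise PanelError("fixed-effect design is rank deficient")
    grid = np.linspace(-10.0, 10.0, n_grid)
    vals = np.array([_reml_neg_loglik(g, d, Xt, yt, logdet_xtx) for g in grid])
    i = int(np.argmin(vals))
    lo = grid[max(i - 1, 0)]
    hi = grid[min(i + 1, n_grid - 1)]
    res = optimize.minimize_scalar(
        _reml_neg_loglik, bounds=(lo, hi), method="bounded",
        args=(d, Xt, yt, logdet_xtx), options={"xatol": 1e-8},
    )
    log_delta = float(res.x) if res.fun <= vals[i] else float(grid[i])
    delta = float(np.exp(log_delta))
    p = X.shape[1]
    w = 1.0 / (d + delta)
    XtW = Xt * w[:, None]
    B = Xt.T @ XtW
    beta = np.linalg.solve(B, XtW.T @ yt)
    r = yt - Xt @ beta
    sigma_g2 = float(r @ (w * r)) / (n - p)
    ll = -_reml_neg_loglik(log_delta, d, Xt, yt, logdet_xtx)
    return VarianceComponents(sigma_g2, sigma_g2 * delta, float(ll))


# ---------------------------------------------------------------------------
# diagnostics


def genomic_lambda(p_values: np.ndarray) -> float:
    """Genomic-control inflation factor: median chi2_1 quantile of the
    p-values over the null chi2_1 median."""
    p = np.asarray(p_values, dtype=float)
    p = p[~np.isnan(p)]
    if p.size == 0:
        raise ValueError("no p-values supplied")
    chi2 = stats.chi2.isf(p, df=1)
    return float(np.median(chi2) / CHI2_1_MEDIAN)


def bonferroni_threshold(n_tests: int, alpha: float = 0.05) -> float:
    """Genome-wide significance threshold on the -log10(p) scale."""
    if n_tests < 1:
        raise ValueError("n_tests must be positive")
    return float(-np.log10(alpha / n_tests))


def qq_data(p_values: np.ndarray) -> pd.DataFrame:
    """Paired expected/observed -log10(p) quantiles, both sorted ascending.

    Expected quantile i of m is (i - 0.5)/m on the p scale.
    """
    p = np.asarray(p_values, dtype=float)
    p = p[~np.isnan(p)]
    m = p.size
    if m == 0:
        raise ValueError("no p-values supplied")
    obs = np.sort(-np.log10(np.clip(p, 1e-300, 1.0)))
    i = np.arange(1, m + 1)
    exp = np.sort(-np.log10((i - 0.5) / m))
    return pd.DataFrame({"expected": exp, "observed": obs})


def rank_models(lambdas: Mapping[str, float]) -> dict[str, int]:
    """Rank models by closeness of lambda_GC to 1 (ascending |lambda - 1|).

    Ties break toward the smaller lambda, then by model name, so the ranking
    is deterministic.  Deflated models (lambda < 1) rank by the same
    closeness-to-1 rule.
    """
    order = sorted(lambdas, key=lambda k: (abs(lambdas[k] - 1.0), lambdas[k], str(k)))
    return {name: i + 1 for i, name in enumerate(order)}


# ---------------------------------------------------------------------------
# the model object


class DosageGwas:
    """Single-trait mixed-model GWAS over a dosage panel.

    Parameters
    ----------
    trait : pandas Series of BLUEs indexed by sample id (missing allowed;
        those samples are dropped, with K and Q subset accordingly).
    panel : QC-filtered :class:`DosagePanel`.
    model : one of 'naive', 'k', 'q', 'qk', or a :class:`GwasModelSpec`.
    kinship, covariates : required by the K/QK and Q/QK variants.
    marker_map : optional; annotates the scan with chromosome/position.

    ``fit()`` returns a :class:`GwasResults`.
    """

    def __init__(
        self,
        trait: pd.Series,
        panel: DosagePanel,
        model: str | ModelKind | GwasModelSpec = ModelKind.NAIVE,
        kinship: RelationshipMatrix | None = None,
        covariates: StructureCovariates | None = None,
        marker_map: MarkerMap | None = None,
    ) -> None:
        if isinstance(model, GwasModelSpec):
            spec = model
        else:
            spec = GwasModelSpec(ModelKind(model), covariates, kinship)
        self.spec = spec
        self.panel = panel
        self.marker_map = marker_map
        trait = trait.dropna()
        keep = [s for s in panel.sample_ids if s in trait.index]
        if len(keep) < 10:
            raise PanelError("fewer than 10 phenotyped samples overlap the panel")
        self.sample_ids = np.asarray(keep, dtype=object)
        self.y = trait.loc[keep].to_numpy(dtype=float)
        self.trait_name = str(trait.name) if trait.name is not None else "trait"
        self._sub_panel = panel.subset_samples(keep)
        cols = [np.ones(len(keep))]
        if spec.uses_covariates:
            cols.append(spec.covariates.subset(keep).Q)
        self.X = np.column_stack(cols)
        self.K = spec.kinship.subset(keep) if spec.uses_kinship else None

    # -- fitting -----------------------------------------------------------

    def fit(self, method: str = "p3d") -> "GwasResults":
        """Scan all markers; 'p3d' reuses null variance components for every
        marker, 'exact' re-estimates them per marker (small panels only)."""
        if method not in ("p3d", "exact"):
            raise ValueError("method must be 'p3d' or 'exact'")
        n = len(self.y)
        varcomp = None
        if self.K is not None:
            varcomp = reml_null_fit(self.y, self.X, self.K)
            delta = (
                np.inf if varcomp.sigma_g2 <= 0
                else varcomp.sigma_e2 / varcomp.sigma_g2
            )
            d, U = np.linalg.eigh((self.K.S + self.K.S.T) / 2.0)
            d = np.clip(d, 0.0, None)
            w = np.ones(n) if np.isinf(delta) else 1.0 / (d + delta)
        else:
            U = None
            w = np.ones(n)

        S, keep_idx, dropped = self._marker_matrix()
        if method == "exact" and self.K is not None:
            eff, se, pval = self._scan_exact(S)
        else:
            eff, se, pval = self._scan_gls(S, U, w)

        scan = pd.DataFrame(
            {
                "marker_id": self.panel.marker_ids[keep_idx],
                "effect": eff,
                "se": se,
                "p": pval,
                "score": -np.log10(np.clip(pval, 1e-300, 1.0)),
            }
        )
        if self.marker_map is not None:
            ann = self.marker_map.aligned_to(scan["marker_id"])
            scan.insert(1, "chromosome", ann["chromosome"].to_numpy())
            scan.insert(2, "position_bp", ann["position_bp"].to_numpy())
        return GwasResults(self, scan, varcomp, dropped, n_used=n)

    # -- internals ---------------------------------------------------------

    def _marker_matrix(self) -> tuple[np.ndarray, np.ndarray, dict[str, str]]:
        """Marker-mean imputed dosage matrix (markers x samples); monomorphic
        markers (after imputation) are omitted with a reason."""
        X = self._sub_panel.values
        mean = np.nanmean(np.where(np.isnan(X), np.nan, X), axis=1)
        all_missing = np.isnan(mean)
        filled = np.where(np.isnan(X), mean[:, None], X)
        var = np.nanvar(filled, axis=1)
        keep = (~all_missing) & (var > 1e-12)
        dropped = {}
        for i in np.nonzero(~keep)[0]:
            reason = "all calls missing" if all_missing[i] else "monomorphic"
            dropped[str(self.panel.marker_ids[i])] = reason
        return filled[keep], np.nonzero(keep)[0], dropped

    def _scan_gls(
        self, S: np.ndarray, U: np.ndarray | None, w: np.ndarray
    ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Vectorized per-marker GLS Wald tests with fixed weights.

        Works in the eigenbasis of K (identity when no kinship): residualize
        the rotated marker and trait against the rotated fixed effects under
        weights w, then a weighted simple regression per marker.
        """
        n, p = self.X.shape
        if U is not None:
            Xt, yt, St = U.T @ self.X, U.T @ self.y, S @ U
        else:
            Xt, yt, St = self.X, self.y, S
        WX = Xt * w[:, None]
        G = np.linalg.inv(Xt.T @ WX)
        # residualize trait
        by = G @ (WX.T @ yt)
        ry = yt - Xt @ by
        # residualize every marker at once
        A = St @ WX  # (m, p)
        Sr = St - (A @ G) @ Xt.T  # (m, n)
        den = ((Sr**2) * w).sum(axis=1)
        num = (Sr * w) @ ry
        yy = float(ry @ (w * ry))
        df = n - p - 1
        with np.errstate(invalid="ignore", divide="ignore"):
            alpha = num / den
            rss = yy - alpha * num
            sigma2 = np.clip(rss, 0.0, None) / df
            se = np.sqrt(sigma2 / den)
            tstat = alpha / se
        pval = 2.0 * stats.t.sf(np.abs(tstat), df)
        return alpha, se, pval

    def _scan_exact(self, S: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Per-marker REML refit (verification path; O(markers) REML solves)."""
        n, p = self.X.shape
        m = S.shape[0]
        eff = np.empty(m)
        se = np.empty(m)
        pval = np.empty(m)
        for j in range(m):
            Xj = np.column_stack([self.X, S[j]])
            vc = reml_null_fit(self.y, Xj, self.K)
            delta = np.inf if vc.sigma_g2 <= 0 else vc.sigma_e2 / vc.sigma_g2
            d, U = np.linalg.eigh((self.K.S + self.K.S.T) / 2.0)
            d = np.clip(d, 0.0, None)
            w = np.ones(n) if np.isinf(delta) else 1.0 / (d + delta)
            Xt, yt = U.T @ Xj, U.T @ self.y
            WX = Xt * w[:, None]
            B = Xt.T @ WX
            Binv = np.linalg.inv(B)
            beta = Binv @ (WX.T @ yt)
            r = yt - Xt @ beta
            df = n - p - 1
            sigma2 = float(r @ (w * r)) / df
            eff[j] = beta[-1]
            se[j] = np.sqrt(sigma2 * Binv[-1, -1])
            tstat = eff[j] / se[j]
            pval[j] = 2.0 * stats.t.sf(abs(tstat), df)
        return eff, se, pval


@dataclass
class GwasResults:
    """Fitted scan for one trait under one model, with diagnostics."""

    model: DosageGwas
    scan: pd.DataFrame
    varcomp: VarianceComponents | None
    dropped: dict[str, str]
    n_used: int

    @property
    def p_values(self) -> np.ndarray:
        return self.scan["p"].to_numpy()

    @property
    def scores(self) -> np.ndarray:
        return self.scan["score"].to_numpy()

    @property
    def lambda_gc(self) -> float:
        return genomic_lambda(self.p_values)

    def qq_table(self) -> pd.DataFrame:
        return qq_data(self.p_values)

    def bonferroni(self, alpha: float = 0.05) -> float:
        return bonferroni_threshold(len(self.scan), alpha)

    def significant_hits(self, threshold: float | None = None,
                         alpha: float = 0.05) -> pd.DataFrame:
        if threshold is None:
            threshold = self.bonferroni(alpha)
        return significant_hits(self, threshold)

    def diagnostics(self, alpha: float = 0.05) -> dict:
        return {
            "trait": self.model.trait_name,
            "model": self.model.spec.kind.value,
            "n_used": self.n_used,
            "n_markers": int(len(self.scan)),
            "n_dropped": len(self.dropped),
            "lambda_gc": self.lambda_gc,
            "bonferroni_threshold": self.bonferroni(alpha),
            "sigma_g2": None if self.varcomp is None else self.varcomp.sigma_g2,
            "sigma_e2": None if self.varcomp is None else self.varcomp.sigma_e2,
            "h2": None if self.varcomp is None else self.varcomp.h2,
        }

    def summary(self, alpha: float = 0.05, top: int = 5) -> str:
        d = self.diagnostics(alpha)
        lines = [
            f"GWAS scan: trait={d['trait']!r} model={d['model'].upper()}",
            f"  samples used: {d['n_used']}   markers tested: {d['n_markers']}"
            f" (dropped: {d['n_dropped']})",
            f"  lambda_GC = {d['lambda_gc']:.3f}   "
            f"Bonferroni -log10(p) threshold (alpha={alpha:g}) = "
            f"{d['bonferroni_threshold']:.2f}",
        ]
        if self.varcomp is not None:
            lines.append(
                f"  REML null: sigma_g2={self.varcomp.sigma_g2:.4g} "
                f"sigma_e2={self.varcomp.sigma_e2:.4g} h2={self.varcomp.h2:.3f}"
            )
        best = self.scan.nlargest(top, "score")
        lines.append("  top markers:")
        for _, r in best.iterrows():
            loc = (
                f" chr{int(r['chromosome'])}:{int(r['position_bp'])}"
                if "chromosome" in self.scan.columns
                else ""
            )
            lines.append(
                f"    {r['marker_id']}{loc}  effect={r['effect']:+.3f} "
                f"se={r['se']:.3f} -log10p={r['score']:.2f}"
            )
        return "\n".join(lines)


def scan(
    panel: DosagePanel,
    trait: pd.Series,
    model: str | GwasModelSpec = "naive",
    kinship: RelationshipMatrix | None = None,
    covariates: StructureCovariates | None = None,
    marker_map: MarkerMap | None = None,
    method: str = "p3d",
) -> GwasResults:
    """Functional wrapper: build a :class:`DosageGwas` and fit it."""
    return DosageGwas(
        trait, panel, model, kinship=kinship, covariates=covariates,
        marker_map=marker_map,
    ).fit(method=method)


def significant_hits(results: GwasResults, threshold: float) -> pd.DataFrame:
    """Markers with score strictly above the -log10(p) threshold; the
    per-trait top marker is flagged."""
    hits = results.scan[results.scan["score"] > threshold].copy()
    hits = hits.sort_values("score", ascending=False, ignore_index=True)
    hits["trait"] = results.model.trait_name
    hits["model"] = results.model.spec.kind.value
    hits["top_hit"] = False
    if len(hits):
        hits.loc[0, "top_hit"] = True
    return hits
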