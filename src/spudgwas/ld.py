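"""Linkage-disequilibrium decay from dosage correlations.

LD between two markers is the squared Pearson correlation r^2 of their
dosage vectors (0..4) over the samples called in both.  Pairs are always
intra-chromosomal and are partitioned by genome region relative to the
pericentromeric heterochromatin block: short arm, long arm, euchromatin
(both arms), heterochromatin, or the whole chromosome.

Decay is summarised by fitting the 90th-percentile of r^2 against physical
distance (Mb) with nonlinear quantile regression (pinball loss), using by
default the Hill & Weir drift expectation of r^2 with C = a*d and a fitted
amplitude, or alternatively a simple exponential r0*exp(-d/delta).  From
the fitted curve three estimators are read off: r2_max90 (the fitted value
at the smallest observed distance), LD_1/2max,90 (distance at half of
r2_max90) and LD_1/10,90 (distance at r^2 = 0.1).  A mean-r^2 least-squares
variant of the same expectation is provided for comparison with studies
that model average LD.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from itertools import product
from typing import Callable

import numpy as np
import pandas as pd
from scipy import optimize

from .panel import DosagePanel, HetBoundaries, MarkerMap, PanelError, Region

log = logging.getLogger(__name__)

PARTITIONS = ("short", "long", "euchromatin", "het", "whole")

_PARTITION_REGIONS = {
    "short": {Region.SHORT_ARM.value},
    "long": {Region.LONG_ARM.value},
    "euchromatin": {Region.SHORT_ARM.value, Region.LONG_ARM.value},
    "het": {Region.HETEROCHROMATIN.value},
    "whole": {r.value for r in Region},
}


# ---------------------------------------------------------------------------
# region assignment


def assign_region(mmap: MarkerMap, bounds: HetBoundaries) -> MarkerMap:
    """Classify each marker as short arm / heterochromatin / long arm.

    Boundaries are inclusive to heterochromatin; positions below het_start
    are short arm, above het_end long arm.  Chromosomes without a boundary
    record stay UNASSIGNED (with a warning).  A pericentric chromosome
    (het_start = 1) simply has no short-arm markers.
    """
    t = mmap.table.copy()
    regions = []
    missing_chroms = set()
    for chrom, pos in zip(t["chromosome"], t["position_bp"]):
        iv = bounds.interval(int(chrom))
        if iv is None:
            missing_chroms.add(int(chrom))
            regions.append(Region.UNASSIGNED.value)
        elif pos < iv[0]:
            regions.append(Region.SHORT_ARM.value)
        elif pos > iv[1]:
            regions.append(Region.LONG_ARM.value)
        else:
            regions.append(Region.HETEROCHROMATIN.value)
    if missing_chroms:
        warnings.warn(
            f"no heterochromatin boundaries for chromosomes {sorted(missing_chroms)}; "
            "their markers are UNASSIGNED", stacklevel=2,
        )
    t["region"] = regions
    return MarkerMap(t)


# ---------------------------------------------------------------------------
# pairwise r^2


@dataclass
class LdPairs:
    """Intra-chromosomal marker pairs with distance (Mb) and r^2."""

    table: pd.DataFrame  # chromosome, marker_a, marker_b, distance_mb, r2, n_shared
    partition: str
    n_skipped: int = 0  # pairs dropped for zero variance or too few shared samples

    def __len__(self) -> int:
        return len(self.table)

    @property
    def distances(self) -> np.ndarray:
        return self.table["distance_mb"].to_numpy()

    @property
    def r2(self) -> np.ndarray:
        return self.table["r2"].to_numpy()


def _pairwise_complete_r2(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """r^2 and shared-sample counts between rows of X (NaN = missing)."""
    M = (~np.isnan(X)).astype(float)
    Z = np.where(np.isnan(X), 0.0, X)
    n = M @ M.T
    Sx = Z @ M.T  # Sx[i, j] = sum over shared of x_i
    Sxx = (Z * Z) @ M.T
    Sxy = Z @ Z.T
    with np.errstate(invalid="ignore", divide="ignore"):
        cov = n * Sxy - Sx * Sx.T
        varx = n * Sxx - Sx**2
        denom = varx * varx.T
        r2 = np.where(denom > 0, cov**2 / denom, np.nan)
    return r2, n


def pairwise_r2(
    panel: DosagePanel,
    mmap: MarkerMap,
    partition: str = "whole",
    chromosome: int | str = "all",
    min_shared: int = 30,
) -> LdPairs:
    """All intra-chromosomal marker pairs of a genome partition.

    'euchromatin' pools short- and long-arm markers (cross-arm pairs kept,
    still within a chromosome).  Pairs with fewer than ``min_shared``
    jointly-called samples or with a zero-variance marker are skipped and
    counted.
    """
    if partition not in PARTITIONS:
        raise ValueError(f"partition must be one of {PARTITIONS}")
    ann = mmap.aligned_to(panel.marker_ids)
    wanted = _PARTITION_REGIONS[partition]
    in_part = ann["region"].isin(wanted).to_numpy()
    chroms = (
        sorted(ann.loc[in_part, "chromosome"].unique())
        if chromosome == "all"
        else [int(chromosome)]
    )
    X = panel.values
    frames = []
    skipped = 0
    for chrom in chroms:
        sel = in_part & (ann["chromosome"] == chrom).to_numpy()
        idx = np.nonzero(sel)[0]
        if idx.size < 2:
            continue
        pos = ann.loc[sel, "position_bp"].to_numpy()
        ids = ann.loc[sel, "marker_id"].to_numpy()
        r2, nshared = _pairwise_complete_r2(X[idx])
        iu = np.triu_indices(idx.size, k=1)
        r2v, nv = r2[iu], nshared[iu]
        dist = np.abs(pos[iu[0]] - pos[iu[1]]) / 1e6
        ok = (~np.isnan(r2v)) & (nv >= min_shared)
        skipped += int((~ok).sum())
        frames.append(
            pd.DataFrame(
                {
                    "chromosome": chrom,
                    "marker_a": ids[iu[0][ok]],
                    "marker_b": ids[iu[1][ok]],
                    "distance_mb": dist[ok],
                    "r2": np.clip(r2v[ok], 0.0, 1.0),
                    "n_shared": nv[ok].astype(int),
                }
            )
        )
    table = (
        pd.concat(frames, ignore_index=True)
        if frames
        else pd.DataFrame(
            columns=["chromosome", "marker_a", "marker_b", "distance_mb", "r2", "n_shared"]
        )
    )
    return LdPairs(table, partition, skipped)


# ---------------------------------------------------------------------------
# decay forms


def hill_weir_r2(C: np.ndarray, n_eff: float) -> np.ndarray:
    """Drift-recombination expectation of r^2 at population recombination
    parameter C, for n_eff sampled individuals."""
    C = np.asarray(C, dtype=float)
    a = (10.0 + C) / ((2.0 + C) * (11.0 + C))
    b = ((3.0 + C) * (12.0 + 12.0 * C + C**2)) / (n_eff * (2.0 + C) * (11.0 + C))
    return a * (1.0 + b)


def _curve(form: str, params: np.ndarray, n_eff: float) -> Callable[[np.ndarray], np.ndarray]:
    if form == "hill_weir":
        a, amp = params

        def f(d: np.ndarray) -> np.ndarray:
            return amp * hill_weir_r2(a * np.asarray(d, dtype=float), n_eff)

    elif form == "exponential":
        r0, delta = params

        def f(d: np.ndarray) -> np.ndarray:
            return r0 * np.exp(-np.asarray(d, dtype=float) / delta)

    else:
        raise ValueError(f"unknown decay form {form!r}")
    return f


def _pinball(resid: np.ndarray, tau: float) -> float:
    return float(np.where(resid >= 0, tau * resid, (tau - 1.0) * resid).sum())


# ---------------------------------------------------------------------------
# model object


@dataclass
class LdDecayResults:
    """Fitted decay curve for one genome partition."""

    partition: str
    form: str
    tau: float
    params: np.ndarray
    n_eff: float
    n_pairs: int
    loss: float
    d_min: float
    d_max: float
    r2_max90: float = np.nan
    ld_half_max90: float | None = None
    ld_tenth90: float | None = None

    def curve(self, d: np.ndarray) -> np.ndarray:
        return _curve(self.form, self.params, self.n_eff)(d)

    def to_dict(self) -> dict:
        return {
            "partition": self.partition,
            "form": self.form,
            "tau": self.tau,
            "params": [float(p) for p in self.params],
            "n_pairs": self.n_pairs,
            "r2_max90": None if np.isnan(self.r2_max90) else float(self.r2_max90),
            "ld_half_max90": self.ld_half_max90,
            "ld_tenth90": self.ld_tenth90,
        }

    def summary(self) -> str:
        half = "undefined" if self.ld_half_max90 is None else f"{self.ld_half_max90:.2f} Mb"
        tenth = "undefined" if self.ld_tenth90 is None else f"{self.ld_tenth90:.2f} Mb"
        return (
            f"LD decay [{self.partition}] form={self.form} tau={self.tau:g} "
            f"pairs={self.n_pairs}\n"
            f"  r2_max,{int(self.tau * 100)} = {self.r2_max90:.2f}   "
            f"LD_1/2max = {half}   LD_1/10 = {tenth}"
        )


class LdDecay:
    """Quantile-regression decay model over a set of LD pairs.

    Minimizes the pinball (check) loss at level ``tau`` over the parameters
    of the decay form, via a deterministic multi-start parameter grid
    followed by Nelder-Mead refinement.  Co-located pairs (distance 0) are
    excluded from the fit.
    """

    def __init__(
        self,
        pairs: LdPairs,
        tau: float = 0.90,
        form: str = "hill_weir",
        n_eff: float | None = None,
    ) -> None:
        if form not in ("hill_weir", "exponential"):
            raise ValueError("form must be 'hill_weir' or 'exponential'")
        keep = pairs.distances > 0
        self.d = pairs.distances[keep]
        self.r2 = pairs.r2[keep]
        self.partition = pairs.partition
        self.tau = float(tau)
        self.form = form
        if n_eff is None:
            n_eff = float(np.median(pairs.table["n_shared"])) if len(pairs) else 100.0
        self.n_eff = float(n_eff)
        if self.d.size < 2:
            raise PanelError("need at least 2 positive-distance pairs to fit decay")
        if self.d.size < 200:
            warnings.warn(
                f"only {self.d.size} pairs; decay fit may be unstable", stacklevel=2
            )

    def _objective(self, x: np.ndarray) -> float:
        params = self._transform(x)
        f = _curve(self.form, params, self.n_eff)
        return _pinball(self.r2 - f(self.d), self.tau)

    def _transform(self, x: np.ndarray) -> np.ndarray:
        if self.form == "hill_weir":
            return np.array([np.exp(x[0]), np.clip(np.exp(x[1]), 1e-6, 4.0)])
        return np.array([np.clip(np.exp(x[0]), 1e-6, 1.0), np.exp(x[1])])

    def fit(self) -> LdDecayResults:
        d_max = float(self.d.max())
        if self.form == "hill_weir":
            grid_a = np.log(np.logspace(-3, 2, 11))
            grid_b = np.log(np.array([0.25, 0.5, 1.0, 1.5, 2.5]))
        else:
            grid_a = np.log(np.array([0.05, 0.1, 0.2, 0.4, 0.8, 1.0]))
            grid_b = np.log(np.logspace(-2, np.log10(5 * d_max), 9))
        starts = sorted(product(grid_a, grid_b))
        best: optimize.OptimizeResult | None = None
        trace = []
        for x0 in starts:
            res = optimize.minimize(
                self._objective, np.array(x0), method="Nelder-Mead",
                options={"xatol": 1e-6, "fatol": 1e-9, "maxiter": 600},
            )
            trace.append(float(res.fun))
            if np.isfinite(res.fun) and (best is None or res.fun < best.fun - 1e-12):
                best = res
        if best is None:
            raise RuntimeError(f"quantile decay fit failed to converge; losses: {trace}")
        params = self._transform(best.x)
        out = LdDecayResults(
            partition=self.partition, form=self.form, tau=self.tau,
            params=params, n_eff=self.n_eff, n_pairs=int(self.d.size),
            loss=float(best.fun), d_min=float(self.d.min()), d_max=d_max,
        )
        r2m, half, tenth = decay_estimators(out)
        out.r2_max90, out.ld_half_max90, out.ld_tenth90 = r2m, half, tenth
        return out


def fit_quantile_decay(
    pairs: LdPairs, tau: float = 0.90, form: str = "hill_weir",
    n_eff: float | None = None,
) -> LdDecayResults:
    """Functional wrapper over :class:`LdDecay`."""
    return LdDecay(pairs, tau=tau, form=form, n_eff=n_eff).fit()


def _solve_level(
    f: Callable[[np.ndarray], np.ndarray], level: float, d_lo: float, d_hi: float
) -> float | None:
    """Smallest d in [d_lo, d_hi] with f(d) = level, for non-increasing f."""
    f_lo = float(f(np.array([d_lo]))[0])
    f_hi = float(f(np.array([d_hi]))[0])
    if f_lo <= level or f_hi > level:
        return None
    return float(optimize.brentq(lambda d: float(f(np.array([d]))[0]) - level,
                                 d_lo, d_hi, xtol=1e-10))


def decay_estimators(
    fit: LdDecayResults, d_min: float | None = None
) -> tuple[float, float | None, float | None]:
    """(r2_max90, LD_1/2max,90, LD_1/10,90) from a fitted curve.

    r2_max90 is the fitted value at the smallest observed pair distance (not
    extrapolated to zero).  Each crossing is solved by root bracketing and
    reported as undefined (None) when the curve never reaches the level
    within 10x the observed distance range.
    """
    if d_min is None:
        d_min = fit.d_min
    f = _curve(fit.form, fit.params, fit.n_eff)
    r2_max = float(f(np.array([d_min]))[0])
    d_far = 10.0 * max(fit.d_max, d_min)
    half = _solve_level(f, r2_max / 2.0, d_min, d_far)
    tenth = _solve_level(f, 0.1, d_min, d_far) if r2_max > 0.1 else None
    return r2_max, half, tenth


# ---------------------------------------------------------------------------
# mean-r^2 nonlinear regression (average-LD comparator)


def fit_mean_decay(
    pairs: LdPairs,
    n_eff: float | None = None,
    fit_amplitude: bool = True,
) -> dict:
    """Least-squares fit of the Hill-Weir expectation to pointwise mean r^2.

    Returns the fitted parameters and the distance at which the fitted mean
    reaches 0.1 (None when the curve never crosses it).
    """
    keep = pairs.distances > 0
    d, r2 = pairs.distances[keep], pairs.r2[keep]
    if d.size < 2:
        raise PanelError("need at least 2 positive-distance pairs")
    if n_eff is None:
        n_eff = float(np.median(pairs.table["n_shared"])) if len(pairs) else 100.0

    if fit_amplitude:
        def model(dd, log_a, log_amp):
            return np.exp(log_amp) * hill_weir_r2(np.exp(log_a) * dd, n_eff)
        p0s = [(la, lam) for la in np.log([0.01, 0.1, 1.0, 10.0]) for lam in (np.log(0.5), 0.0)]
    else:
        def model(dd, log_a):
            return hill_weir_r2(np.exp(log_a) * dd, n_eff)
        p0s = [(la,) for la in np.log([0.01, 0.1, 1.0, 10.0])]

    best_p, best_sse = None, np.inf
    for p0 in p0s:
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", optimize.OptimizeWarning)
                popt, _ = optimize.curve_fit(model, d, r2, p0=p0, maxfev=5000)
        except RuntimeError:
            continue
        sse = float(((r2 - model(d, *popt)) ** 2).sum())
        if sse < best_sse:
            best_p, best_sse = popt, sse
    if best_p is None:
        raise RuntimeError("mean-decay least-squares fit failed to converge")

    def f(dd: np.ndarray) -> np.ndarray:
        return model(np.asarray(dd, dtype=float), *best_p)

    d_lo, d_far = float(d.min()), 10.0 * float(d.max())
    tenth = _solve_level(f, 0.1, d_lo, d_far)
    if tenth is None and float(f(np.array([d_lo]))[0]) > 0.1:
        tenth = None
    out = {
        "form": "hill_weir_mean",
        "params": [float(np.exp(p)) for p in best_p],
        "n_eff": float(n_eff),
        "n_pairs": int(d.size),
        "sse": best_sse,
        "ld_tenth_mean": tenth,
    }
    return out


# ---------------------------------------------------------------------------
# plot-ready binned grid


def ld_grid(pairs: LdPairs, bin_mb: float = 1.0) -> pd.DataFrame:
    """Plot-ready binned LD table: mean r^2 and pair count per distance bin.

    Pairs are binned per chromosome by floor(distance / bin_mb); the cell
    counts sum to the total pair count (conservation), so the table can be
    rendered directly as a decay heatmap/profile.
    """
    if bin_mb <= 0:
        raise ValueError("bin_mb must be positive")
    t = pairs.table
    if t.empty:
        return pd.DataFrame(columns=["chromosome", "bin", "bin_start_mb", "mean_r2", "n_pairs"])
    d_bin = np.floor(t["distance_mb"].to_numpy() / bin_mb).astype(int)
    g = (
        t.assign(bin=d_bin)
        .groupby(["chromosome", "bin"])
        .agg(mean_r2=("r2", "mean"), n_pairs=("r2", "size"))
        .reset_index()
    )
    g["bin_start_mb"] = g["bin"] * bin_mb
    return g[["chromosome", "bin", "bin_start_mb", "mean_r2", "n_pairs"]]
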