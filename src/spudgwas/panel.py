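"""Tetraploid SNP dosage panels: containers, file I/O, QC filters, diversity statistics.

The central container is :class:`DosagePanel`, a markers x samples matrix of
allele dosages (0..4 for an autotetraploid) with an explicit missing-data mask.
Marker metadata live in :class:`MarkerMap` (chromosome, 1-based bp position,
and a genome-region class derived from per-chromosome pericentromeric
heterochromatin boundaries, :class:`HetBoundaries`).  Phenotypes (per-clone
BLUEs) are held in :class:`TraitTable`.

QC follows standard SNP-array practice for association panels: markers are
excluded when missing-data rate reaches 20% or minor allele frequency falls
to 5% (both boundaries excluded from the retained set).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

#: sentinel used for missing dosage calls in all text formats
MISSING_TOKEN = "NA"


class PanelError(ValueError):
    """Invalid panel content or structure."""


class PanelFormatError(PanelError):
    """A file could not be parsed as the expected format."""


class UndefinedFrequencyError(PanelError):
    """Allele frequency requested for a marker with no non-missing calls."""


class Region(str, Enum):
    """Genome-region class of a marker relative to the pericentromeric block."""

    SHORT_ARM = "SHORT_ARM"
    HETEROCHROMATIN = "HETEROCHROMATIN"
    LONG_ARM = "LONG_ARM"
    UNASSIGNED = "UNASSIGNED"


class PicFormula(str, Enum):
    """Variant of the polymorphic-information-content statistic.

    BOTSTEIN subtracts the chance of drawing indistinguishable heterozygote
    pairs and caps at 0.375 for biallelic markers; HETEROZYGOSITY is expected
    heterozygosity 1 - sum(p^2), capping at 0.5.
    """

    BOTSTEIN = "BOTSTEIN"
    HETEROZYGOSITY = "HETEROZYGOSITY"


def _check_unique(ids: np.ndarray, what: str) -> None:
    if len(ids) != len(set(ids.tolist())):
        seen: set[str] = set()
        for x in ids.tolist():
            if x in seen:
                raise PanelError(f"duplicate {what} identifier: {x!r}")
            seen.add(x)


@dataclass
class DosagePanel:
    """Markers x samples matrix of tetraploid allele dosages.

    Parameters
    ----------
    marker_ids, sample_ids : arrays of unique string identifiers.
    dosages : int8 array, shape (n_markers, n_samples); entries are only
        meaningful where ``missing`` is False.
    missing : boolean array, same shape; True marks a missing call.
    ploidy : fixed at 4 for autotetraploids.
    """

    marker_ids: np.ndarray
    sample_ids: np.ndarray
    dosages: np.ndarray
    missing: np.ndarray
    ploidy: int = 4

    def __post_init__(self) -> None:
        self.marker_ids = np.asarray(self.marker_ids, dtype=object)
        self.sample_ids = np.asarray(self.sample_ids, dtype=object)
        self.dosages = np.asarray(self.dosages, dtype=np.int8)
        self.missing = np.asarray(self.missing, dtype=bool)
        _check_unique(self.marker_ids, "marker")
        _check_unique(self.sample_ids, "sample")
        m, n = len(self.marker_ids), len(self.sample_ids)
        if self.dosages.shape != (m, n) or self.missing.shape != (m, n):
            raise PanelError(
                f"dosage matrix shape {self.dosages.shape} does not match "
                f"{m} markers x {n} samples"
            )
        obs = self.dosages[~self.missing]
        if obs.size and (obs.min() < 0 or obs.max() > self.ploidy):
            raise PanelError(
                f"dosage outside [0, {self.ploidy}] found: {int(obs.min())}..{int(obs.max())}"
            )

    # -- construction ------------------------------------------------------

    @classmethod
    def from_values(
        cls,
        marker_ids: Sequence[str],
        sample_ids: Sequence[str],
        values: np.ndarray,
        ploidy: int = 4,
    ) -> "DosagePanel":
        """Build a panel from a float matrix using NaN for missing calls."""
        values = np.asarray(values, dtype=float)
        missing = np.isnan(values)
        dosages = np.where(missing, 0, values)
        if not np.allclose(dosages, np.round(dosages)):
            raise PanelError("non-integer dosage value supplied")
        return cls(
            np.asarray(marker_ids, dtype=object),
            np.asarray(sample_ids, dtype=object),
            np.round(dosages).astype(np.int8),
            missing,
            ploidy,
        )

    # -- basic properties --------------------------------------------------

    @property
    def n_markers(self) -> int:
        return len(self.marker_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def values(self) -> np.ndarray:
        """Float copy of the dosage matrix with NaN at missing calls."""
        out = self.dosages.astype(float)
        out[self.missing] = np.nan
        return out

    def marker_index(self, marker_id: str) -> int:
        idx = np.nonzero(self.marker_ids == marker_id)[0]
        if idx.size == 0:
            raise KeyError(f"unknown marker {marker_id!r}")
        return int(idx[0])

    def subset_markers(self, keep: np.ndarray) -> "DosagePanel":
        """New panel with markers selected by boolean mask or index array."""
        keep = np.asarray(keep)
        return DosagePanel(
            self.marker_ids[keep],
            self.sample_ids,
            self.dosages[keep],
            self.missing[keep],
            self.ploidy,
        )

    def subset_samples(self, sample_ids: Sequence[str]) -> "DosagePanel":
        pos = {s: i for i, s in enumerate(self.sample_ids)}
        try:
            idx = np.array([pos[s] for s in sample_ids], dtype=int)
        except KeyError as e:
            raise PanelError(f"unknown sample identifier {e.args[0]!r}") from e
        return DosagePanel(
            self.marker_ids,
            np.asarray(list(sample_ids), dtype=object),
            self.dosages[:, idx],
            self.missing[:, idx],
            self.ploidy,
        )

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, index=self.marker_ids, columns=self.sample_ids)
        df.index.name = "marker_id"
        return df


# ---------------------------------------------------------------------------
# file I/O


def read_dosage(path: str | Path, ploidy: int = 4) -> DosagePanel:
    """Read a dosage TSV: header row of sample ids, first column marker ids,
    entries in {0..ploidy, NA}.  Raises :class:`PanelFormatError` naming the
    offending marker and sample on any out-of-range or non-integer entry."""
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str, keep_default_na=False)
    marker_ids = df.index.to_numpy(dtype=object)
    sample_ids = df.columns.to_numpy(dtype=object)
    raw = df.to_numpy(dtype=object)
    is_na = raw == MISSING_TOKEN
    num = pd.to_numeric(pd.Series(raw[~is_na].ravel()), errors="coerce").to_numpy()
    flat_bad = np.isnan(num) | (num != np.round(num)) | (num < 0) | (num > ploidy)
    if flat_bad.any():
        bad_pos = np.nonzero(~is_na)
        k = int(np.nonzero(flat_bad)[0][0])
        i, j = bad_pos[0][k], bad_pos[1][k]
        raise PanelFormatError(
            f"invalid dosage {raw[i, j]!r} for marker {marker_ids[i]!r}, "
            f"sample {sample_ids[j]!r} (expected integer 0..{ploidy} or NA)"
        )
    values = np.full(raw.shape, np.nan)
    values[~is_na] = num
    panel = DosagePanel.from_values(marker_ids, sample_ids, values, ploidy)
    log.info("read dosage panel: %d markers x %d samples from %s",
             panel.n_markers, panel.n_samples, path)
    return panel


def write_dosage(panel: DosagePanel, path: str | Path) -> None:
    df = panel.to_frame()
    out = df.map(lambda v: MISSING_TOKEN if np.isnan(v) else str(int(v)))
    out.to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# per-marker statistics


def allele_frequencies(panel: DosagePanel) -> np.ndarray:
    """Alternative-allele frequency per marker over non-missing calls.

    p = sum(dosages) / (ploidy * n_called); NaN where every call is missing.
    """
    called = ~panel.missing
    n_called = called.sum(axis=1)
    total = np.where(called, panel.dosages, 0).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = total / (panel.ploidy * n_called)
    return np.where(n_called > 0, p, np.nan)


def allele_frequency(panel: DosagePanel, marker_id: str) -> float:
    p = allele_frequencies(panel)[panel.marker_index(marker_id)]
    if np.isnan(p):
        raise UndefinedFrequencyError(f"marker {marker_id!r} has no non-missing calls")
    return float(p)


def maf(panel: DosagePanel, marker_id: str) -> float:
    p = allele_frequency(panel, marker_id)
    return min(p, 1.0 - p)


def mafs(panel: DosagePanel) -> np.ndarray:
    p = allele_frequencies(panel)
    return np.minimum(p, 1.0 - p)


def missing_rate(panel: DosagePanel, marker_id: str) -> float:
    return float(panel.missing[panel.marker_index(marker_id)].mean())


def missing_rates(panel: DosagePanel) -> np.ndarray:
    return panel.missing.mean(axis=1)


def filter_markers(
    panel: DosagePanel, max_missing: float = 0.20, min_maf: float = 0.05
) -> DosagePanel:
    """Retain markers with missing_rate < max_missing AND maf > min_maf.

    Both boundaries are excluded: a marker at exactly 20% missing or exactly
    5% MAF is removed.  All-missing markers are removed.  Returns a new panel;
    an empty result only warns.
    """
    if not (0 <= max_missing <= 1 and 0 <= min_maf <= 1):
        raise ValueError("thresholds must lie in [0, 1]")
    miss = missing_rates(panel)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        m = mafs(panel)
    keep = (miss < max_missing) & np.where(np.isnan(m), False, m > min_maf)
    out = panel.subset_markers(keep)
    log.info("filter_markers: retained %d of %d markers (max_missing=%g, min_maf=%g)",
             out.n_markers, panel.n_markers, max_missing, min_maf)
    if out.n_markers == 0:
        warnings.warn("no markers pass the QC thresholds", stacklevel=2)
    return out


def pic(
    panel: DosagePanel,
    marker_id: str,
    formula: PicFormula | str = PicFormula.HETEROZYGOSITY,
) -> float:
    """Polymorphic information content of a biallelic marker."""
    p = allele_frequency(panel, marker_id)
    return pic_from_frequency(p, formula)


def pic_from_frequency(
    p: float | np.ndarray, formula: PicFormula | str = PicFormula.HETEROZYGOSITY
) -> float | np.ndarray:
    formula = PicFormula(formula)
    q = 1.0 - np.asarray(p, dtype=float)
    p = np.asarray(p, dtype=float)
    het = 1.0 - (p**2 + q**2)
    if formula is PicFormula.HETEROZYGOSITY:
        out = het
    else:
        out = het - 2.0 * p**2 * q**2
    out = np.clip(out, 0.0, None)  # guard against float cancellation near p in {0, 1}
    return float(out) if out.ndim == 0 else out


def pic_values(
    panel: DosagePanel, formula: PicFormula | str = PicFormula.HETEROZYGOSITY
) -> np.ndarray:
    return pic_from_frequency(allele_frequencies(panel), formula)


def duplicate_pairs(panel: DosagePanel, threshold: float = 0.99) -> pd.DataFrame:
    """Sample pairs whose Gower similarity strictly exceeds ``threshold``.

    Near-duplicate clones (similarity > 0.99 in the field panel this mirrors)
    typically indicate mislabelled or re-submitted material; one member of
    each pair is usually dropped before analysis.
    """
    from .relatedness import gower_kinship  # local import: avoids module cycle

    K = gower_kinship(panel)
    n = len(K.sample_ids)
    iu = np.triu_indices(n, k=1)
    sim = K.S[iu]
    hit = np.nonzero(sim > threshold)[0]
    return pd.DataFrame(
        {
            "sample_a": K.sample_ids[iu[0][hit]],
            "sample_b": K.sample_ids[iu[1][hit]],
            "similarity": sim[hit],
        }
    ).sort_values("similarity", ascending=False, ignore_index=True)


# ---------------------------------------------------------------------------
# marker map and heterochromatin boundaries


@dataclass
class MarkerMap:
    """Per-marker chromosome and 1-based bp position, plus region class."""

    table: pd.DataFrame  # columns: marker_id, chromosome, position_bp, region

    def __post_init__(self) -> None:
        t = self.table.copy()
        required = {"marker_id", "chromosome", "position_bp"}
        if not required.issubset(t.columns):
            raise PanelFormatError(f"marker map needs columns {sorted(required)}")
        t["chromosome"] = t["chromosome"].astype(int)
        t["position_bp"] = t["position_bp"].astype(int)
        if (t["position_bp"] < 1).any():
            raise PanelError("marker positions must be 1-based (>= 1)")
        if "region" not in t.columns:
            t["region"] = Region.UNASSIGNED.value
        t["region"] = t["region"].map(lambda r: Region(r).value)
        _check_unique(t["marker_id"].to_numpy(dtype=object), "marker")
        self.table = t.reset_index(drop=True)

    @classmethod
    def from_positions(
        cls, marker_ids: Sequence[str], chromosomes: Sequence[int], positions: Sequence[int]
    ) -> "MarkerMap":
        return cls(
            pd.DataFrame(
                {
                    "marker_id": list(marker_ids),
                    "chromosome": list(chromosomes),
                    "position_bp": list(positions),
                }
            )
        )

    def aligned_to(self, marker_ids: Sequence[str]) -> pd.DataFrame:
        """Rows reordered to a panel's marker list (all must be present)."""
        t = self.table.set_index("marker_id")
        missing = [m for m in marker_ids if m not in t.index]
        if missing:
            raise PanelError(f"{len(missing)} markers absent from map, e.g. {missing[0]!r}")
        return t.loc[list(marker_ids)].reset_index()


@dataclass
class HetBoundaries:
    """Pericentromeric heterochromatin interval per chromosome (1-based, inclusive)."""

    table: pd.DataFrame  # columns: chromosome, het_start_bp, het_end_bp

    def __post_init__(self) -> None:
        t = self.table.copy()
        required = {"chromosome", "het_start_bp", "het_end_bp"}
        if not required.issubset(t.columns):
            raise PanelFormatError(f"boundary table needs columns {sorted(required)}")
        for c in required:
            t[c] = t[c].astype(int)
        if t["chromosome"].duplicated().any():
            raise PanelError("one boundary record per chromosome is required")
        if (t["het_start_bp"] > t["het_end_bp"]).any():
            raise PanelError("het_start_bp must be <= het_end_bp")
        if (t["het_start_bp"] < 1).any():
            raise PanelError("boundaries are 1-based (>= 1)")
        self.table = t.reset_index(drop=True)

    def interval(self, chromosome: int) -> tuple[int, int] | None:
        row = self.table[self.table["chromosome"] == chromosome]
        if row.empty:
            return None
        return int(row["het_start_bp"].iloc[0]), int(row["het_end_bp"].iloc[0])


def read_marker_map(path: str | Path) -> MarkerMap:
    return MarkerMap(pd.read_csv(path, sep="\t"))


def write_marker_map(mmap: MarkerMap, path: str | Path) -> None:
    mmap.table.to_csv(path, sep="\t", index=False)


def read_het_boundaries(path: str | Path) -> HetBoundaries:
    return HetBoundaries(pd.read_csv(path, sep="\t"))


def write_het_boundaries(bounds: HetBoundaries, path: str | Path) -> None:
    bounds.table.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# phenotypes


@dataclass
class TraitTable:
    """Per-sample trait BLUEs; rows indexed by sample id, one column per trait."""

    table: pd.DataFrame

    def __post_init__(self) -> None:
        t = self.table.copy()
        t.index = t.index.astype(str)
        t.index.name = "sample_id"
        _check_unique(t.index.to_numpy(dtype=object), "sample")
        self.table = t.astype(float)

    @property
    def trait_names(self) -> list[str]:
        return list(self.table.columns)

    @property
    def sample_ids(self) -> np.ndarray:
        return self.table.index.to_numpy(dtype=object)

    def trait(self, name: str) -> pd.Series:
        return self.table[name]

    def aligned_to(self, panel: DosagePanel) -> "TraitTable":
        """Restrict to the panel's samples, preserving panel order."""
        common = [s for s in panel.sample_ids if s in self.table.index]
        if not common:
            raise PanelError("no phenotyped samples overlap the panel")
        return TraitTable(self.table.loc[common])


def read_traits(path: str | Path) -> TraitTable:
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=[MISSING_TOKEN])
    return TraitTable(df)


def write_traits(traits: TraitTable, path: str | Path) -> None:
    traits.table.to_csv(path, sep="\t", na_rep=MISSING_TOKEN)
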