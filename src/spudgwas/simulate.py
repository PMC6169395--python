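"""Synthetic autotetraploid SNP panels with known truth.

The generator emulates the statistical structure a potato-style association
panel presents to the estimators in this package:

* weak subpopulation divergence — ancestral allele frequencies U(0.1, 0.9)
  diverged per subpopulation under the Balding-Nichols beta model with a
  chosen Fst;
* strong family kinship — panel members are offspring of listed (or
  auto-generated) tetrasomic crosses between founders, with random bivalent
  pairing and Poisson crossovers (1 cM per euchromatic Mb, no double
  reduction);
* distance-dependent LD — founder haplotype alleles are thresholded from a
  latent Gaussian AR(1) whose correlation decays as exp(-d/decay_scale_mb),
  which preserves every marker's allele frequency exactly while giving
  monotone-decaying founder LD; the latent correlation is held at 1 across
  the pericentromeric heterochromatin block, so LD does not decay there
  (recombination is also suppressed inside the block);
* additive quantitative traits — per-trait optional dosage QTL, a polygenic
  background drawn with covariance sigma_g^2 * K (K the Gower kinship of
  the simulated panel), optional per-subpopulation mean shifts, and iid
  Gaussian residual noise.

All randomness flows from a single seed through named SeedSequence streams,
so each stage is independently reproducible.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .panel import (
    DosagePanel,
    HetBoundaries,
    MarkerMap,
    TraitTable,
    write_dosage,
    write_het_boundaries,
    write_marker_map,
    write_traits,
)

log = logging.getLogger(__name__)

_STREAMS = ("freqs", "haplotypes", "pedigree", "meiosis", "missing", "traits")


@dataclass
class TraitSpec:
    """One simulated quantitative trait.

    qtl entries are (marker index or marker id, additive effect per allele
    copy).  h2_polygenic is the polygenic share of the non-QTL variance:
    sigma_g^2 = h2/(1-h2) * residual_sd^2.  subpop_shift adds a fixed mean
    offset per subpopulation (confounding with structure).

    When qtl_var_fraction is set, the listed QTL effects are treated as
    relative weights and rescaled jointly so that the realized QTL term
    explains exactly that fraction of the QTL + polygenic + residual
    variance in the generated panel (the realized effects are recorded in
    the truth record).
    """

    name: str
    qtl: Sequence[tuple[int | str, float]] = ()
    h2_polygenic: float = 0.0
    residual_sd: float = 1.0
    subpop_shift: Sequence[float] | None = None
    qtl_var_fraction: float | None = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.h2_polygenic < 1.0):
            raise ValueError("h2_polygenic must lie in [0, 1)")
        if self.residual_sd < 0:
            raise ValueError("residual_sd must be non-negative")
        if self.qtl_var_fraction is not None:
            if not (0.0 < self.qtl_var_fraction < 1.0):
                raise ValueError("qtl_var_fraction must lie in (0, 1)")
            if not self.qtl:
                raise ValueError("qtl_var_fraction requires at least one QTL")


@dataclass
class FamilySpec:
    parent_a: str
    parent_b: str
    n_offspring: int


@dataclass
class SimConfig:
    """Study-condition parameters of the synthetic panel."""

    n_founders: int = 45
    n_samples: int = 300
    n_subpops: int = 3
    fst: float = 0.10
    n_chrom: int = 12
    markers_per_chrom: int = 170
    chrom_length_mb: float = 60.0
    het_fraction: float = 0.35
    het_marker_density: float = 0.4  # array density in het relative to arms
    decay_scale_mb: float = 2.0
    n_generations: int = 1
    offspring_per_family: int = 10
    families: Sequence[FamilySpec] | None = None
    traits: Sequence[TraitSpec] = field(default_factory=list)
    missing_rate: float = 0.0
    cm_per_mb: float = 1.0
    ploidy: int = 4
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_founders", "n_samples", "n_subpops", "n_chrom",
                     "markers_per_chrom", "n_generations", "offspring_per_family"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        if not (0.0 < self.fst < 1.0):
            raise ValueError("fst must lie in (0, 1)")
        if not (0.0 < self.het_fraction < 1.0):
            raise ValueError("het_fraction must lie in (0, 1)")
        if not (0.0 < self.het_marker_density <= 1.0):
            raise ValueError("het_marker_density must lie in (0, 1]")
        if not (0.0 <= self.missing_rate < 1.0):
            raise ValueError("missing_rate must lie in [0, 1)")

    @property
    def n_markers(self) -> int:
        return self.n_chrom * self.markers_per_chrom

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        if self.families is not None:
            d["families"] = [dataclasses.asdict(f) for f in self.families]
        d["traits"] = [dataclasses.asdict(t) for t in self.traits]
        for t in d["traits"]:
            t["qtl"] = [list(q) for q in t["qtl"]]
            if t["subpop_shift"] is not None:
                t["subpop_shift"] = list(t["subpop_shift"])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        d = dict(d)
        if d.get("families") is not None:
            d["families"] = [FamilySpec(**f) for f in d["families"]]
        d["traits"] = [
            TraitSpec(
                name=t["name"],
                qtl=[tuple(q) for q in t.get("qtl", [])],
                h2_polygenic=t.get("h2_polygenic", 0.0),
                residual_sd=t.get("residual_sd", 1.0),
                subpop_shift=t.get("subpop_shift"),
            )
            for t in d.get("traits", [])
        ]
        return cls(**d)


@dataclass
class SimPanel:
    """A simulated panel plus the truth needed to score every estimator."""

    panel: DosagePanel
    marker_map: MarkerMap
    het_bounds: HetBoundaries
    traits: TraitTable
    truth: dict
    config: SimConfig


# ---------------------------------------------------------------------------
# random streams


def _rngs(seed: int) -> dict[str, np.random.Generator]:
    children = np.random.SeedSequence(seed).spawn(len(_STREAMS))
    return {name: np.random.default_rng(c) for name, c in zip(_STREAMS, children)}


# ---------------------------------------------------------------------------
# genome layout


def make_genome(config: SimConfig, rng: np.random.Generator) -> tuple[MarkerMap, HetBoundaries]:
    """Random marker positions per chromosome with a centred het block.

    Marker density inside the pericentromeric block is reduced by
    ``het_marker_density`` relative to the arms, mirroring the euchromatin
    (gene) bias of transcript-derived SNP arrays.
    """
    L = config.chrom_length_mb * 1e6
    het_len = config.het_fraction * L
    het_start = int(round((L - het_len) / 2.0)) + 1
    het_end = int(round((L + het_len) / 2.0))
    f, d = config.het_fraction, config.het_marker_density
    het_share = f * d / (f * d + (1.0 - f))
    n_het = int(round(config.markers_per_chrom * het_share))
    n_arm = config.markers_per_chrom - n_het
    def draw_unique(lo: int, hi: int, n: int) -> np.ndarray:
        """n distinct integers in [lo, hi) without materializing the range."""
        out = np.unique(rng.integers(lo, hi, size=2 * n + 10))
        while out.size < n:
            out = np.unique(np.concatenate([out, rng.integers(lo, hi, size=n)]))
        return rng.permutation(out)[:n]

    rows = []
    for c in range(1, config.n_chrom + 1):
        short_len = het_start - 1
        arm_total = short_len + (int(L) - het_end)
        arm_off = draw_unique(0, arm_total, n_arm)
        pos_arm = np.where(arm_off < short_len, arm_off + 1,
                           arm_off - short_len + het_end + 1)
        pos_het = draw_unique(het_start, het_end + 1, n_het)
        pos = np.sort(np.concatenate([pos_arm, pos_het]))
        for j, p in enumerate(pos):
            rows.append((f"c{c}_m{j:04d}", c, int(p)))
    mmap = MarkerMap(pd.DataFrame(rows, columns=["marker_id", "chromosome", "position_bp"]))
    bounds = HetBoundaries(pd.DataFrame({
        "chromosome": list(range(1, config.n_chrom + 1)),
        "het_start_bp": het_start,
        "het_end_bp": het_end,
    }))
    return mmap, bounds


def _effective_positions_mb(pos_bp: np.ndarray, het: tuple[int, int],
                            cm_per_mb: float = 1.0) -> np.ndarray:
    """Map physical positions to cumulative euchromatic (recombining) length.

    Distance accumulated inside the het interval is zero, implementing both
    the suppressed recombination and the frozen founder LD of the block.
    """
    s, e = het
    pos = pos_bp.astype(float)
    eff = np.where(
        pos < s, pos,
        np.where(pos <= e, float(s), pos - (e - s)),
    )
    return eff / 1e6 * cm_per_mb


# ---------------------------------------------------------------------------
# founders


def founder_freqs(
    config: SimConfig, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Ancestral and per-subpopulation allele frequencies.

    Ancestral p ~ U(0.1, 0.9); each subpopulation draws
    p' ~ Beta(p(1-F)/F, (1-p)(1-F)/F) (Balding-Nichols), so E[p'] = p and
    Var[p'] = F p (1-p).  With a single subpopulation the ancestral
    frequencies are used unchanged.
    """
    m = config.n_markers
    p = rng.uniform(0.1, 0.9, size=m)
    if config.n_subpops == 1:
        return p, p[None, :].copy()
    F = config.fst
    a = p * (1 - F) / F
    b = (1 - p) * (1 - F) / F
    sub = rng.beta(a[None, :].repeat(config.n_subpops, axis=0),
                   b[None, :].repeat(config.n_subpops, axis=0))
    sub = np.clip(sub, 1e-4, 1 - 1e-4)
    return p, sub


def founder_haplotypes(
    config: SimConfig,
    subpop_freqs: np.ndarray,
    founder_subpop: np.ndarray,
    mmap: MarkerMap,
    bounds: HetBoundaries,
    rng: np.random.Generator,
) -> np.ndarray:
    """Founder haplotypes (n_founders, ploidy, n_markers) with spatial LD.

    Along each chromosome a latent standard-normal AR(1) chain with
    correlation exp(-delta_d / decay_scale_mb) between adjacent markers
    (delta_d measured in euchromatic Mb, hence 0 inside the het block) is
    thresholded at each marker's subpopulation frequency.
    """
    n_hap_total = config.n_founders * config.ploidy
    m = config.n_markers
    out = np.empty((n_hap_total, m), dtype=np.int8)
    hap_subpop = np.repeat(founder_subpop, config.ploidy)
    t = mmap.table
    for chrom in range(1, config.n_chrom + 1):
        sel = (t["chromosome"] == chrom).to_numpy()
        idx = np.nonzero(sel)[0]
        pos = t.loc[sel, "position_bp"].to_numpy()
        eff = _effective_positions_mb(pos, bounds.interval(chrom), 1.0)
        rho = np.exp(-np.diff(eff) / config.decay_scale_mb)
        z = np.empty((n_hap_total, idx.size))
        z[:, 0] = rng.standard_normal(n_hap_total)
        for j in range(1, idx.size):
            eps = rng.standard_normal(n_hap_total)
            z[:, j] = rho[j - 1] * z[:, j - 1] + np.sqrt(1 - rho[j - 1] ** 2) * eps
        thresh = stats.norm.ppf(subpop_freqs[hap_subpop][:, idx])
        out[:, idx] = (z < thresh).astype(np.int8)
    return out.reshape(config.n_founders, config.ploidy, m)


# ---------------------------------------------------------------------------
# meiosis


def make_gamete(
    haps: np.ndarray,
    genetic_pos_cm: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """One tetrasomic gamete (2 chromatids) from 4 parental homologs.

    The four homologs pair into two random bivalents; each bivalent
    recombines (Poisson crossovers along the genetic map) and contributes
    one chromatid.  Double reduction is not modelled.

    Parameters
    ----------
    haps : (4, m) homolog alleles for one chromosome.
    genetic_pos_cm : (m,) cumulative genetic positions (flat inside the
        pericentromeric block, where crossovers are suppressed).
    """
    perm = rng.permutation(4)
    length = float(genetic_pos_cm[-1] - genetic_pos_cm[0])
    gamete = np.empty((2, haps.shape[1]), dtype=haps.dtype)
    for b in range(2):
        a, c = perm[2 * b], perm[2 * b + 1]
        n_x = rng.poisson(length / 100.0)
        start = rng.integers(2)
        if n_x == 0:
            gamete[b] = haps[a] if start == 0 else haps[c]
            continue
        xpos = np.sort(rng.uniform(genetic_pos_cm[0], genetic_pos_cm[-1], size=n_x))
        seg = (start + np.searchsorted(xpos, genetic_pos_cm)) % 2
        gamete[b] = np.where(seg == 0, haps[a], haps[c])
    return gamete


# ---------------------------------------------------------------------------
# panel assembly


def _auto_families(
    config: SimConfig, founder_ids: list[str], founder_subpop: np.ndarray,
    rng: np.random.Generator,
) -> list[FamilySpec]:
    """Random within-subpopulation founder crosses covering n_samples."""
    fams: list[FamilySpec] = []
    total = 0
    by_pop: dict[int, list[str]] = {}
    for fid, sp in zip(founder_ids, founder_subpop):
        by_pop.setdefault(int(sp), []).append(fid)
    for pop, members in by_pop.items():
        if len(members) < 2:
            raise ValueError(f"subpopulation {pop} has fewer than 2 founders")
    pops = sorted(by_pop)
    k = 0
    while total < config.n_samples:
        pop = pops[k % len(pops)]
        pa, pb = rng.choice(by_pop[pop], size=2, replace=False)
        n_off = min(config.offspring_per_family, config.n_samples - total)
        fams.append(FamilySpec(str(pa), str(pb), int(n_off)))
        total += n_off
        k += 1
    return fams


def simulate_panel(config: SimConfig) -> SimPanel:
    """Generate a full synthetic panel; byte-identical for identical config."""
    rngs = _rngs(config.seed)
    mmap, bounds = make_genome(config, rngs["freqs"])
    anc, sub = founder_freqs(config, rngs["freqs"])
    founder_subpop = (np.arange(config.n_founders) * config.n_subpops
                      // config.n_founders)
    founder_ids = [f"F{i:03d}" for i in range(config.n_founders)]
    haps = founder_haplotypes(config, sub, founder_subpop, mmap, bounds,
                              rngs["haplotypes"])

    t = mmap.table
    chrom_slices = []
    genetic_pos = []
    for chrom in range(1, config.n_chrom + 1):
        sel = np.nonzero((t["chromosome"] == chrom).to_numpy())[0]
        chrom_slices.append(sel)
        eff = _effective_positions_mb(
            t.loc[sel, "position_bp"].to_numpy(), bounds.interval(chrom),
            config.cm_per_mb,
        )
        genetic_pos.append(eff)

    def cross(h_a: np.ndarray, h_b: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        """Offspring homologs (ploidy, m) from two parents' homolog sets."""
        child = np.empty((config.ploidy, config.n_markers), dtype=np.int8)
        for sel, gpos in zip(chrom_slices, genetic_pos):
            ga = make_gamete(h_a[:, sel], gpos, rng)
            gb = make_gamete(h_b[:, sel], gpos, rng)
            child[:, sel] = np.vstack([ga, gb])
        return child

    hap_store: dict[str, np.ndarray] = {fid: haps[i] for i, fid in enumerate(founder_ids)}
    subpop_of: dict[str, int] = {fid: int(sp) for fid, sp in zip(founder_ids, founder_subpop)}
    pedigree: list[dict] = []

    if config.families is not None and len(config.families) == 0:
        # founders-only panel of unrelated individuals
        if config.n_samples != config.n_founders:
            raise ValueError("founders-only panel requires n_samples == n_founders")
        sample_ids = founder_ids
    else:
        families = (
            list(config.families)
            if config.families is not None
            else _auto_families(config, founder_ids, founder_subpop, rngs["pedigree"])
        )
        current: list[str] = []
        counter = 0
        for gen in range(1, config.n_generations + 1):
            if gen > 1:
                # next generation: random within-subpop crosses of previous one
                prev = current
                by_pop: dict[int, list[str]] = {}
                for s in prev:
                    by_pop.setdefault(subpop_of[s], []).append(s)
                families = []
                total = 0
                pops = sorted(p for p in by_pop if len(by_pop[p]) >= 2)
                k = 0
                while total < config.n_samples and pops:
                    pop = pops[k % len(pops)]
                    pa, pb = rngs["pedigree"].choice(by_pop[pop], size=2, replace=False)
                    n_off = min(config.offspring_per_family, config.n_samples - total)
                    families.append(FamilySpec(str(pa), str(pb), int(n_off)))
                    total += n_off
                    k += 1
            current = []
            for fam in families:
                if fam.parent_a not in hap_store or fam.parent_b not in hap_store:
                    raise ValueError(
                        f"family references unknown parent: {fam.parent_a!r} x {fam.parent_b!r}"
                    )
                for _ in range(fam.n_offspring):
                    sid = f"S{counter:04d}"
                    counter += 1
                    hap_store[sid] = cross(hap_store[fam.parent_a],
                                           hap_store[fam.parent_b], rngs["meiosis"])
                    subpop_of[sid] = subpop_of[fam.parent_a]
                    pedigree.append({"id": sid, "parent_a": fam.parent_a,
                                     "parent_b": fam.parent_b, "generation": gen})
                    current.append(sid)
        sample_ids = current

    dosage = np.stack([hap_store[s].sum(axis=0) for s in sample_ids], axis=1).astype(np.int8)
    missing = np.zeros(dosage.shape, dtype=bool)
    if config.missing_rate > 0:
        missing = rngs["missing"].random(dosage.shape) < config.missing_rate
    panel = DosagePanel(
        t["marker_id"].to_numpy(dtype=object),
        np.asarray(sample_ids, dtype=object),
        dosage, missing, config.ploidy,
    )

    subpop_labels = {s: subpop_of[s] for s in sample_ids}
    trait_df, trait_truth = _make_traits(config, panel, dosage, sample_ids,
                                         subpop_labels, rngs["traits"])
    truth = {
        "subpop": subpop_labels,
        "founder_subpop": {f: int(s) for f, s in zip(founder_ids, founder_subpop)},
        "pedigree": pedigree,
        "ancestral_freqs": anc,
        "subpop_freqs": sub,
        "traits": trait_truth,
    }
    return SimPanel(panel, mmap, bounds, TraitTable(trait_df), truth, config)


def _make_traits(
    config: SimConfig,
    panel: DosagePanel,
    dosage: np.ndarray,
    sample_ids: list[str],
    subpop_labels: dict[str, int],
    rng: np.random.Generator,
) -> tuple[pd.DataFrame, dict]:
    n = len(sample_ids)
    cols = {}
    truth: dict[str, dict] = {}
    chol = None
    if any(ts.h2_polygenic > 0 for ts in config.traits):
        from .relatedness import gower_kinship

        K = gower_kinship(panel).S
        chol = np.linalg.cholesky(K + 1e-8 * np.eye(n))
    marker_pos = {m: i for i, m in enumerate(panel.marker_ids)}
    for ts in config.traits:
        sigma_e2 = ts.residual_sd**2
        sigma_g2 = (
            ts.h2_polygenic / (1.0 - ts.h2_polygenic) * sigma_e2
            if ts.h2_polygenic > 0 else 0.0
        )
        y = rng.standard_normal(n) * ts.residual_sd
        if sigma_g2 > 0:
            y = y + np.sqrt(sigma_g2) * (chol @ rng.standard_normal(n))
        qtl_list = []
        effects = [float(e) for _, e in ts.qtl]
        if ts.qtl and ts.qtl_var_fraction is not None:
            g = np.zeros(n)
            for (ref, _), e in zip(ts.qtl, effects):
                j = marker_pos[ref] if isinstance(ref, str) else int(ref)
                g = g + e * dosage[j].astype(float)
            var_g = float(np.var(g))
            if var_g <= 0:
                raise ValueError(f"trait {ts.name!r}: QTL dosages are monomorphic")
            f = ts.qtl_var_fraction
            target = f / (1.0 - f) * (sigma_g2 + sigma_e2)
            scale = np.sqrt(target / var_g)
            effects = [e * scale for e in effects]
        for (ref, _), effect in zip(ts.qtl, effects):
            j = marker_pos[ref] if isinstance(ref, str) else int(ref)
            y = y + effect * dosage[j].astype(float)
            qtl_list.append({"marker_id": str(panel.marker_ids[j]), "effect": float(effect)})
        if ts.subpop_shift is not None:
            shifts = np.asarray(ts.subpop_shift, dtype=float)
            y = y + shifts[[subpop_labels[s] for s in sample_ids]]
        cols[ts.name] = y
        truth[ts.name] = {
            "qtl": qtl_list,
            "sigma_g2": float(sigma_g2),
            "sigma_e2": float(sigma_e2),
            "h2_polygenic": ts.h2_polygenic,
            "subpop_shift": None if ts.subpop_shift is None else list(ts.subpop_shift),
        }
    df = pd.DataFrame(cols, index=pd.Index(sample_ids, name="sample_id"))
    return df, truth


def resample_traits(sim: SimPanel, seed: int) -> TraitTable:
    """Redraw the trait table of an existing simulated panel.

    Keeps the genotypes (and hence the kinship and QTL dosages) fixed while
    replicating the stochastic trait layers (polygenic draw, residual
    noise), which is the natural replication unit for scoring the
    variance-component estimator.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, sim.config.seed]))
    sample_ids = list(sim.panel.sample_ids)
    df, _ = _make_traits(sim.config, sim.panel, sim.panel.dosages, sample_ids,
                         sim.truth["subpop"], rng)
    return TraitTable(df)


# ---------------------------------------------------------------------------
# generator-implied LD truth (oracle for decay-estimator recovery)


def implied_quantile_r2(
    config: SimConfig,
    distances_mb: np.ndarray,
    tau: float = 0.90,
    n_freq_pairs: int = 2000,
    n_samples: int | None = None,
    seed: int = 12345,
) -> np.ndarray:
    """Generator-implied 90th-percentile r^2 at given distances.

    For a founders-only single-subpopulation panel the genotype correlation
    between two markers equals the haplotype correlation, which for the
    thresholded latent AR(1) is r = (P11 - p1 p2)/sqrt(p1 q1 p2 q2) with
    P11 the bivariate-normal orthant mass at latent correlation
    rho = exp(-d / decay_scale_mb).  The tau-quantile over random frequency
    pairs drawn from the generator's marginal frequency law gives the
    implied quantile curve, independent of any fitted decay form.

    When ``n_samples`` is given the quantile additionally accounts for the
    finite-panel sampling noise of the estimated correlation (Fisher-z
    normal approximation), i.e. it is the implied quantile of *observed*
    r^2 in a panel of that size; with ``n_samples=None`` it is the
    population quantile.
    """
    if config.n_subpops != 1:
        raise ValueError("implied LD curve is defined for single-subpopulation panels")
    rng = np.random.default_rng(seed)
    p1 = rng.uniform(0.1, 0.9, size=n_freq_pairs)
    p2 = rng.uniform(0.1, 0.9, size=n_freq_pairs)
    a1 = stats.norm.ppf(p1)
    a2 = stats.norm.ppf(p2)
    out = np.empty(len(distances_mb))
    for i, d in enumerate(np.asarray(distances_mb, dtype=float)):
        rho = float(np.exp(-d / config.decay_scale_mb))
        rho = min(rho, 1.0 - 1e-12)
        cov = np.array([[1.0, rho], [rho, 1.0]])
        p11 = stats.multivariate_normal(mean=[0.0, 0.0], cov=cov).cdf(
            np.column_stack([a1, a2])
        )
        r = (p11 - p1 * p2) / np.sqrt(p1 * (1 - p1) * p2 * (1 - p2))
        if n_samples is not None:
            z = np.arctanh(np.clip(r, -0.999, 0.999))
            z = z + rng.standard_normal(n_freq_pairs) / np.sqrt(n_samples - 3)
            r = np.tanh(z)
        out[i] = np.quantile(r**2, tau)
    return out


def implied_ld_tenth(
    config: SimConfig, tau: float = 0.90, d_max_mb: float | None = None,
    n_grid: int = 25, **kwargs,
) -> float:
    """Distance where the generator-implied tau-quantile r^2 crosses 0.1."""
    if d_max_mb is None:
        d_max_mb = 6.0 * config.decay_scale_mb
    grid = np.linspace(1e-3, d_max_mb, n_grid)
    q = implied_quantile_r2(config, grid, tau=tau, **kwargs)
    below = np.nonzero(q < 0.1)[0]
    if below.size == 0 or below[0] == 0:
        raise RuntimeError("implied quantile curve does not cross 0.1 on the grid")
    j = below[0]
    # linear interpolation across the crossing
    d0, d1, q0, q1 = grid[j - 1], grid[j], q[j - 1], q[j]
    return float(d0 + (q0 - 0.1) / (q0 - q1) * (d1 - d0))


# ---------------------------------------------------------------------------
# fixture output


def write_fixture(sim: SimPanel, outdir: str | Path) -> dict[str, Path]:
    """Emit every module input format plus a truth JSON."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "dosage": outdir / "dosage.tsv",
        "marker_map": outdir / "marker_map.tsv",
        "het_boundaries": outdir / "het_boundaries.tsv",
        "traits": outdir / "traits.tsv",
        "truth": outdir / "truth.json",
        "config": outdir / "sim_config.json",
    }
    write_dosage(sim.panel, paths["dosage"])
    write_marker_map(sim.marker_map, paths["marker_map"])
    write_het_boundaries(sim.het_bounds, paths["het_boundaries"])
    write_traits(sim.traits, paths["traits"])
    truth = dict(sim.truth)
    truth["ancestral_freqs"] = np.asarray(truth["ancestral_freqs"]).round(6).tolist()
    truth["subpop_freqs"] = np.asarray(truth["subpop_freqs"]).round(6).tolist()
    paths["truth"].write_text(json.dumps(truth, indent=1))
    paths["config"].write_text(json.dumps(sim.config.to_dict(), indent=1))
    log.info("wrote fixture to %s", outdir)
    return paths
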