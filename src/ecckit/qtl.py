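"""Single-marker LOD scan over an F2 population with permutation thresholds.

The scan regresses the (ordinal, treated as numeric) phenotype on an
additive genotype code (AA=-1, AB=0, BB=+1) plus a dominance indicator
(AB=1), complete-case per marker, and reports LOD = (n/2) log10(RSS_null /
RSS_full).  Genome-wide significance uses the Churchill-Doerge scheme:
the phenotype vector is permuted against the genotype rows, preserving
marker LD, and the threshold is the empirical (1-alpha) quantile of the
genome-wide maximum LOD.  This is a deliberate, documented simplification
of composite interval mapping: no cofactors, no interval positions between
markers.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

#: cap for LOD on (numerically) perfect fits
LOD_MAX = 50.0
GENOTYPE_CODES = {"AA": (-1.0, 0.0), "AB": (0.0, 1.0), "BB": (1.0, 0.0)}


@dataclass(frozen=True)
class GeneticMap:
    """Markers as (name, chromosome, position-cM) triples, sorted within
    chromosome."""

    markers: tuple

    def __post_init__(self):
        names = [m[0] for m in self.markers]
        if len(set(names)) != len(names):
            raise ValueError("duplicate marker names")
        by_chrom = {}
        for name, chrom, pos in self.markers:
            if pos < 0:
                raise ValueError(f"marker {name!r} has negative position {pos}")
            by_chrom.setdefault(chrom, []).append(pos)
        for chrom, positions in by_chrom.items():
            if positions != sorted(positions):
                raise ValueError(f"markers on chromosome {chrom!r} are not sorted")

    @property
    def names(self):
        return [m[0] for m in self.markers]

    @property
    def chromosomes(self):
        seen = []
        for _, chrom, _ in self.markers:
            if chrom not in seen:
                seen.append(chrom)
        return seen


@dataclass
class F2Population:
    """Genotypes (individuals x markers, strings AA/AB/BB or NA) on a map,
    with an ordinal 1-5 phenotype per individual."""

    gmap: GeneticMap
    genotypes: pd.DataFrame
    phenotype: np.ndarray

    def __post_init__(self):
        self.phenotype = np.asarray(self.phenotype, dtype=float)
        if list(self.genotypes.columns) != self.gmap.names:
            raise ValueError("genotype columns do not match map markers")
        if len(self.phenotype) != len(self.genotypes):
            raise ValueError("phenotype length does not match individuals")
        finite = self.phenotype[np.isfinite(self.phenotype)]
        if finite.size and ((finite < 1) | (finite > 5)).any():
            raise ValueError("phenotype outside the 1-5 scale")


@dataclass
class ScanResult:
    lod: pd.Series  # per marker
    threshold: float | None = None
    peaks: list = field(default_factory=list)  # (marker, chrom, cM, lod)
    support_intervals: list = field(default_factory=list)
    flags: dict = field(default_factory=dict)


def _design_matrices(pop: F2Population):
    """Per-marker (mask, orthonormal basis Q of [1, add, dom]) for LOD."""
    out = {}
    for name in pop.gmap.names:
        col = pop.genotypes[name]
        mask = col.isin(GENOTYPE_CODES).to_numpy()
        codes = np.array(
            [GENOTYPE_CODES.get(g, (np.nan, np.nan)) for g in col], dtype=float
        )
        n_classes = col[mask].nunique()
        x = np.column_stack([np.ones(mask.sum()), codes[mask]])
        q, _ = np.linalg.qr(x)
        out[name] = (mask, q, n_classes)
    return out


def _lod_from_design(y: np.ndarray, mask, q, n_classes, lod_max: float):
    ym = y[mask]
    n = ym.size
    if n < 4 or n_classes < 2:
        return 0.0, "too_few_classes" if n_classes < 2 else "too_few_obs"
    rss_null = float(np.sum((ym - ym.mean()) ** 2))
    if rss_null <= 1e-12:
        return 0.0, "constant_phenotype"
    proj = q.T @ ym
    rss_full = float(ym @ ym - proj @ proj)
    if rss_full <= 1e-10 * rss_null:
        return lod_max, "perfect_fit"
    return (n / 2.0) * np.log10(rss_null / rss_full), None


def marker_scan(pop: F2Population, lod_max: float = LOD_MAX) -> ScanResult:
    """Per-marker LOD scores; degenerate markers get LOD 0 with a flag."""
    designs = _design_matrices(pop)
    y = pop.phenotype
    lods, flags = {}, {}
    for name in pop.gmap.names:
        mask, q, n_classes = designs[name]
        lod, flag = _lod_from_design(y, mask, q, n_classes, lod_max)
        lods[name] = max(float(lod), 0.0)
        if flag:
            flags[name] = flag
    return ScanResult(lod=pd.Series(lods), flags=flags)


def permutation_threshold(
    pop: F2Population,
    n_perm: int = 1000,
    alpha: float = 0.05,
    seed: int | None = None,
    lod_max: float = LOD_MAX,
) -> float:
    """Genome-wide (1-alpha) quantile of the max LOD under phenotype
    permutation (Churchill-Doerge); deterministic given ``seed``."""
    if n_perm < 100:
        raise ValueError("n_perm must be at least 100")
    rng = np.random.default_rng(seed)
    designs = _design_matrices(pop)
    y = pop.phenotype
    n = len(y)
    perm_y = np.empty((n, n_perm))
    for j in range(n_perm):
        perm_y[:, j] = y[rng.permutation(n)]
    max_lod = np.zeros(n_perm)
    for name in pop.gmap.names:
        mask, q, n_classes = designs[name]
        if n_classes < 2:
            continue
        ym = perm_y[mask]  # (n_m, n_perm)
        nm = ym.shape[0]
        if nm < 4:
            continue
        rss_null = np.sum(ym**2, axis=0) - ym.sum(axis=0) ** 2 / nm
        proj = q.T @ ym
        rss_full = np.sum(ym**2, axis=0) - np.sum(proj**2, axis=0)
        with np.errstate(divide="ignore", invalid="ignore"):
            lod = (nm / 2.0) * np.log10(rss_null / np.maximum(rss_full, 1e-300))
        lod = np.where(rss_full <= 1e-10 * np.maximum(rss_null, 1e-300), lod_max, lod)
        lod = np.where(rss_null <= 1e-12, 0.0, lod)
        np.maximum(max_lod, np.clip(lod, 0.0, lod_max), out=max_lod)
    return float(np.quantile(max_lod, 1.0 - alpha, method="higher"))


def lod_support_interval(pop: F2Population, scan: ScanResult, peak_marker: str, drop: float = 1.5):
    """LOD-drop support interval around a peak marker.

    The interval spans the contiguous run of markers (on the peak's
    chromosome) with LOD >= peak - drop, extended to the first marker
    falling below on each side (or the chromosome end).
    """
    marker_info = {m[0]: (m[1], m[2]) for m in pop.gmap.markers}
    chrom, _ = marker_info[peak_marker]
    chrom_markers = [m for m in pop.gmap.markers if m[1] == chrom]
    names = [m[0] for m in chrom_markers]
    positions = [m[2] for m in chrom_markers]
    lods = [scan.lod[n] for n in names]
    idx = names.index(peak_marker)
    cutoff = lods[idx] - drop
    lo = idx
    while lo > 0 and lods[lo - 1] >= cutoff:
        lo -= 1
    hi = idx
    while hi < len(names) - 1 and lods[hi + 1] >= cutoff:
        hi += 1
    # bracket with the first below-cutoff marker where one exists
    lo_pos = positions[lo - 1] if lo > 0 else positions[lo]
    hi_pos = positions[hi + 1] if hi < len(names) - 1 else positions[hi]
    return (chrom, lo_pos, hi_pos)


def scan_with_threshold(
    pop: F2Population,
    n_perm: int = 1000,
    alpha: float = 0.05,
    seed: int | None = None,
    drop: float = 1.5,
) -> ScanResult:
    """Full scan: LOD curve, permutation threshold, peaks and intervals."""
    scan = marker_scan(pop)
    scan.threshold = permutation_threshold(pop, n_perm=n_perm, alpha=alpha, seed=seed)
    marker_info = {m[0]: (m[1], m[2]) for m in pop.gmap.markers}
    above = scan.lod[scan.lod > scan.threshold]
    for chrom in pop.gmap.chromosomes:
        on_chrom = [n for n in above.index if marker_info[n][0] == chrom]
        if not on_chrom:
            continue
        peak = max(on_chrom, key=lambda n: scan.lod[n])
        scan.peaks.append((peak, chrom, marker_info[peak][1], float(scan.lod[peak])))
        scan.support_intervals.append(lod_support_interval(pop, scan, peak, drop=drop))
    return scan


def segregation_test(observed, expected_ratio):
    """Pearson chi-square goodness of fit of class counts to a ratio."""
    observed = np.asarray(observed, dtype=float)
    ratio = np.asarray(expected_ratio, dtype=float)
    if observed.size != ratio.size:
        raise ValueError("observed and ratio differ in length")
    if (observed < 0).any() or (ratio <= 0).any():
        raise ValueError("counts must be non-negative and ratio positive")
    total = observed.sum()
    if total == 0:
        raise ValueError("zero total count")
    expected = ratio / ratio.sum() * total
    chi2 = float(np.sum((observed - expected) ** 2 / expected))
    df = observed.size - 1
    p = float(stats.chi2.sf(chi2, df))
    return chi2, df, p
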