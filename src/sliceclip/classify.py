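"""Differential site classification from wild-type vs slicer-dead CLIP.

The core inference: a site cleaved by AGO2 loses its RNA (and hence
its wild-type CLIP signal) while the catalytically inactive mutant
parks on it, so the mutant/WT abundance ratio separates cleaved from
merely bound sites.

Stages, in pipeline order:

1. ``sirna_enriched_clusters`` — universe intervals whose with-shRNA /
   without-shRNA fold enrichment exceeds a cutoff k, either fixed or
   estimated from the fold-ratio density (``estimate_k``): enrichment
   is called where the density has fallen well below the unenriched
   mode.
2. ``classify_sirna_sites`` — mutant/WT ratios over the enriched set,
   normalized by their median; >= 2x the median = cleaved off-target,
   1.4-2x = noncleaved off-target, the rest unclassified; the interval
   containing the guide's full reverse complement is flagged
   on-target.
3. ``endogenous_cleavage_sites`` — no shRNA contrast: a site is an
   endogenous miRNA-mediated cleavage target iff both AGO1/WT and
   mutant/WT abundance ratios reach 2x.

All ratios use a small RPM pseudocount on numerator and denominator.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .clusters import DEFAULT_PSEUDOCOUNT, ClusterUniverse
from .pairing import reverse_complement

CLEAVED_BOUNDS = (1.4, 2.0)  # median-normalized mutant/WT ratio band edges
MIN_FOLD_ENDOGENOUS = 2.0


class NoThresholdError(RuntimeError):
    """The fold-ratio density never drops below the cutoff; use a fixed k."""


@dataclass
class KThreshold:
    """Fold-enrichment cutoff above which clusters count as siRNA-enriched."""

    k: float
    method: str = "fixed"          # "fixed" | "density"
    density_alpha: float = 0.05    # drop point, as a fraction of peak density

    def __post_init__(self) -> None:
        if self.k <= 1:
            raise ValueError(f"k must exceed 1, got {self.k}")


def estimate_k(fold_ratios: np.ndarray, density_alpha: float = 0.05,
               min_enriched_fraction: float = 0.01,
               grid_size: int = 2048) -> KThreshold:
    """Data-driven fold cutoff from the density of log2 fold ratios.

    A Gaussian kernel density (Silverman bandwidth) is evaluated on a
    grid over the log2 ratios. Above the density mode (the unenriched
    bulk), the crossing point where density first falls below
    ``density_alpha`` x peak marks where clusters become
    "considerably" rarer than the bulk. An enriched population exists
    only if the data mass beyond that crossing is non-trivial
    (>= ``min_enriched_fraction``; the extreme tail of a unimodal
    distribution carries ~0.7% at alpha = 0.05, so unimodal inputs
    raise :class:`NoThresholdError`). The cutoff k is then placed a
    quarter of the way (in log space) from the crossing toward the
    mode of the enriched component — inside the density valley
    separating bulk from enriched clusters, but near its bulk edge so
    weak enriched clusters are kept (the later mutant/WT
    classification, not this cutoff, provides specificity).
    """
    fold_ratios = np.asarray(fold_ratios, dtype=float)
    if len(fold_ratios) < 50:
        raise ValueError(
            f"density-based k needs >= 50 ratios, got {len(fold_ratios)}; "
            "supply a fixed k instead")
    if np.any(fold_ratios <= 0):
        raise ValueError("fold ratios must be positive")
    log_ratios = np.log2(fold_ratios)
    kde = stats.gaussian_kde(log_ratios, bw_method="silverman")
    pad = 4 * kde.factor * log_ratios.std()
    grid = np.linspace(log_ratios.min() - pad, log_ratios.max() + pad,
                       grid_size)
    dens = kde(grid)
    peak_idx = int(np.argmax(dens))
    below = np.flatnonzero(dens[peak_idx:] < density_alpha * dens[peak_idx])
    if len(below) == 0:
        raise NoThresholdError(
            "fold-ratio density never drops below alpha x peak above the "
            "mode; the distribution looks unimodal — use a fixed k")
    cross_idx = peak_idx + below[0]
    cross = grid[cross_idx]
    if np.mean(log_ratios > cross) < min_enriched_fraction:
        raise NoThresholdError(
            "essentially no clusters beyond the density drop; the "
            "distribution looks unimodal — use a fixed k")
    rising = np.flatnonzero(np.diff(dens[cross_idx:]) > 0)
    if len(rising) == 0:
        raise NoThresholdError(
            "density only decays beyond the drop point; the distribution "
            "looks unimodal — use a fixed k")
    valley_idx = cross_idx + rising[0]
    rebound = valley_idx + int(np.argmax(dens[valley_idx:]))
    k_log2 = cross + 0.25 * (grid[rebound] - cross)
    if k_log2 <= 0:
        raise NoThresholdError(
            "estimated cutoff does not exceed 1-fold; use a fixed k")
    return KThreshold(k=float(2.0 ** k_log2), method="density",
                      density_alpha=density_alpha)


def fold_enrichment(universe: ClusterUniverse, lib_with: str,
                    lib_without: str,
                    pseudocount: float = DEFAULT_PSEUDOCOUNT) -> np.ndarray:
    """(rpm with shRNA + c) / (rpm without shRNA + c) per universe interval."""
    for lib in (lib_with, lib_without):
        if lib not in universe.rpm.columns:
            raise KeyError(f"library {lib!r} not in universe")
    num = universe.rpm[lib_with].to_numpy() + pseudocount
    den = universe.rpm[lib_without].to_numpy() + pseudocount
    return num / den


def sirna_enriched_clusters(
    universe: ClusterUniverse,
    lib_with_shrna: str,
    lib_without_shrna: str,
    kthr: KThreshold | None = None,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    density_alpha: float = 0.05,
) -> pd.DataFrame:
    """Universe intervals with shRNA fold enrichment strictly over k.

    ``kthr=None`` estimates k from the fold-ratio density first. The
    comparison is strict: a cluster at exactly k is excluded. Returns
    the interval rows with a ``fold_sirna`` column (empty universe ->
    empty result).
    """
    if len(universe.intervals) == 0:
        out = universe.intervals.copy()
        out["fold_sirna"] = np.array([], dtype=float)
        return out
    fold = fold_enrichment(universe, lib_with_shrna, lib_without_shrna,
                           pseudocount)
    if kthr is None:
        kthr = estimate_k(fold, density_alpha=density_alpha)
    keep = fold > kthr.k
    out = universe.intervals.loc[keep].copy()
    out["fold_sirna"] = fold[keep]
    return out


def find_on_target_intervals(intervals: pd.DataFrame, guide: str,
                             genome: dict[str, str],
                             flank: int = 10) -> np.ndarray:
    """Flag intervals whose ±flank sequence contains the guide's full
    reverse complement — the definition of the siRNA on-target site."""
    target = reverse_complement(guide, alphabet="DNA")
    flags = np.zeros(len(intervals), dtype=bool)
    for i, row in enumerate(intervals.itertuples(index=False)):
        ref = genome.get(row.chrom)
        if ref is None:
            continue
        s = max(int(row.start) - flank, 0)
        e = min(int(row.end) + flank, len(ref))
        seq = ref[s:e]
        if row.strand == "-":
            seq = reverse_complement(seq, alphabet="DNA")
        flags[i] = target in seq.upper().replace("U", "T")
    return flags


def classify_sirna_sites(
    enriched: pd.DataFrame,
    mutant_rpm: np.ndarray,
    wt_rpm: np.ndarray,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    bounds: tuple[float, float] = CLEAVED_BOUNDS,
    guide: str | None = None,
    genome: dict[str, str] | None = None,
    normalize_by_median: bool = True,
) -> pd.DataFrame:
    """Assign cleaved / noncleaved / unclassified to enriched clusters.

    ``ratio_mut_wt = (mutant rpm + c) / (WT rpm + c)`` per enriched
    interval; ``ratio_norm`` divides by the median over the enriched
    set (even-sized sets use the mean of the two central values), so
    the unenriched bulk sits at 1. Classes, with both band edges
    closed on the cleaved/noncleaved side:

    - ``cleaved_off_target``    iff ratio_norm >= bounds[1] (2.0)
    - ``noncleaved_off_target`` iff bounds[0] (1.4) <= ratio_norm < bounds[1]
    - ``unclassified``          otherwise

    When ``guide`` and ``genome`` are given, intervals containing the
    guide's full reverse complement are additionally marked
    ``on_target`` (overriding the ratio class in the ``class`` column;
    the ratio columns are untouched). ``normalize_by_median=False``
    applies the band to the raw ratio instead, for sensitivity
    analysis.
    """
    if len(enriched) == 0:
        raise ValueError("enriched set is empty; nothing to classify")
    lower, upper = bounds
    if not 0 < lower < upper:
        raise ValueError(f"invalid bounds {bounds}")
    mutant_rpm = np.asarray(mutant_rpm, dtype=float)
    wt_rpm = np.asarray(wt_rpm, dtype=float)
    if len(mutant_rpm) != len(enriched) or len(wt_rpm) != len(enriched):
        raise ValueError("abundance arrays must match the enriched set")

    ratio = (mutant_rpm + pseudocount) / (wt_rpm + pseudocount)
    ratio_norm = ratio / np.median(ratio) if normalize_by_median else ratio

    cls = np.where(
        ratio_norm >= upper, "cleaved_off_target",
        np.where(ratio_norm >= lower, "noncleaved_off_target", "unclassified"))
    out = enriched.reset_index(drop=True).copy()
    out["ratio_mut_wt"] = ratio
    out["ratio_norm"] = ratio_norm
    out["on_target"] = False
    if guide is not None and genome is not None:
        out["on_target"] = find_on_target_intervals(out, guide, genome)
        cls = np.where(out["on_target"], "on_target", cls)
    out["class"] = cls
    return out


def endogenous_cleavage_sites(
    universe: ClusterUniverse,
    ago1_lib: str,
    mutant_lib: str,
    wt_lib: str,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    min_fold: float = MIN_FOLD_ENDOGENOUS,
) -> pd.DataFrame:
    """Call endogenous miRNA-mediated cleavage target sites.

    A universe interval is called iff BOTH the AGO1/WT and the
    (pooled) mutant/WT abundance ratios are at least ``min_fold``
    (2-fold, edge included). Returns all intervals with both ratios
    and a boolean ``endogenous_cleavage`` column plus a ``class``
    column for the called rows.
    """
    for lib in (ago1_lib, mutant_lib, wt_lib):
        if lib not in universe.rpm.columns:
            raise KeyError(f"library {lib!r} not in universe")
    wt = universe.rpm[wt_lib].to_numpy() + pseudocount
    ago1_ratio = (universe.rpm[ago1_lib].to_numpy() + pseudocount) / wt
    mut_ratio = (universe.rpm[mutant_lib].to_numpy() + pseudocount) / wt
    called = (ago1_ratio >= min_fold) & (mut_ratio >= min_fold)
    out = universe.intervals.reset_index(drop=True).copy()
    out["ratio_ago1_wt"] = ago1_ratio
    out["ratio_mut_wt"] = mut_ratio
    out["endogenous_cleavage"] = called
    out["class"] = np.where(called, "endogenous_cleavage", "unclassified")
    return out


def pool_mutant_libraries(
    reads_a: pd.DataFrame, total_a: int,
    reads_b: pd.DataFrame, total_b: int,
) -> tuple[pd.DataFrame, int]:
    """Pool two slicer-dead replicate libraries into one.

    Reads are concatenated and the RPM denominator becomes the sum of
    the two genome-mapped totals, so pooled RPM is the depth-weighted
    mean of the replicate RPMs.
    """
    if len(reads_a) == 0 or len(reads_b) == 0:
        raise ValueError("both replicate read sets must be non-empty")
    if total_a <= 0 or total_b <= 0:
        raise ValueError("replicate totals must be positive")
    pooled = pd.concat([reads_a, reads_b], ignore_index=True)
    return pooled, total_a + total_b
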