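"""Crosslink-cluster calling from read 5' start positions.

CLIP protocols that read out the crosslink site at the 5' end of the
insert cDNA reduce each usable read to a single genomic position. This
module groups those positions into clusters by single-linkage merging
within a small window (default 6 nt), normalizes cluster read counts to
RPM (reads per million genome-mapped reads of the library), removes
noise by comparison with an input library, and builds the merged
cross-library interval universe on which all downstream enrichment
ratios are computed.

Coordinates are 0-based half-open throughout; clusters never mix
strands or chromosomes.

Reads are carried as pandas DataFrames with columns
``chrom, strand, pos`` (one row per usable read); clusters as
DataFrames with ``chrom, strand, start, end, count`` and, after
normalization, ``rpm``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats

READ_COLUMNS = ["chrom", "strand", "pos"]
CLUSTER_COLUMNS = ["chrom", "strand", "start", "end", "count"]

#: RPM added to an abundance before it enters a denominator (or a log);
#: keeps ratios bounded when the comparison library has no reads in an
#: interval while leaving well-covered intervals essentially untouched.
DEFAULT_PSEUDOCOUNT = 0.1


def _empty_clusters() -> pd.DataFrame:
    return pd.DataFrame({
        "chrom": pd.Series(dtype=object),
        "strand": pd.Series(dtype=object),
        "start": pd.Series(dtype=np.int64),
        "end": pd.Series(dtype=np.int64),
        "count": pd.Series(dtype=np.int64),
    })


def call_clusters(reads: pd.DataFrame, window: int = 6) -> pd.DataFrame:
    """Group read 5' starts into single-linkage clusters.

    Two reads fall in the same cluster iff they share chromosome and
    strand and are connected by a chain of positions each at most
    ``window`` nt apart (a gap of exactly ``window`` still links).
    The cluster interval spans ``[min pos, max pos + 1)`` and ``count``
    is the number of member reads (duplicate positions each count).

    Parameters
    ----------
    reads
        One library's reads, columns ``chrom, strand, pos``.
    window
        Maximum linking gap in nt, >= 1.

    Returns
    -------
    DataFrame with columns ``chrom, strand, start, end, count``,
    sorted by (chrom, strand, start). Empty input yields an empty
    frame, not an error.
    """
    if window < 1:
        raise ValueError(f"window must be >= 1, got {window}")
    if len(reads) == 0:
        return _empty_clusters()
    if (reads["pos"] < 0).any():
        raise ValueError("read positions must be non-negative")
    bad = set(reads["strand"].unique()) - {"+", "-"}
    if bad:
        raise ValueError(f"invalid strand value(s): {sorted(bad)}")

    out = []
    for (chrom, strand), grp in reads.groupby(["chrom", "strand"], sort=True):
        pos = np.sort(grp["pos"].to_numpy(dtype=np.int64))
        # boundary where the gap to the previous position exceeds the window
        breaks = np.flatnonzero(np.diff(pos) > window) + 1
        starts_idx = np.concatenate(([0], breaks))
        ends_idx = np.concatenate((breaks, [len(pos)]))
        out.append(pd.DataFrame({
            "chrom": chrom,
            "strand": strand,
            "start": pos[starts_idx],
            "end": pos[ends_idx - 1] + 1,
            "count": ends_idx - starts_idx,
        }))
    res = pd.concat(out, ignore_index=True)
    return res.sort_values(["chrom", "strand", "start"], ignore_index=True)


def compute_rpm(clusters: pd.DataFrame, total_mapped: int) -> pd.DataFrame:
    """Attach RPM = count / total_mapped * 1e6 to each cluster."""
    if total_mapped <= 0:
        raise ValueError(f"total_mapped must be positive, got {total_mapped}")
    clusters = clusters.copy()
    clusters["rpm"] = clusters["count"] / total_mapped * 1e6
    return clusters


def count_reads_in_intervals(intervals: pd.DataFrame, reads: pd.DataFrame) -> np.ndarray:
    """Count reads whose 5' position lies inside each interval.

    Strand-specific containment: a read at ``pos`` is counted for an
    interval iff same chrom, same strand and ``start <= pos < end``.
    Intervals may appear in any order; counts are returned in input
    row order.
    """
    counts = np.zeros(len(intervals), dtype=np.int64)
    if len(reads) == 0 or len(intervals) == 0:
        return counts
    for (chrom, strand), grp in reads.groupby(["chrom", "strand"], sort=False):
        mask = (intervals["chrom"] == chrom) & (intervals["strand"] == strand)
        if not mask.any():
            continue
        pos = np.sort(grp["pos"].to_numpy(dtype=np.int64))
        lo = np.searchsorted(pos, intervals.loc[mask, "start"].to_numpy(), side="left")
        hi = np.searchsorted(pos, intervals.loc[mask, "end"].to_numpy(), side="left")
        counts[mask.to_numpy()] += hi - lo
    return counts


def input_noise_filter(
    clip_clusters: pd.DataFrame,
    input_reads: pd.DataFrame,
    input_total: int,
    min_rpm: float = 5.0,
    min_fold: float = 15.0,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> pd.DataFrame:
    """Keep CLIP clusters that stand out over the input library.

    A cluster is protein-specific iff its RPM exceeds ``min_rpm``
    (strictly: abundance of exactly ``min_rpm`` is rejected) and its
    RPM is at least ``min_fold`` times the input abundance in the same
    interval. The input abundance is recounted positionally — input
    read starts falling inside the CLIP cluster interval on the same
    strand — rather than by calling clusters on the input side. Input
    intervals with zero reads take ``pseudocount`` RPM so the fold
    ratio stays defined.
    """
    if min_rpm <= 0 or min_fold <= 0:
        raise ValueError("min_rpm and min_fold must be positive")
    if input_total <= 0:
        raise ValueError(f"input_total must be positive, got {input_total}")
    if "rpm" not in clip_clusters.columns:
        raise ValueError("clip_clusters lack 'rpm'; run compute_rpm first")
    if len(clip_clusters) == 0:
        return clip_clusters.copy()
    input_counts = count_reads_in_intervals(clip_clusters, input_reads)
    input_rpm = input_counts / input_total * 1e6
    fold = clip_clusters["rpm"].to_numpy() / np.maximum(input_rpm, pseudocount)
    keep = (clip_clusters["rpm"].to_numpy() > min_rpm) & (fold >= min_fold)
    out = clip_clusters.loc[keep].copy()
    out["input_rpm"] = input_rpm[keep]
    out["input_fold"] = fold[keep]
    return out.reset_index(drop=True)


def merge_intervals(interval_sets: Iterable[pd.DataFrame]) -> pd.DataFrame:
    """Strand-specific merge (any overlap, including touching ends)."""
    frames = [df[["chrom", "strand", "start", "end"]] for df in interval_sets if len(df)]
    if not frames:
        return _empty_clusters()[["chrom", "strand", "start", "end"]]
    allint = pd.concat(frames, ignore_index=True)
    merged = []
    for (chrom, strand), grp in allint.groupby(["chrom", "strand"], sort=True):
        grp = grp.sort_values("start")
        starts = grp["start"].to_numpy()
        ends = grp["end"].to_numpy()
        cur_s, cur_e = starts[0], ends[0]
        for s, e in zip(starts[1:], ends[1:]):
            if s <= cur_e:
                cur_e = max(cur_e, e)
            else:
                merged.append((chrom, strand, cur_s, cur_e))
                cur_s, cur_e = s, e
        merged.append((chrom, strand, cur_s, cur_e))
    return pd.DataFrame(merged, columns=["chrom", "strand", "start", "end"])


@dataclass
class ClusterUniverse:
    """Merged cross-library intervals with per-library abundances.

    ``intervals`` holds the pairwise non-overlapping strand-specific
    intervals; ``counts`` and ``rpm`` are DataFrames indexed like
    ``intervals`` with one column per library; ``totals`` maps library
    id to its genome-mapped read total (the RPM denominator).
    """

    intervals: pd.DataFrame
    counts: pd.DataFrame
    rpm: pd.DataFrame
    totals: dict[str, int] = field(default_factory=dict)

    @property
    def libraries(self) -> list[str]:
        return list(self.rpm.columns)

    def to_frame(self) -> pd.DataFrame:
        """Flat table: interval columns + one rpm column per library."""
        return pd.concat(
            [self.intervals.reset_index(drop=True),
             self.rpm.add_suffix("_rpm").reset_index(drop=True)], axis=1)


def build_universe(
    cluster_sets: Mapping[str, pd.DataFrame],
    read_sets: Mapping[str, pd.DataFrame],
    totals: Mapping[str, int],
) -> ClusterUniverse:
    """Combine per-library clusters into one comparable interval set.

    The universe intervals are the strand-specific merge of every
    cluster in ``cluster_sets``. The abundance of each interval in each
    library of ``read_sets`` is then recounted from that library's read
    starts and normalized by its ``totals`` entry, so a library whose
    own clusters missed an interval still contributes its (possibly
    zero) signal there.
    """
    if len(cluster_sets) == 0:
        raise ValueError("at least one cluster set is required")
    missing = set(read_sets) - set(totals)
    if missing:
        raise ValueError(f"totals missing for libraries: {sorted(missing)}")
    intervals = merge_intervals(cluster_sets.values())
    counts = {}
    rpm = {}
    for lib, reads in read_sets.items():
        c = count_reads_in_intervals(intervals, reads)
        counts[lib] = c
        rpm[lib] = c / totals[lib] * 1e6
    return ClusterUniverse(
        intervals=intervals,
        counts=pd.DataFrame(counts, index=intervals.index),
        rpm=pd.DataFrame(rpm, index=intervals.index),
        totals=dict(totals),
    )


def correlate_libraries(
    universe: ClusterUniverse,
    lib_a: str,
    lib_b: str,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> float:
    """Pearson r of log2(rpm + pseudocount) across universe intervals."""
    for lib in (lib_a, lib_b):
        if lib not in universe.rpm.columns:
            raise KeyError(f"library {lib!r} not in universe")
    if len(universe.intervals) < 3:
        raise ValueError("correlation needs at least 3 universe intervals")
    a = np.log2(universe.rpm[lib_a].to_numpy() + pseudocount)
    b = np.log2(universe.rpm[lib_b].to_numpy() + pseudocount)
    if np.ptp(a) == 0 and np.ptp(b) == 0:
        return 1.0  # identical constant profiles
    return float(stats.pearsonr(a, b).statistic)


# ---------------------------------------------------------------------------
# BED6 / TSV interchange


def read_bed6(path) -> pd.DataFrame:
    """Read one-read-per-record BED6 into a reads DataFrame."""
    bed = pd.read_csv(
        path, sep="\t", header=None, comment="#",
        names=["chrom", "start", "end", "name", "score", "strand"],
        dtype={"chrom": str, "start": np.int64, "end": np.int64,
               "name": str, "strand": str},
    )
    return pd.DataFrame({
        "chrom": bed["chrom"], "strand": bed["strand"], "pos": bed["start"],
    })


def write_reads_bed6(reads: pd.DataFrame, library: str, path) -> None:
    bed = pd.DataFrame({
        "chrom": reads["chrom"],
        "start": reads["pos"],
        "end": reads["pos"] + 1,
        "name": library,
        "score": 1,
        "strand": reads["strand"],
    })
    bed.to_csv(path, sep="\t", header=False, index=False)


def write_clusters(clusters: pd.DataFrame, path) -> None:
    """Clusters as BED6-plus: name=cluster id, score=count, extra rpm column."""
    out = pd.DataFrame({
        "chrom": clusters["chrom"],
        "start": clusters["start"],
        "end": clusters["end"],
        "name": [f"cluster_{i}" for i in range(len(clusters))],
        "score": clusters["count"],
        "strand": clusters["strand"],
    })
    if "rpm" in clusters.columns:
        out["rpm"] = clusters["rpm"].to_numpy()
    out.to_csv(path, sep="\t", header=False, index=False)
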