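"""Transcript-region assignment and size-corrected region distributions.

Sites are assigned to 5'UTR / CDS / 3'UTR by the region containing the
site midpoint; when several transcript models overlap a midpoint the
precedence CDS > 3'UTR > 5'UTR decides, and sites outside any model
are labeled "other". Counts per region are reported raw and corrected
for region size — sites per nt, renormalized to proportions — because
a long 3'UTR collects more sites by area alone.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

REGION_5UTR = "five_prime_utr"
REGION_CDS = "CDS"
REGION_3UTR = "three_prime_utr"
REGION_OTHER = "other"

#: tie-break when a midpoint falls in several overlapping models
REGION_PRECEDENCE = (REGION_CDS, REGION_3UTR, REGION_5UTR)


@dataclass
class TranscriptModel:
    """Ordered 5'UTR/CDS/3'UTR intervals of one transcript, half-open."""

    tx_id: str
    chrom: str
    strand: str
    regions: dict[str, list[tuple[int, int]]]

    def __post_init__(self) -> None:
        ivs = sorted((s, e) for lst in self.regions.values() for (s, e) in lst)
        for (s, e) in ivs:
            if e <= s:
                raise ValueError(f"{self.tx_id}: empty region interval {s, e}")
        for (_, e1), (s2, _) in zip(ivs, ivs[1:]):
            if s2 < e1:
                raise ValueError(f"{self.tx_id}: overlapping region intervals")
        if not ivs:
            raise ValueError(f"{self.tx_id}: transcript has no regions")

    def region_at(self, pos: int) -> str | None:
        hits = [r for r, lst in self.regions.items()
                if any(s <= pos < e for s, e in lst)]
        if not hits:
            return None
        for r in REGION_PRECEDENCE:
            if r in hits:
                return r
        return hits[0]

    def region_lengths(self) -> dict[str, int]:
        return {r: sum(e - s for s, e in lst)
                for r, lst in self.regions.items()}


def read_gtf(path) -> list[TranscriptModel]:
    """Load transcript models from a simplified GTF.

    Only rows whose feature is five_prime_utr / CDS / three_prime_utr
    are used; coordinates convert from GTF 1-based inclusive to
    0-based half-open. The chromosome column doubles as the transcript
    when no transcript_id attribute is present.
    """
    gtf = pd.read_csv(
        path, sep="\t", header=None, comment="#",
        names=["chrom", "source", "feature", "start", "end",
               "score", "strand", "frame", "attributes"],
        dtype={"chrom": str, "feature": str, "attributes": str},
    )
    gtf = gtf[gtf["feature"].isin([REGION_5UTR, REGION_CDS, REGION_3UTR])]
    tx_ids = gtf["attributes"].str.extract(r'transcript_id "([^"]+)"')[0]
    tx_ids = tx_ids.fillna(gtf["chrom"])
    models = []
    for tx_id, grp in gtf.groupby(tx_ids, sort=True):
        regions: dict[str, list[tuple[int, int]]] = {}
        for row in grp.itertuples(index=False):
            regions.setdefault(row.feature, []).append(
                (int(row.start) - 1, int(row.end)))
        models.append(TranscriptModel(
            tx_id=str(tx_id), chrom=str(grp["chrom"].iloc[0]),
            strand=str(grp["strand"].iloc[0]), regions=regions))
    return models


def select_longest_per_gene(models: Iterable[TranscriptModel],
                            gene_of: Mapping[str, str] | None = None
                            ) -> list[TranscriptModel]:
    """Keep the longest model per gene so every site gets one label.

    Without a transcript->gene map each model is its own gene (the
    synthetic annotation has one model per transcript already).
    """
    best: dict[str, TranscriptModel] = {}
    for m in models:
        gene = gene_of.get(m.tx_id, m.tx_id) if gene_of else m.tx_id
        if gene not in best or (sum(m.region_lengths().values())
                                > sum(best[gene].region_lengths().values())):
            best[gene] = m
    return list(best.values())


def annotate_site(start: int, end: int, chrom: str,
                  models: Iterable[TranscriptModel]) -> str:
    """Region label of one site by midpoint containment."""
    mid = (int(start) + int(end)) // 2
    hits = [m.region_at(mid) for m in models if m.chrom == chrom]
    hits = [h for h in hits if h is not None]
    if not hits:
        return REGION_OTHER
    for r in REGION_PRECEDENCE:
        if r in hits:
            return r
    return hits[0]


def annotate_sites(intervals: pd.DataFrame,
                   models: Iterable[TranscriptModel]) -> pd.Series:
    """Vector version of :func:`annotate_site` over an interval frame."""
    by_chrom: dict[str, list[TranscriptModel]] = {}
    for m in models:
        by_chrom.setdefault(m.chrom, []).append(m)
    labels = []
    for row in intervals.itertuples(index=False):
        labels.append(annotate_site(row.start, row.end, row.chrom,
                                    by_chrom.get(row.chrom, ())))
    return pd.Series(labels, index=intervals.index, name="region")


def total_region_lengths(models: Iterable[TranscriptModel]) -> dict[str, int]:
    out: dict[str, int] = {}
    for m in models:
        for r, ln in m.region_lengths().items():
            out[r] = out.get(r, 0) + ln
    return out


@dataclass
class RegionDistribution:
    raw_counts: dict[str, int]
    raw: dict[str, float]          # count proportions
    corrected: dict[str, float]    # per-nt density proportions
    region_lengths: dict[str, int]

    def to_frame(self) -> pd.DataFrame:
        regions = list(self.raw_counts)
        return pd.DataFrame({
            "region": regions,
            "count": [self.raw_counts[r] for r in regions],
            "length_nt": [self.region_lengths.get(r, np.nan) for r in regions],
            "raw_proportion": [self.raw[r] for r in regions],
            "corrected_proportion": [self.corrected[r] for r in regions],
        })


def region_distribution(labels: Iterable[str],
                        region_lengths: Mapping[str, int]
                        ) -> RegionDistribution:
    """Raw and region-size-corrected proportions of site labels.

    ``corrected_i = (count_i / length_i) / sum_j (count_j / length_j)``
    — the share each region would have if all regions were the same
    size. Every labeled region must have a positive annotated length.
    """
    counts = pd.Series(list(labels)).value_counts().to_dict()
    if not counts:
        raise ValueError("at least one labeled site is required")
    for r in counts:
        if region_lengths.get(r, 0) <= 0:
            raise ValueError(
                f"region {r!r} has sites but no annotated length")
    total = sum(counts.values())
    raw = {r: c / total for r, c in counts.items()}
    dens = {r: counts[r] / region_lengths[r] for r in counts}
    dens_total = sum(dens.values())
    corrected = {r: d / dens_total for r, d in dens.items()}
    return RegionDistribution(
        raw_counts=dict(counts), raw=raw, corrected=corrected,
        region_lengths={r: int(region_lengths[r]) for r in counts})
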