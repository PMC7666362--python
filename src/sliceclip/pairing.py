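"""Successive-7-mer complementarity profiles of small RNAs vs target sites.

For a guide of length L, every 7-mer window (nucleotides 1-7, 2-8,
... L-6..L, 1-based along the guide) is searched as an exact reverse
complement inside each target-site sequence; the per-position match
fraction over a set of sites is the base-pairing tendency profile.
Matching is exact Watson-Crick — G:U wobble pairs do not count — and
all sequences are normalized to the RNA alphabet before comparison, so
DNA site sequences and RNA guides mix freely.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

_RNA_COMPLEMENT = str.maketrans("ACGUN", "UGCAN")
_DNA_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str, alphabet: str = "RNA") -> str:
    """Watson-Crick reverse complement in the given alphabet.

    ``alphabet="DNA"`` accepts U on input (treated as T) and returns
    DNA; ``"RNA"`` accepts T (treated as U) and returns RNA.
    """
    seq = seq.upper()
    if alphabet == "RNA":
        seq = seq.replace("T", "U")
        table = _RNA_COMPLEMENT
        valid = set("ACGUN")
    elif alphabet == "DNA":
        seq = seq.replace("U", "T")
        table = _DNA_COMPLEMENT
        valid = set("ACGTN")
    else:
        raise ValueError(f"alphabet must be 'RNA' or 'DNA', got {alphabet!r}")
    bad = set(seq) - valid
    if bad:
        raise ValueError(f"invalid {alphabet} character(s): {sorted(bad)}")
    return seq.translate(table)[::-1]


def normalize_rna(seq: str) -> str:
    return seq.upper().replace("T", "U")


@dataclass
class SevenMerProfile:
    """Per-start-position match fractions for one guide vs one site set."""

    guide: str
    positions: np.ndarray      # 1-based 7-mer start positions, 1..L-6
    match_fraction: np.ndarray
    n_sites: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"position": self.positions,
                             "match_fraction": self.match_fraction})


def sevenmer_profile(guide: str, site_sequences: Sequence[str],
                     k: int = 7) -> SevenMerProfile:
    """Fraction of sites containing each guide k-mer's reverse complement.

    A site matches position p iff the site sequence contains, as an
    exact substring, the reverse complement of guide[p..p+k-1]
    (1-based). Identical k-mers at different guide positions therefore
    give identical fractions.
    """
    guide = normalize_rna(guide)
    if len(guide) < k + 1:
        raise ValueError(f"guide must be >= {k + 1} nt, got {len(guide)}")
    if len(site_sequences) == 0:
        raise ValueError("at least one site sequence is required")
    sites = [normalize_rna(s) for s in site_sequences]
    for s in sites:
        if len(s) < k:
            raise ValueError(f"site sequences must be >= {k} nt")
    n_pos = len(guide) - k + 1
    fractions = np.empty(n_pos)
    for i in range(n_pos):
        target = reverse_complement(guide[i:i + k], alphabet="RNA")
        fractions[i] = sum(target in s for s in sites) / len(sites)
    return SevenMerProfile(
        guide=guide, positions=np.arange(1, n_pos + 1),
        match_fraction=fractions, n_sites=len(sites))


def expected_random_match_fraction(site_length: int, n_sites: int = 1,
                                   k: int = 7) -> float:
    """Chance match fraction for i.i.d. uniform random site sequences.

    Probability that at least one of the ``site_length - k + 1``
    windows of one site equals a fixed k-mer, treating windows as
    independent: ``1 - (1 - 4**-k)**n_windows`` (an accurate
    approximation at these densities). ``n_sites`` > 1 returns the
    same per-site probability — the expected fraction is the per-site
    hit probability regardless of the set size.
    """
    n_windows = max(site_length - k + 1, 0)
    return 1.0 - (1.0 - 4.0 ** (-k)) ** n_windows


def aggregate_profiles(
    profiles_by_class: Mapping[str, Iterable[SevenMerProfile]],
) -> pd.DataFrame:
    """Unweighted mean profile per site class over multiple guides.

    All profiles within and across classes must share one position
    grid (guides of equal length); resampling is deliberately not
    attempted — trim guides to a common length upstream instead.

    Returns a tidy frame (position, class, fraction).
    """
    rows = []
    grid: np.ndarray | None = None
    for cls, profiles in profiles_by_class.items():
        profiles = list(profiles)
        if not profiles:
            continue
        for p in profiles:
            if grid is None:
                grid = p.positions
            elif not np.array_equal(p.positions, grid):
                raise ValueError(
                    "profiles are on different position grids; trim guides "
                    "to a common length before aggregating")
        mean = np.mean([p.match_fraction for p in profiles], axis=0)
        rows.append(pd.DataFrame({
            "position": grid, "class": cls, "fraction": mean}))
    if not rows:
        raise ValueError("no profiles to aggregate")
    return pd.concat(rows, ignore_index=True)


def extract_site_sequences(intervals: pd.DataFrame,
                           genome: Mapping[str, str],
                           flank: int = 10) -> list[str]:
    """Sequences under intervals, extended ±flank, strand-respecting.

    Minus-strand intervals return the reverse complement so every
    sequence reads 5'->3' on the bound RNA's sense strand. Coordinates
    are clipped to the reference ends.
    """
    seqs = []
    for row in intervals.itertuples(index=False):
        ref = genome[row.chrom]
        s = max(int(row.start) - flank, 0)
        e = min(int(row.end) + flank, len(ref))
        seq = ref[s:e]
        if row.strand == "-":
            seq = reverse_complement(seq, alphabet="DNA")
        seqs.append(seq)
    return seqs
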