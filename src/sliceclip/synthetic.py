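"""Seeded synthetic CLIP data with planted, labeled target sites.

Emulates the statistical structure a slicer-activity CLIP comparison
assumes: clustered read 5' starts at Argonaute binding sites whose
abundance ratio between a catalytically inactive (mutant) library and
the wild-type library differs by site class, over a
transcript-proportional uniform background, plus a position-uniform
input library.

Site classes
------------
``on_target``
    The single site fully complementary to the guide; cleavage removes
    it from wild-type signal, so its planted log2 mutant/WT ratio is
    the largest of all classes (default mean 3.5).
``cleaved``
    Off-target sites cleaved by AGO2: >= 2x mutant enrichment (log2
    ratio truncated at 1.0); planted pairing covers the guide's
    central and 3' region (nt 8-21) without a complete seed 7-mer.
``noncleaved``
    miRNA-like off-target sites: 1.4-2x mutant enrichment; planted
    pairing is the seed only (guide nt 2-8).
``background``
    siRNA-dependent sites with ratio ~ 1 — bound upon shRNA expression
    but not differentially enriched; they anchor the median used for
    ratio normalization.
``constitutive``
    shRNA-independent binding sites with ratio ~ 1 (endogenous-miRNA-
    guided binding): present in every condition; in the siRNA scenario
    they supply the unenriched density mode the data-driven fold
    threshold is estimated against.
``endogenous_cleavage``
    shRNA-independent sites cleaved under endogenous miRNA guidance:
    enriched in both AGO1 and mutant AGO2 over wild-type AGO2 (log2
    ratio truncated at 1.5).

The first four classes emit reads only in the shRNA condition; the
last two in every condition. Expected read count at a site is
``reads_per_site_mean`` in the mutant (and AGO1) library and
``reads_per_site_mean * 2**(-true log2 ratio)`` in wild type; the
input library is position-uniform. Per-library counts are multinomial
at the configured depth, with the uniform background absorbing the
non-site probability mass, so library totals are exact.

All coordinates are 0-based half-open; every transcript is its own
reference sequence on the "+" strand.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .pairing import reverse_complement


class ConfigError(ValueError):
    """Invalid synthetic-data configuration."""


class GenerationError(RuntimeError):
    """Requested sites do not fit the simulated transcriptome."""


CLASS_ON_TARGET = "on_target"
CLASS_CLEAVED = "cleaved"
CLASS_NONCLEAVED = "noncleaved"
CLASS_BACKGROUND = "background"
CLASS_CONSTITUTIVE = "constitutive"
CLASS_ENDOGENOUS = "endogenous_cleavage"

SITE_CLASSES = (
    CLASS_ON_TARGET, CLASS_CLEAVED, CLASS_NONCLEAVED,
    CLASS_BACKGROUND, CLASS_CONSTITUTIVE, CLASS_ENDOGENOUS,
)

#: classes whose sites emit reads only when the shRNA is expressed
SHRNA_DEPENDENT_CLASSES = frozenset(
    {CLASS_ON_TARGET, CLASS_CLEAVED, CLASS_NONCLEAVED, CLASS_BACKGROUND})

#: truncation bounds (log2 mutant/WT) enforcing each class's definition
RATIO_BOUNDS: dict[str, tuple[float, float]] = {
    CLASS_ON_TARGET: (2.5, np.inf),
    CLASS_CLEAVED: (1.0, np.inf),                 # >= 2-fold
    CLASS_NONCLEAVED: (math.log2(1.4), 1.0),      # 1.4- to 2-fold
    CLASS_BACKGROUND: (-np.inf, np.inf),
    CLASS_CONSTITUTIVE: (-np.inf, np.inf),
    CLASS_ENDOGENOUS: (1.5, np.inf),
}

#: 1-based guide subregions (inclusive) whose reverse complement is
#: planted at sites of each class; None = no guide complementarity.
PAIRING_SUBREGIONS: dict[str, tuple[int, int] | None] = {
    CLASS_ON_TARGET: None,  # resolved to the full guide at plant time
    CLASS_CLEAVED: (8, 21),
    CLASS_NONCLEAVED: (2, 8),
    CLASS_BACKGROUND: None,
    CLASS_CONSTITUTIVE: None,
    CLASS_ENDOGENOUS: None,
}

#: a fixed 21-nt guide with no repeated 7-mer, used when none is given
DEFAULT_GUIDE = "UGAAGCUCAUCGGAUCAUGUC"

LIBRARY_PROTEINS = {"wt": "WT", "mut": "MUT", "mut1": "MUT", "mut2": "MUT",
                    "ago1": "AGO1", "input": "INPUT"}
LIBRARY_CONDITIONS = ("shrna", "ctrl")


def parse_library_id(library: str) -> tuple[str, str]:
    """Split e.g. ``"mut1_shrna"`` into protein ``"MUT"`` and condition."""
    prefix, _, cond = library.partition("_")
    if prefix not in LIBRARY_PROTEINS or cond not in LIBRARY_CONDITIONS:
        raise ConfigError(
            f"unrecognized library id {library!r}; expected "
            f"<{'|'.join(LIBRARY_PROTEINS)}>_<{'|'.join(LIBRARY_CONDITIONS)}>")
    return LIBRARY_PROTEINS[prefix], cond


@dataclass
class SyntheticConfig:
    """Parameters of the synthetic study.

    ``ratio_params`` maps class -> (mean, sd) of the true log2
    mutant/WT ratio; draws are truncated to the class bounds in
    :data:`RATIO_BOUNDS`.

    Each site also carries its own binding strength — the expected
    mutant-library read count — drawn log-normally with median
    ``reads_per_site_mean`` and log2 sd ``site_strength_log2_sd``, the
    orders-of-magnitude spread real binding sites show (and the shared
    signal replicate correlations measure).

    ``library_depths`` of ``None`` derives each CLIP library's depth
    so its site reads occupy ``1 - background_read_fraction`` of the
    library; input libraries instead get ``input_reads_per_nt`` x
    transcriptome length, dense enough that an interval with zero
    input reads reflects genuine absence rather than shallow sampling.
    """

    n_transcripts: int = 1000
    transcript_length_range: tuple[int, int] = (600, 1400)
    region_fractions: tuple[float, float, float] = (0.15, 0.45, 0.40)
    n_sites_per_class: dict[str, int] = field(default_factory=lambda: {
        CLASS_ON_TARGET: 1, CLASS_CLEAVED: 20, CLASS_NONCLEAVED: 20,
        CLASS_BACKGROUND: 200, CLASS_CONSTITUTIVE: 2000, CLASS_ENDOGENOUS: 0,
    })
    reads_per_site_mean: float = 200.0
    background_read_fraction: float = 0.01
    ratio_params: dict[str, tuple[float, float]] = field(default_factory=lambda: {
        CLASS_ON_TARGET: (3.5, 0.3), CLASS_CLEAVED: (2.0, 0.2),
        CLASS_NONCLEAVED: (0.75, 0.10), CLASS_BACKGROUND: (0.0, 0.05),
        CLASS_CONSTITUTIVE: (0.0, 0.05), CLASS_ENDOGENOUS: (2.0, 0.2),
    })
    libraries: tuple[str, ...] = (
        "wt_shrna", "wt_ctrl", "mut1_shrna", "mut2_shrna",
        "input_shrna", "input_ctrl",
    )
    library_depths: dict[str, int] | None = None
    site_strength_log2_sd: float = 1.0
    input_reads_per_nt: float = 4.0
    site_length: int = 21
    read_jitter: int = 2
    seed: int = 0

    def validate(self) -> None:
        if self.n_transcripts < 1:
            raise ConfigError("n_transcripts must be >= 1")
        lo, hi = self.transcript_length_range
        if lo <= 0 or hi < lo:
            raise ConfigError(f"invalid transcript_length_range {lo, hi}")
        if abs(sum(self.region_fractions) - 1.0) > 1e-9:
            raise ConfigError(
                f"region_fractions must sum to 1, got {self.region_fractions}")
        if any(f < 0 for f in self.region_fractions):
            raise ConfigError("region_fractions must be non-negative")
        unknown = set(self.n_sites_per_class) - set(SITE_CLASSES)
        if unknown:
            raise ConfigError(f"unknown site classes: {sorted(unknown)}")
        if any(n < 0 for n in self.n_sites_per_class.values()):
            raise ConfigError("site counts must be non-negative")
        if not 0.0 <= self.background_read_fraction <= 1.0:
            raise ConfigError("background_read_fraction must be in [0, 1]")
        if self.reads_per_site_mean <= 0:
            raise ConfigError("reads_per_site_mean must be positive")
        if self.site_strength_log2_sd < 0:
            raise ConfigError("site_strength_log2_sd must be >= 0")
        if self.input_reads_per_nt <= 0:
            raise ConfigError("input_reads_per_nt must be positive")
        if self.read_jitter < 0 or self.read_jitter > 5:
            raise ConfigError("read_jitter must stay within 0-5 nt so the "
                              "6-nt clustering reunites one site's reads")
        for lib in self.libraries:
            parse_library_id(lib)
        mean = self.ratio_params.get(CLASS_CLEAVED, (0, 0))[0]
        if self.n_sites_per_class.get(CLASS_CLEAVED, 0) and mean <= 1.0:
            raise ConfigError("cleaved mean log2 ratio must exceed 1 (>2-fold)")


def scale_config(config: SyntheticConfig, scale: float) -> SyntheticConfig:
    """Shrink (or grow) a scenario: transcript and site counts scale
    together, so densities and abundance ratios are preserved."""
    if scale <= 0:
        raise ConfigError("scale must be positive")
    import dataclasses
    return dataclasses.replace(
        config,
        n_transcripts=max(int(round(config.n_transcripts * scale)), 1),
        n_sites_per_class={
            cls: (min(n, 1) if cls == CLASS_ON_TARGET
                  else int(round(n * scale)))
            for cls, n in config.n_sites_per_class.items()},
    )


def endogenous_config(**overrides) -> SyntheticConfig:
    """Default configuration for the endogenous-cleavage scenario.

    No shRNA condition: wild-type, two mutant replicates, AGO1 and
    input libraries, with cleavage sites and constitutive background
    sites planted shRNA-independently.

    With only 330 sites, per-site reads default higher than in the
    siRNA scenario so the derived library depth keeps one read well
    under the 5-RPM cluster floor — below that depth, single stray
    background reads masquerade as clusters.
    """
    overrides.setdefault("reads_per_site_mean", 1200.0)
    cfg = SyntheticConfig(
        n_sites_per_class={CLASS_ENDOGENOUS: 30, CLASS_CONSTITUTIVE: 300},
        libraries=("wt_ctrl", "mut1_ctrl", "mut2_ctrl", "ago1_ctrl",
                   "input_ctrl"),
        **overrides,
    )
    return cfg


# ---------------------------------------------------------------------------
# transcriptome


@dataclass
class Transcript:
    tx_id: str
    length: int
    regions: dict[str, tuple[int, int]]  # feature -> half-open interval
    sequence: str
    strand: str = "+"


def region_intervals(length: int, fractions: tuple[float, float, float]
                     ) -> dict[str, tuple[int, int]]:
    b1 = round(length * fractions[0])
    b2 = round(length * (fractions[0] + fractions[1]))
    return {"five_prime_utr": (0, b1), "CDS": (b1, b2),
            "three_prime_utr": (b2, length)}


def simulate_transcriptome(config: SyntheticConfig) -> list[Transcript]:
    """Random transcript models and sequences, deterministic given seed."""
    config.validate()
    rng = np.random.default_rng([config.seed, 1])
    lo, hi = config.transcript_length_range
    lengths = rng.integers(lo, hi + 1, size=config.n_transcripts)
    out = []
    for i, length in enumerate(lengths):
        seq = "".join(rng.choice(list("ACGT"), size=int(length)))
        out.append(Transcript(
            tx_id=f"tx{i:04d}", length=int(length),
            regions=region_intervals(int(length), config.region_fractions),
            sequence=seq))
    return out


# ---------------------------------------------------------------------------
# site planting


@dataclass
class SyntheticTruth:
    """Planted ground truth: one row per site, plus the guide sequence."""

    sites: pd.DataFrame  # site_id, transcript, start, end, strand, class, true_log2_ratio, motif
    guide: str


def _draw_ratios(cls: str, n: int, params: tuple[float, float],
                 rng: np.random.Generator) -> np.ndarray:
    mean, sd = params
    lo, hi = RATIO_BOUNDS[cls]
    if sd == 0:
        return np.full(n, np.clip(mean, lo, hi))
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=n,
                               random_state=rng)


def plant_sites(transcripts: list[Transcript], guide: str,
                config: SyntheticConfig) -> SyntheticTruth:
    """Plant labeled sites uniformly per nt, sequences edited in place.

    Each site occupies ``site_length`` nt; sites never overlap within a
    transcript. The planted motif is the reverse complement (DNA) of
    the class's guide subregion, centered in the site; on-target sites
    carry the full-length reverse complement of the guide.
    """
    config.validate()
    guide = guide.upper().replace("T", "U")
    if len(guide) < 8:
        raise ConfigError(f"guide must be >= 8 nt, got {len(guide)}")
    if config.n_sites_per_class.get(CLASS_ON_TARGET, 0) > 1:
        raise ConfigError("at most one on_target site may be planted")
    for cls, sub in PAIRING_SUBREGIONS.items():
        if sub and config.n_sites_per_class.get(cls, 0):
            if sub[1] > len(guide):
                raise ConfigError(
                    f"pairing subregion {sub} for class {cls!r} exceeds "
                    f"guide length {len(guide)}")
    if config.site_length < len(guide):
        raise ConfigError("site_length must be >= guide length")

    rng = np.random.default_rng([config.seed, 2])
    slen = config.site_length
    # candidate start positions, uniform per nt over the transcriptome
    cand = [(t, s) for t in transcripts for s in range(t.length - slen + 1)]
    order = rng.permutation(len(cand))

    n_wanted = sum(config.n_sites_per_class.values())
    labels = [cls for cls in SITE_CLASSES
              for _ in range(config.n_sites_per_class.get(cls, 0))]
    occupied: dict[str, list[tuple[int, int]]] = {t.tx_id: [] for t in transcripts}
    placed: list[tuple[Transcript, int]] = []
    for idx in order:
        if len(placed) == n_wanted:
            break
        tx, start = cand[idx]
        if any(start < e and s < start + slen for s, e in occupied[tx.tx_id]):
            continue
        occupied[tx.tx_id].append((start, start + slen))
        placed.append((tx, start))
    if len(placed) < n_wanted:
        raise GenerationError(
            f"transcriptome too small: placed {len(placed)} of {n_wanted} sites")

    seqs = {t.tx_id: list(t.sequence) for t in transcripts}
    rows = []
    for i, (label, (tx, start)) in enumerate(zip(labels, placed)):
        sub = PAIRING_SUBREGIONS[label]
        if label == CLASS_ON_TARGET:
            sub = (1, len(guide))
        motif = ""
        if sub is not None:
            motif = reverse_complement(guide[sub[0] - 1:sub[1]], alphabet="DNA")
            off = start + (slen - len(motif)) // 2
            seqs[tx.tx_id][off:off + len(motif)] = list(motif)
        ratio = _draw_ratios(label, 1, config.ratio_params[label], rng)[0]
        strength = config.reads_per_site_mean * 2.0 ** (
            rng.normal(0.0, config.site_strength_log2_sd))
        rows.append((f"site{i:04d}", tx.tx_id, start, start + slen, "+",
                     label, float(ratio), float(strength), motif))
    for t in transcripts:
        t.sequence = "".join(seqs[t.tx_id])

    sites = pd.DataFrame(rows, columns=[
        "site_id", "transcript", "start", "end", "strand", "class",
        "true_log2_ratio", "site_strength", "motif"])
    return SyntheticTruth(sites=sites, guide=guide)


# ---------------------------------------------------------------------------
# read simulation


def expected_site_reads(truth: SyntheticTruth, config: SyntheticConfig,
                        library: str) -> np.ndarray:
    """Expected read count at every planted site in one library."""
    protein, cond = parse_library_id(library)
    lam = np.zeros(len(truth.sites))
    if protein == "INPUT":
        return lam
    strength = truth.sites["site_strength"].to_numpy(dtype=float)
    cls = truth.sites["class"].to_numpy()
    ratio = truth.sites["true_log2_ratio"].to_numpy()
    active = np.array([c not in SHRNA_DEPENDENT_CLASSES or cond == "shrna"
                       for c in cls], dtype=bool)
    if protein in ("MUT", "AGO1"):
        lam[active] = strength[active]
    elif protein == "WT":
        lam[active] = strength[active] * 2.0 ** (-ratio[active])
    return lam


def resolve_depths(truth: SyntheticTruth, config: SyntheticConfig,
                   total_nt: int) -> dict[str, int]:
    """Per-library totals unless configured explicitly.

    Each CLIP library's depth is derived from its own expected site
    reads and the background fraction, keeping the genomic background
    equally sparse in every condition; input libraries are sized at
    ``input_reads_per_nt`` x transcriptome length.
    """
    if config.library_depths is not None:
        depths = {lib: int(config.library_depths[lib]) for lib in config.libraries}
        if any(d <= 0 for d in depths.values()):
            raise ConfigError("library_depths must be positive")
        return depths
    frac = 1.0 - config.background_read_fraction
    input_depth = max(math.ceil(config.input_reads_per_nt * total_nt), 1)
    depths = {}
    for lib in config.libraries:
        if parse_library_id(lib)[0] == "INPUT":
            depths[lib] = input_depth
            continue
        site_reads = expected_site_reads(truth, config, lib).sum()
        if site_reads == 0.0:
            depths[lib] = 10_000  # pure-background simulation
        elif frac <= 0:
            raise ConfigError("background_read_fraction=1 needs explicit "
                              "depths when sites are planted")
        else:
            depths[lib] = math.ceil(site_reads / frac)
    return depths


def simulate_reads(truth: SyntheticTruth, transcripts: list[Transcript],
                   config: SyntheticConfig) -> dict[str, pd.DataFrame]:
    """Per-library read 5' starts; totals equal library depths exactly.

    Site reads start within ``read_jitter`` nt of the site midpoint
    (the crosslink sits at the center of the binding footprint), so
    single-linkage clustering at 6 nt reunites them and the called
    cluster interval, extended by a small flank, covers the whole
    planted site. The uniform background (and the whole input library)
    is drawn per nt over the transcriptome.
    """
    config.validate()
    tx_lengths = np.array([t.length for t in transcripts], dtype=np.int64)
    tx_ids = np.array([t.tx_id for t in transcripts], dtype=object)
    tx_offsets = np.concatenate(([0], np.cumsum(tx_lengths)))
    total_nt = int(tx_offsets[-1])
    depths = resolve_depths(truth, config, total_nt)

    out = {}
    for k, lib in enumerate(config.libraries):
        rng = np.random.default_rng([config.seed, 3, k])
        depth = depths[lib]
        lam = expected_site_reads(truth, config, lib)
        probs = lam / depth
        p_bg = 1.0 - probs.sum()
        if p_bg < 0:
            raise ConfigError(
                f"library {lib!r}: expected site reads {lam.sum():.0f} exceed "
                f"depth {depth}; raise library_depths")
        counts = rng.multinomial(depth, np.append(probs, p_bg))
        chroms, positions = [], []
        mids = ((truth.sites["start"].to_numpy()
                 + truth.sites["end"].to_numpy()) // 2)
        txs = truth.sites["transcript"].to_numpy()
        for s in range(len(truth.sites)):
            c = counts[s]
            if c == 0:
                continue
            chroms.append(np.full(c, txs[s], dtype=object))
            jit = rng.integers(-config.read_jitter, config.read_jitter + 1,
                               size=c)
            positions.append(np.maximum(mids[s] + jit, 0))
        n_bg = counts[-1]
        if n_bg:
            gpos = rng.integers(0, total_nt, size=n_bg)
            tx_idx = np.searchsorted(tx_offsets, gpos, side="right") - 1
            chroms.append(tx_ids[tx_idx])
            positions.append(gpos - tx_offsets[tx_idx])
        reads = pd.DataFrame({
            "chrom": np.concatenate(chroms) if chroms else np.array([], dtype=object),
            "strand": "+",
            "pos": (np.concatenate(positions).astype(np.int64)
                    if positions else np.array([], dtype=np.int64)),
        })
        out[lib] = reads.sort_values(["chrom", "pos"], ignore_index=True)
    return out


# ---------------------------------------------------------------------------
# fixture serialization


def write_gtf(transcripts: list[Transcript], path) -> None:
    """Simplified GTF: one five_prime_utr/CDS/three_prime_utr row each."""
    rows = []
    for t in transcripts:
        for feature, (s, e) in t.regions.items():
            if e <= s:
                continue
            rows.append((t.tx_id, "sliceclip_sim", feature, s + 1, e, ".",
                         t.strand, ".",
                         f'gene_id "{t.tx_id}"; transcript_id "{t.tx_id}";'))
    pd.DataFrame(rows).to_csv(path, sep="\t", header=False, index=False)


def write_fasta(records: dict[str, str], path) -> None:
    from Bio.Seq import Seq
    from Bio.SeqIO import write as seqio_write
    from Bio.SeqRecord import SeqRecord
    seqio_write([SeqRecord(Seq(s), id=name, description="")
                 for name, s in records.items()], str(path), "fasta")


def write_fixture_dir(outdir, config: SyntheticConfig,
                      guide: str = DEFAULT_GUIDE) -> dict:
    """Run the full generator and serialize everything under ``outdir``.

    Writes ``genome.fa``, ``annotation.gtf``, ``guide.fa``,
    ``truth.tsv`` and ``reads/<library>.bed``; returns the in-memory
    objects for callers that keep going.
    """
    from .clusters import write_reads_bed6

    outdir = Path(outdir)
    (outdir / "reads").mkdir(parents=True, exist_ok=True)
    transcripts = simulate_transcriptome(config)
    truth = plant_sites(transcripts, guide, config)
    reads = simulate_reads(truth, transcripts, config)

    write_fasta({t.tx_id: t.sequence for t in transcripts}, outdir / "genome.fa")
    write_gtf(transcripts, outdir / "annotation.gtf")
    write_fasta({"guide": truth.guide}, outdir / "guide.fa")
    truth.sites.to_csv(outdir / "truth.tsv", sep="\t", index=False)
    for lib, df in reads.items():
        write_reads_bed6(df, lib, outdir / "reads" / f"{lib}.bed")
    return {"transcripts": transcripts, "truth": truth, "reads": reads}
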