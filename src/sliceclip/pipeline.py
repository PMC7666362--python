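"""End-to-end orchestration: cluster calling -> noise filter ->
universe -> enrichment -> classification -> annotation -> pairing
profile, with all thresholds in one config object.

The stages are plain library calls; this module wires them in the
order the method runs, logs per-stage record counts to stderr and
serializes every intermediate as TSV/BED so a run is inspectable and
byte-reproducible given the seed.
"""

from __future__ import annotations

import logging
import sys
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO

from . import classify as _classify
from . import clusters as _clusters
from . import pairing as _pairing
from . import regions as _regions
from .classify import KThreshold
from .clusters import ClusterUniverse

logger = logging.getLogger("sliceclip")


def configure_logging(verbose: bool = True) -> None:
    handler = logging.StreamHandler(sys.stderr)
    handler.setFormatter(logging.Formatter("[%(name)s] %(message)s"))
    logger.handlers[:] = [handler]
    logger.setLevel(logging.INFO if verbose else logging.WARNING)


@dataclass
class PipelineConfig:
    """All thresholds of the analysis, defaulting to the published values."""

    window: int = 6                    # nt, single-linkage cluster gap
    min_rpm: float = 5.0               # cluster abundance floor (strict >)
    min_fold_input: float = 15.0       # CLIP/input enrichment floor
    pseudocount: float = 0.1           # RPM, all ratio numerators/denominators
    k_method: str = "density"          # "density" | "fixed"
    k_fixed: float = 3.0               # used when k_method == "fixed" or as fallback
    k_density_alpha: float = 0.05
    bounds_lower: float = 1.4          # noncleaved band lower edge (closed)
    bounds_upper: float = 2.0          # cleaved threshold (closed)
    min_fold_endogenous: float = 2.0
    profile_flank: int = 10            # nt added around a site for sequence search
    seed: int = 0
    extra: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {k: v for k, v in raw.items() if k in cls.__dataclass_fields__}
        unknown = {k: v for k, v in raw.items()
                   if k not in cls.__dataclass_fields__}
        cfg = cls(**known)
        cfg.extra = unknown
        return cfg

    def validate(self) -> None:
        positive = ["window", "min_rpm", "min_fold_input", "pseudocount",
                    "bounds_lower", "bounds_upper", "min_fold_endogenous"]
        for name in positive:
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.bounds_lower >= self.bounds_upper:
            raise ValueError("bounds_lower must be below bounds_upper")
        if self.k_method not in ("density", "fixed"):
            raise ValueError("k_method must be 'density' or 'fixed'")


def load_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper()
            for rec in SeqIO.parse(str(path), "fasta")}


def load_read_sets(paths: dict[str, Path]) -> tuple[dict, dict]:
    """BED6 read files -> (reads per library, totals per library)."""
    reads, totals = {}, {}
    for lib, path in paths.items():
        df = _clusters.read_bed6(path)
        reads[lib] = df
        totals[lib] = len(df)
        logger.info("loaded %s: %d reads", lib, len(df))
    return reads, totals


def _specific_clusters(reads: pd.DataFrame, total: int,
                       input_reads: pd.DataFrame, input_total: int,
                       cfg: PipelineConfig, label: str) -> pd.DataFrame:
    clus = _clusters.call_clusters(reads, window=cfg.window)
    clus = _clusters.compute_rpm(clus, total)
    kept = _clusters.input_noise_filter(
        clus, input_reads, input_total,
        min_rpm=cfg.min_rpm, min_fold=cfg.min_fold_input,
        pseudocount=cfg.pseudocount)
    logger.info("%s: %d clusters, %d survive input filter",
                label, len(clus), len(kept))
    return kept


@dataclass
class SirnaResult:
    universe: ClusterUniverse
    k: KThreshold
    enriched: pd.DataFrame
    site_calls: pd.DataFrame
    region_distribution: dict[str, _regions.RegionDistribution]
    profiles: pd.DataFrame | None


def run_sirna_analysis(
    reads: dict[str, pd.DataFrame],
    totals: dict[str, int],
    guide: str,
    genome: dict[str, str],
    models: list[_regions.TranscriptModel],
    cfg: PipelineConfig | None = None,
    wt_shrna: str = "wt_shrna",
    wt_ctrl: str = "wt_ctrl",
    mutant_libs: tuple[str, str] = ("mut1_shrna", "mut2_shrna"),
    input_shrna: str = "input_shrna",
    input_ctrl: str = "input_ctrl",
) -> SirnaResult:
    """siRNA on/off-target analysis against one guide.

    Requires wild-type libraries with and without the shRNA, one or
    two slicer-dead mutant libraries with the shRNA, and matching
    input libraries. Mutant replicates are pooled before RPM. The
    cluster universe combines the input-filtered clusters of the
    wild-type (both conditions) and pooled-mutant libraries; the
    shRNA fold enrichment that defines siRNA-enriched clusters is the
    wild-type with/without-shRNA contrast.
    """
    cfg = cfg or PipelineConfig()
    cfg.validate()
    required = [wt_shrna, wt_ctrl, input_shrna, input_ctrl, *mutant_libs]
    missing = [lib for lib in required if lib not in reads]
    if missing:
        raise KeyError(f"missing libraries: {missing}")

    if len(mutant_libs) == 2:
        mut_reads, mut_total = _classify.pool_mutant_libraries(
            reads[mutant_libs[0]], totals[mutant_libs[0]],
            reads[mutant_libs[1]], totals[mutant_libs[1]])
    else:
        mut_reads, mut_total = reads[mutant_libs[0]], totals[mutant_libs[0]]
    MUT = "mut_pooled"

    cluster_sets = {
        wt_shrna: _specific_clusters(
            reads[wt_shrna], totals[wt_shrna],
            reads[input_shrna], totals[input_shrna], cfg, wt_shrna),
        wt_ctrl: _specific_clusters(
            reads[wt_ctrl], totals[wt_ctrl],
            reads[input_ctrl], totals[input_ctrl], cfg, wt_ctrl),
        MUT: _specific_clusters(
            mut_reads, mut_total,
            reads[input_shrna], totals[input_shrna], cfg, MUT),
    }
    universe = _clusters.build_universe(
        cluster_sets,
        read_sets={wt_shrna: reads[wt_shrna], wt_ctrl: reads[wt_ctrl],
                   MUT: mut_reads},
        totals={wt_shrna: totals[wt_shrna], wt_ctrl: totals[wt_ctrl],
                MUT: mut_total})
    logger.info("universe: %d intervals", len(universe.intervals))

    if cfg.k_method == "fixed":
        kthr = KThreshold(k=cfg.k_fixed, method="fixed")
    else:
        fold = _classify.fold_enrichment(universe, wt_shrna, wt_ctrl,
                                         cfg.pseudocount)
        kthr = _classify.estimate_k(fold, density_alpha=cfg.k_density_alpha)
    enriched = _classify.sirna_enriched_clusters(
        universe, wt_shrna, wt_ctrl, kthr, pseudocount=cfg.pseudocount)
    logger.info("k = %.2f (%s): %d siRNA-enriched clusters",
                kthr.k, kthr.method, len(enriched))
    if len(enriched) == 0:
        raise RuntimeError("no siRNA-enriched clusters; check the shRNA "
                           "contrast libraries")

    calls = _classify.classify_sirna_sites(
        enriched,
        mutant_rpm=universe.rpm.loc[enriched.index, MUT].to_numpy(),
        wt_rpm=universe.rpm.loc[enriched.index, wt_shrna].to_numpy(),
        pseudocount=cfg.pseudocount,
        bounds=(cfg.bounds_lower, cfg.bounds_upper),
        guide=guide, genome=genome)
    calls["region"] = _regions.annotate_sites(calls, models).to_numpy()
    logger.info("site calls: %s",
                calls["class"].value_counts().to_dict())

    lengths = _regions.total_region_lengths(models)
    dist = {}
    for cls, grp in calls.groupby("class"):
        labeled = grp["region"][grp["region"] != _regions.REGION_OTHER]
        if len(labeled):
            dist[cls] = _regions.region_distribution(labeled, lengths)

    profiles = None
    frames = []
    for cls in ("cleaved_off_target", "noncleaved_off_target"):
        sub = calls[calls["class"] == cls]
        if len(sub) == 0:
            continue
        seqs = _pairing.extract_site_sequences(sub, genome,
                                               flank=cfg.profile_flank)
        prof = _pairing.sevenmer_profile(guide, seqs)
        df = prof.to_frame()
        df["class"] = cls
        frames.append(df)
    if frames:
        profiles = pd.concat(frames, ignore_index=True)

    return SirnaResult(universe=universe, k=kthr, enriched=enriched,
                       site_calls=calls, region_distribution=dist,
                       profiles=profiles)


@dataclass
class EndogenousResult:
    universe: ClusterUniverse
    replicate_correlation: float
    wt_mut_correlation: float
    site_calls: pd.DataFrame
    region_distribution: dict[str, _regions.RegionDistribution]


def run_endogenous_analysis(
    reads: dict[str, pd.DataFrame],
    totals: dict[str, int],
    models: list[_regions.TranscriptModel],
    cfg: PipelineConfig | None = None,
    wt_lib: str = "wt_ctrl",
    mutant_libs: tuple[str, str] = ("mut1_ctrl", "mut2_ctrl"),
    ago1_lib: str = "ago1_ctrl",
    input_lib: str = "input_ctrl",
) -> EndogenousResult:
    """Endogenous miRNA-mediated cleavage-site analysis.

    Pools the two slicer-dead replicates, builds a universe over the
    wild-type / pooled-mutant / AGO1 filtered clusters, reports the
    mutant replicate concordance and the WT-vs-mutant correlation of
    log abundances, and calls cleavage sites by the dual >= 2-fold
    (AGO1/WT and mutant/WT) criterion.
    """
    cfg = cfg or PipelineConfig()
    cfg.validate()
    required = [wt_lib, ago1_lib, input_lib, *mutant_libs]
    missing = [lib for lib in required if lib not in reads]
    if missing:
        raise KeyError(f"missing libraries: {missing}")

    mut_reads, mut_total = _classify.pool_mutant_libraries(
        reads[mutant_libs[0]], totals[mutant_libs[0]],
        reads[mutant_libs[1]], totals[mutant_libs[1]])
    MUT = "mut_pooled"

    cluster_sets = {
        lib: _specific_clusters(r, t, reads[input_lib], totals[input_lib],
                                cfg, lib)
        for lib, r, t in [
            (wt_lib, reads[wt_lib], totals[wt_lib]),
            (MUT, mut_reads, mut_total),
            (ago1_lib, reads[ago1_lib], totals[ago1_lib]),
        ]
    }
    universe = _clusters.build_universe(
        cluster_sets,
        read_sets={wt_lib: reads[wt_lib], MUT: mut_reads,
                   ago1_lib: reads[ago1_lib],
                   mutant_libs[0]: reads[mutant_libs[0]],
                   mutant_libs[1]: reads[mutant_libs[1]]},
        totals={wt_lib: totals[wt_lib], MUT: mut_total,
                ago1_lib: totals[ago1_lib],
                mutant_libs[0]: totals[mutant_libs[0]],
                mutant_libs[1]: totals[mutant_libs[1]]})
    logger.info("universe: %d intervals", len(universe.intervals))

    rep_r = _clusters.correlate_libraries(
        universe, mutant_libs[0], mutant_libs[1], cfg.pseudocount)
    wt_mut_r = _clusters.correlate_libraries(
        universe, wt_lib, MUT, cfg.pseudocount)
    logger.info("replicate r = %.4f, WT-vs-mutant r = %.4f", rep_r, wt_mut_r)

    calls = _classify.endogenous_cleavage_sites(
        universe, ago1_lib, MUT, wt_lib,
        pseudocount=cfg.pseudocount, min_fold=cfg.min_fold_endogenous)
    calls["region"] = _regions.annotate_sites(calls, models).to_numpy()
    n_called = int(calls["endogenous_cleavage"].sum())
    logger.info("endogenous cleavage sites: %d of %d intervals",
                n_called, len(calls))

    lengths = _regions.total_region_lengths(models)
    dist = {}
    called = calls[calls["endogenous_cleavage"]]
    labeled = called["region"][called["region"] != _regions.REGION_OTHER]
    if len(labeled):
        dist["endogenous_cleavage"] = _regions.region_distribution(
            labeled, lengths)
    return EndogenousResult(
        universe=universe, replicate_correlation=rep_r,
        wt_mut_correlation=wt_mut_r, site_calls=calls,
        region_distribution=dist)


# ---------------------------------------------------------------------------
# serialization of results


def write_sirna_result(result: SirnaResult, outdir) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    result.universe.to_frame().to_csv(outdir / "universe.tsv", sep="\t",
                                      index=False)
    result.site_calls.to_csv(outdir / "site_calls.tsv", sep="\t", index=False)
    for cls, grp in result.site_calls.groupby("class"):
        _clusters.write_clusters(
            grp.rename(columns={"fold_sirna": "score"}).assign(
                count=0, rpm=grp["ratio_norm"]),
            outdir / f"sites_{cls}.bed")
    frames = [d.to_frame().assign(**{"class": cls})
              for cls, d in result.region_distribution.items()]
    if frames:
        pd.concat(frames, ignore_index=True).to_csv(
            outdir / "region_distribution.tsv", sep="\t", index=False)
    if result.profiles is not None:
        result.profiles.to_csv(outdir / "sevenmer_profile.tsv", sep="\t",
                               index=False)
    with open(outdir / "thresholds.yaml", "w") as fh:
        yaml.safe_dump({"k": float(result.k.k), "k_method": result.k.method},
                       fh)


def write_endogenous_result(result: EndogenousResult, outdir) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    result.universe.to_frame().to_csv(outdir / "universe.tsv", sep="\t",
                                      index=False)
    result.site_calls.to_csv(outdir / "site_calls.tsv", sep="\t", index=False)
    frames = [d.to_frame().assign(**{"class": cls})
              for cls, d in result.region_distribution.items()]
    if frames:
        pd.concat(frames, ignore_index=True).to_csv(
            outdir / "region_distribution.tsv", sep="\t", index=False)
    with open(outdir / "metrics.yaml", "w") as fh:
        yaml.safe_dump({
            "replicate_correlation": float(result.replicate_correlation),
            "wt_mut_correlation": float(result.wt_mut_correlation),
            "n_called": int(result.site_calls["endogenous_cleavage"].sum()),
        }, fh)


def config_to_yaml(cfg: PipelineConfig, path) -> None:
    d = asdict(cfg)
    d.pop("extra", None)
    with open(path, "w") as fh:
        yaml.safe_dump(d, fh)
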