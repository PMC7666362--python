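"""Shared fixtures: scaled simulations and truth-matching helpers.

The heavy end-to-end simulations (full default configs, three seeds)
are session-scoped so recovery tests and acceptance tests share one
run per seed.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import sliceclip as sc
from sliceclip import pipeline as pl

RECOVERY_SEEDS = (11, 23, 42)


def simulate_scenario(config: sc.SyntheticConfig, guide: str | None = None):
    """Run the generator and return everything downstream stages need."""
    guide = guide or sc.synthetic.DEFAULT_GUIDE
    transcripts = sc.simulate_transcriptome(config)
    truth = sc.plant_sites(transcripts, guide, config)
    reads = sc.simulate_reads(truth, transcripts, config)
    totals = {lib: len(df) for lib, df in reads.items()}
    genome = {t.tx_id: t.sequence for t in transcripts}
    models = [
        sc.TranscriptModel(t.tx_id, t.tx_id, t.strand,
                           {k: [v] for k, v in t.regions.items() if v[1] > v[0]})
        for t in transcripts
    ]
    return {"config": config, "truth": truth, "reads": reads,
            "totals": totals, "genome": genome, "models": models,
            "transcripts": transcripts}


def match_truth(intervals: pd.DataFrame, truth: sc.SyntheticTruth) -> pd.Series:
    """Planted class overlapping each interval ('none' if background)."""
    sites = truth.sites
    labels = []
    for row in intervals.itertuples(index=False):
        hit = sites[(sites["transcript"] == row.chrom)
                    & (sites["start"] < row.end)
                    & (row.start < sites["end"])]
        labels.append(hit["class"].iloc[0] if len(hit) else "none")
    return pd.Series(labels, index=intervals.index, name="true_class")


@pytest.fixture(scope="session")
def sirna_runs():
    """Full siRNA-scenario pipeline runs for the recovery seeds."""
    out = {}
    for seed in RECOVERY_SEEDS:
        sim = simulate_scenario(sc.SyntheticConfig(seed=seed))
        result = pl.run_sirna_analysis(
            sim["reads"], sim["totals"], sim["truth"].guide,
            sim["genome"], sim["models"])
        calls = result.site_calls.copy()
        calls["true_class"] = match_truth(calls, sim["truth"]).to_numpy()
        out[seed] = {"sim": sim, "result": result, "calls": calls}
    return out


@pytest.fixture(scope="session")
def endogenous_runs():
    """Full endogenous-scenario pipeline runs for the recovery seeds."""
    out = {}
    for seed in RECOVERY_SEEDS:
        sim = simulate_scenario(sc.endogenous_config(seed=seed))
        result = pl.run_endogenous_analysis(
            sim["reads"], sim["totals"], sim["models"])
        calls = result.site_calls.copy()
        calls["true_class"] = match_truth(calls, sim["truth"]).to_numpy()
        out[seed] = {"sim": sim, "result": result, "calls": calls}
    return out


@pytest.fixture()
def small_config():
    """A fast, miniature scenario for smoke-level tests."""
    return sc.SyntheticConfig(
        n_transcripts=40,
        n_sites_per_class={"on_target": 1, "cleaved": 3, "noncleaved": 3,
                           "background": 10, "constitutive": 20},
        reads_per_site_mean=100.0,
        site_strength_log2_sd=0.5,
        seed=7,
    )


def random_reads(rng: np.random.Generator, n: int,
                 n_chroms: int = 3, span: int = 2000) -> pd.DataFrame:
    chroms = rng.choice([f"chr{i}" for i in range(1, n_chroms + 1)], size=n)
    strands = rng.choice(["+", "-"], size=n)
    pos = rng.integers(0, span, size=n)
    return pd.DataFrame({"chrom": chroms, "strand": strands, "pos": pos})
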