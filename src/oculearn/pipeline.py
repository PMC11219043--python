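"""End-to-end orchestration: simulate -> analyze -> stats.

``run_analysis`` reads traces, measures every test, aggregates blocks and
learning curves, and writes four delimited-text tables plus a JSON run
manifest.  ``run_stats`` runs the group comparisons on the learning table.
All outputs are deterministic under a fixed config and input set.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import pandas as pd

from . import __version__
from .config import PipelineConfig, config_hash
from .core import EmptyResultsError
from .desaccade import measure_test
from .metrics import learning_tables
from .stats import ComparisonSpec, rm_anova_tukey
from .synthetic import cohort_from_config, design_from_config, simulate_cohort
from .io import read_traces, write_dataset

__all__ = ["run_simulate", "run_analysis", "run_stats"]

log = logging.getLogger(__name__)


def run_simulate(config: PipelineConfig, outdir: str | Path) -> pd.DataFrame:
    """Simulate the configured cohort and write it to ``outdir``."""
    design = design_from_config(config.design)
    cohort = cohort_from_config(config.cohort)
    if "seed" not in (config.cohort or {}):
        cohort.seed = config.seed
    dataset = simulate_cohort(design, cohort)
    log.info(
        "simulated %d traces (%d animals, protocol %s)",
        len(dataset.traces),
        sum(g.n_animals for g in cohort.groups.values()),
        design.protocol,
    )
    return write_dataset(dataset, outdir)


def run_analysis(
    config: PipelineConfig, indir: str | Path, outdir: str | Path
) -> dict[str, pd.DataFrame]:
    """Measure every trace under ``indir`` and write the result tables.

    Writes ``qc.csv`` (one row per test), ``blocks.csv``, ``learning.csv``
    and ``manifest.json`` to ``outdir``.  Raises
    :class:`EmptyResultsError` when no test is valid.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log.info("analysis parameters: %s", config.analysis)
    traces = read_traces(indir)
    measurements = [measure_test(tr, params=config.analysis) for tr in traces]
    for m in measurements:
        if not m.valid:
            log.info(
                "excluded test %s (reason=%s, excluded_fraction=%.3f)",
                {k: m.metadata.get(k) for k in ("animal", "time_min", "test_index")},
                m.reason,
                m.excluded_fraction,
            )
    qc = pd.DataFrame(
        [
            {
                "animal": m.metadata.get("animal"),
                "group": m.metadata.get("group"),
                "protocol": m.metadata.get("protocol"),
                "time_min": m.metadata.get("time_min"),
                "test_index": m.metadata.get("test_index"),
                "amplitude": m.amplitude,
                "gain": m.gain,
                "phase": m.phase,
                "excluded_fraction": m.excluded_fraction,
                "valid": m.valid,
                "reason": m.reason,
            }
            for m in measurements
        ]
    )
    n_valid = int(qc["valid"].sum()) if len(qc) else 0
    if n_valid == 0:
        qc.to_csv(outdir / "qc.csv", index=False)
        raise EmptyResultsError("no valid tests in the input set")
    blocks, learning = learning_tables(measurements)
    qc.to_csv(outdir / "qc.csv", index=False)
    blocks.to_csv(outdir / "blocks.csv", index=False)
    learning.to_csv(outdir / "learning.csv", index=False)
    manifest = {
        "config_hash": config_hash(config),
        "version": __version__,
        "seed": config.seed,
        "n_tests": len(measurements),
        "n_valid_tests": n_valid,
        "n_excluded_tests": len(measurements) - n_valid,
        "n_blocks": int(len(blocks)),
        "n_learning_points": int(len(learning)),
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return {"qc": qc, "blocks": blocks, "learning": learning}


def run_stats(
    config: PipelineConfig, learning: pd.DataFrame, outdir: str | Path | None = None
) -> pd.DataFrame:
    """Group x time repeated-measures ANOVA (+ Tukey) on the learning table.

    The baseline learning point is identically zero for every animal by
    construction and carries no information, so only post-baseline time
    points enter the ANOVA.  Writes ``stats.csv`` and ``tukey.csv`` when
    ``outdir`` is given; returns the comparisons table (one row per
    contrast: label, statistic, df, p, significant).
    """
    alpha = config.stats.alpha
    d = learning.dropna(subset=["delta_pct"])
    d = d[d["time_min"] > 0]
    spec = ComparisonSpec(
        response="delta_pct",
        between="group" if d["group"].nunique() > 1 else None,
        within="time_min",
        subject="animal",
    )
    aov, tukey, results = rm_anova_tukey(d, spec, alpha)
    rows = [
        {
            "label": r.label,
            "statistic": r.statistic,
            "df": str(r.df),
            "p": r.p,
            "significant": r.significant,
        }
        for r in results
    ]
    comparisons = pd.DataFrame(rows)
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        comparisons.to_csv(outdir / "stats.csv", index=False)
        tukey.to_csv(outdir / "tukey.csv", index=False)
        aov.to_csv(outdir / "anova.csv", index=False)
    return comparisons
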