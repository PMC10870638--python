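"""End-to-end pipeline: split by age, describe, correlate, factor, compare.

A run is fully determined by its configuration (all seeds are explicit; no
wall-clock defaults) and writes plain-text artifacts to a run directory:

* ``descriptives.tsv`` — per-item two-group comparison battery
* ``rankings.json`` — top-k occurrence/severity/distress lists per group
* ``loadings_<group>.tsv`` — rotated loading table at the chosen k
* ``diagnostics_<group>.json`` — per-k fit diagnostics
* ``stability_report.json`` / ``stability_report.txt`` — cluster comparison
* ``run_log.json`` — versions, seeds and every setting in effect

Numeric artifacts are written at full precision except the loading tables,
whose 3-decimal rounding is a display convention; rendered reports apply
display rounding only.
"""

from __future__ import annotations

import json
import logging
import platform
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .clusters import clusters_from_loading_frame, read_loading_table, write_loading_table
from .compare import StabilityReport, compare_cluster_sets
from .dataset import SymptomDataset, dichotomize_by_age
from .descriptives import comparison_frame, compare_groups, mean_symptom_count, \
    occurrence_rates, rank_top_symptoms
from .efa import factor_solution
from .reference import CLUSTER_LABELS
from .tetrachoric import tetrachoric_matrix

__all__ = ["PipelineConfig", "run_pipeline", "render_report"]

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Settings for one end-to-end run (all analysis choices explicit)."""

    age_cutoff: float = 60.0
    alpha: float = 0.05
    loading_threshold: float = 0.40
    k_min: int = 2
    k_max: int = 8
    chosen_k_younger: int = 8
    chosen_k_older: int = 8
    geomin_epsilon: float = 0.01
    rotation_starts: int = 30
    rotation_seed: int = 1
    top_k: int = 10
    cluster_labels: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.k_min < 2:
            raise ValueError("k_min must be >= 2")
        if self.loading_threshold <= 0:
            raise ValueError("loading_threshold must be > 0")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)


def _json_dump(obj, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n", encoding="utf-8")


def _analyze_group(
    dataset: SymptomDataset, group: str, chosen_k: int, config: PipelineConfig, outdir: Path
):
    est = tetrachoric_matrix(dataset)
    sol = factor_solution(
        est.matrix.to_numpy(),
        chosen_k,
        epsilon=config.geomin_epsilon,
        n_starts=config.rotation_starts,
        seed=config.rotation_seed,
        item_codes=dataset.catalog.codes,
    )
    frame = sol.rotated_frame()
    write_loading_table(frame, outdir / f"loadings_{group}.tsv")
    est.matrix.round(6).to_csv(outdir / f"tetrachoric_{group}.tsv", sep="\t")
    _json_dump(
        {
            "psd_adjusted": est.psd_adjusted,
            "min_eigenvalue_before": est.min_eigenvalue_before,
            "frobenius_change": est.frobenius_change,
            "zero_cell_corrections": est.corrections,
            "residual_rmsr": sol.residual_rmsr,
            "converged": sol.converged,
            "heywood_items": sol.heywood_items,
            "rotation_starts_agreeing": sol.n_random_starts_agreeing,
        },
        outdir / f"diagnostics_{group}.json",
    )
    return clusters_from_loading_frame(
        frame, config.loading_threshold, group=group, labels=config.cluster_labels, source=sol
    )


def run_pipeline(config: PipelineConfig, dataset: SymptomDataset, outdir: str | Path) -> StabilityReport:
    """Run the full analysis and write all artifacts to ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stage = "age split"
    try:
        split = dichotomize_by_age(dataset, config.age_cutoff)

        stage = "descriptives"
        rows, n_sig = compare_groups(split, config.alpha)
        df = comparison_frame(rows)
        df.to_csv(outdir / "descriptives.tsv", sep="\t")
        rankings = {}
        for group, ds in (("younger", split.younger), ("older", split.older)):
            rates = occurrence_rates(ds)
            mean, sd = mean_symptom_count(ds)
            ranked = rank_top_symptoms(rates * 100, config.top_k)
            rankings[group] = {
                "n": ds.n,
                "mean_symptom_count": mean,
                "sd_symptom_count": sd,
                "top_occurrence": [
                    {"rank": r, "code": c, "percent": v} for c, v, r in ranked.entries
                ],
            }
        rankings["n_items_significant_occurrence"] = n_sig
        _json_dump(rankings, outdir / "rankings.json")

        stage = "factor analysis (younger)"
        set_y = _analyze_group(split.younger, "younger", config.chosen_k_younger, config, outdir)
        stage = "factor analysis (older)"
        set_o = _analyze_group(split.older, "older", config.chosen_k_older, config, outdir)

        stage = "cluster comparison"
        report = compare_cluster_sets(set_y, set_o)
        _json_dump(report.to_dict(), outdir / "stability_report.json")
        (outdir / "stability_report.txt").write_text(report.render_text() + "\n", encoding="utf-8")

        _json_dump(
            {
                "symclust_version": __version__,
                "numpy_version": np.__version__,
                "pandas_version": pd.__version__,
                "python_version": platform.python_version(),
                "config": asdict(config),
                "n_records": dataset.n,
                "group_sizes": {"younger": split.younger.n, "older": split.older.n},
                "provenance": dataset.provenance,
            },
            outdir / "run_log.json",
        )
    except Exception as exc:  # noqa: BLE001 - annotate failing stage
        raise RuntimeError(f"pipeline failed at stage '{stage}': {exc}") from exc
    return report


def render_report(run_dir: str | Path) -> str:
    """Markdown summary of a completed run (one block per matched pair)."""
    run_dir = Path(run_dir)
    needed = ["stability_report.json", "rankings.json", "run_log.json"]
    for name in needed:
        if not (run_dir / name).exists():
            raise FileNotFoundError(f"missing artifact: {name}")
    rep = json.loads((run_dir / "stability_report.json").read_text(encoding="utf-8"))
    ranks = json.loads((run_dir / "rankings.json").read_text(encoding="utf-8"))
    log = json.loads((run_dir / "run_log.json").read_text(encoding="utf-8"))

    ga, gb = rep["group_a"], rep["group_b"]
    s = rep["summary"]
    lines = [
        "# Symptom cluster comparison",
        "",
        f"Groups: **{ga}** (n={ranks[ga]['n']}) vs **{gb}** (n={ranks[gb]['n']}), "
        f"age cutoff {log['config']['age_cutoff']}.",
        f"Mean symptom count: {ranks[ga]['mean_symptom_count']:.1f} ({ga}) vs "
        f"{ranks[gb]['mean_symptom_count']:.1f} ({gb}); "
        f"{ranks['n_items_significant_occurrence']} items differ in occurrence at "
        f"alpha={log['config']['alpha']}.",
        "",
        f"Matched cluster pairs: {s['n_pairs']} — {s['n_stable']} stable, "
        f"{s['n_consistent']} consistent, {s['n_inconsistent']} not consistent.",
        "",
    ]
    for p in rep["pairs"]:
        name = p["label"] or p["cluster_a"] or p["cluster_b"]
        lines.append(f"## {name}")
        lines.append("")
        lines.append(f"- shared symptoms: {p['overlap']} ({', '.join(p['shared'])})")
        lines.append(f"- stable: {'yes' if p['stable'] else 'NO'}")
        if p["consistency"] is not None:
            verdict = "consistent" if p["consistent"] else "not consistent"
            lines.append(f"- consistency {p['consistency']}: **{verdict}**")
            lines.append(f"- top symptoms {ga}: {', '.join(p['top_a'])}")
            lines.append(f"- top symptoms {gb}: {', '.join(p['top_b'])}")
        lines.append("")
    return "\n".join(lines)


def default_cluster_labels() -> dict[str, str]:
    """Display labels for the bundled reference cluster ids."""
    return dict(CLUSTER_LABELS)
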