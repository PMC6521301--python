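"""End-to-end orchestration: cohort -> QC -> classification -> weights ->
GRS panels -> covariate-adjusted fits -> stepwise refinement ->
retrenchment sweep, with a reproducible manifest.

All randomness flows from the single configured seed (the simulation is
the only stochastic stage), so a rerun with the same config is
byte-identical.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import pandas as pd

from . import classify, models, qc, retrench, scoring
from .cohort import SimulationConfig, simulate_cohort, write_cohort
from .genotypes import GenotypeMatrix, read_genotypes
from .panel import REPLICATION_PANEL

__all__ = ["PipelineConfig", "run_pipeline", "plot_grs_distribution"]


@dataclass
class PipelineConfig:
    """Exactly one of ``simulation`` or (``genotypes`` + ``phenotypes``)."""

    simulation: dict[str, Any] | None = None
    genotypes: str | None = None
    genotype_format: str = "vcf"
    phenotypes: str | None = None
    panels: tuple[str, ...] = ("all", "replication_7", "refined")
    entry_p: float = 0.15
    stay_p: float = 0.15
    retrench_step: int = 10
    retrench_min_n: int = 30
    seed: int = 0
    out_dir: str = "grspipe_out"

    def __post_init__(self) -> None:
        has_sim = self.simulation is not None
        has_files = self.genotypes is not None or self.phenotypes is not None
        if has_sim == has_files:
            raise ValueError(
                "config must supply exactly one of a simulation block or "
                "genotype+phenotype paths"
            )
        if has_files and (self.genotypes is None or self.phenotypes is None):
            raise ValueError("both genotype and phenotype paths are required")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        import yaml

        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {', '.join(sorted(unknown))}")
        if "panels" in raw:
            raw["panels"] = tuple(raw["panels"])
        return cls(**raw)


@dataclass
class PipelineResult:
    summary: dict[str, Any]
    artifacts: dict[str, str]
    out_dir: Path = field(default=Path("."))


def _load_inputs(config: PipelineConfig, out: Path):
    if config.simulation is not None:
        sim_kwargs = dict(config.simulation)
        sim_kwargs.setdefault("seed", config.seed)
        causal = sim_kwargs.get("causal_snps")
        if causal is not None:
            sim_kwargs["causal_snps"] = [tuple(c) for c in causal]
        sim = SimulationConfig(**sim_kwargs)
        cohort = simulate_cohort(sim)
        paths = write_cohort(cohort, out / "cohort")
        return cohort.genotypes, cohort.phenotypes, paths
    matrix = read_genotypes(config.genotypes, config.genotype_format)
    phenotypes = classify.read_phenotypes(config.phenotypes)
    return matrix, phenotypes, {
        "genotypes": str(config.genotypes),
        "phenotypes": str(config.phenotypes),
    }


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Run all stages in dependency order and write a summary manifest."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, str] = {}

    matrix, phenotypes, input_paths = _load_inputs(config, out)
    artifacts.update(input_paths)

    # QC
    qc_frame = qc.qc_report_frame(matrix)
    qc_path = out / "qc_report.tsv"
    qc_frame.to_csv(qc_path, sep="\t", index=False)
    artifacts["qc_report"] = str(qc_path)
    hwe_failures = sorted(qc_frame.loc[~qc_frame["in_hwe"], "rsid"].tolist())

    # classification
    result = classify.classify_responders(phenotypes)
    classified = result.table
    desc_path = out / "descriptive_table.tsv"
    classify.descriptive_frame(classified).to_csv(desc_path, sep="\t", index=False)
    artifacts["descriptive_table"] = str(desc_path)

    # weights
    aligned = classified.set_index("participant_id").reindex(matrix.participant_ids)
    if aligned["responder"].isna().any():
        missing = aligned.index[aligned["responder"].isna()].tolist()
        raise ValueError(
            "participants lack classification (missing phenotypes): "
            + ", ".join(map(str, missing[:5]))
        )
    responder_flags = aligned["responder"].to_numpy(dtype=bool)
    weights = scoring.compute_weights(matrix, responder_flags)
    weights_path = out / "risk_weights.tsv"
    scoring.write_weights(weights, weights_path)
    artifacts["risk_weights"] = str(weights_path)

    summary: dict[str, Any] = {
        "seed": config.seed,
        "n_participants": len(matrix.participant_ids),
        "n_snps": len(matrix.snps),
        "n_responders": result.n_responders,
        "n_non_responders": result.n_non_responders,
        "percent_non_responders": result.percent_non_responders,
        "n_rejected_rows": len(result.rejected_ids),
        "hwe_failures": hwe_failures,
        "panels": {},
    }

    def _score_and_fit(panel_rsids, name):
        grs = scoring.compute_grs(matrix, weights, panel_rsids, panel_name=name)
        grs_path = out / f"grs_{name}.csv"
        grs.to_frame().to_csv(grs_path, index=False)
        artifacts[f"grs_{name}"] = str(grs_path)
        fit = models.fit_grs_model(classified, grs)
        summary["panels"][name] = {
            "n_snps": len(panel_rsids),
            "n_scored": grs.n,
            "grs_percent_variance": round(fit.grs_percent_variance, 4),
            "partial_eta2_percent": round(fit.partial_eta2_percent, 4),
            "grs_p": fit.grs_p,
        }
        return grs, fit

    grs_by_panel: dict[str, scoring.GrsVector] = {}
    if "all" in config.panels:
        grs_by_panel["all"], _ = _score_and_fit(matrix.rsids, "all")
    if "replication_7" in config.panels:
        missing = [r for r in REPLICATION_PANEL if r not in matrix.rsids]
        if missing:
            raise ValueError(
                "stage replication_7: panel rsids absent from genotypes: "
                + ", ".join(missing)
            )
        grs_by_panel["replication_7"], _ = _score_and_fit(
            list(REPLICATION_PANEL), "replication_7"
        )

    refined_grs = None
    if "refined" in config.panels:
        sw = models.stepwise_select(
            classified, matrix, entry_p=config.entry_p, stay_p=config.stay_p
        )
        sw_path = out / "stepwise_log.tsv"
        pd.DataFrame(sw.log, columns=["rsid", "action", "p"]).to_csv(
            sw_path, sep="\t", index=False
        )
        artifacts["stepwise_log"] = str(sw_path)
        summary["stepwise_selected"] = sw.selected
        if sw.selected:
            refined_grs, _ = _score_and_fit(sw.selected, "refined")
        else:
            summary["panels"]["refined"] = None

    # retrenchment on the refined panel (falls back to the full panel)
    sweep_grs = refined_grs or grs_by_panel.get("all")
    if sweep_grs is not None:
        rows = retrench.retrench_and_refit(
            classified, sweep_grs,
            step=config.retrench_step, min_n=config.retrench_min_n,
        )
        ret_path = out / "retrenchment.tsv"
        retrench.retrenchment_frame(rows).to_csv(ret_path, sep="\t", index=False)
        artifacts["retrenchment"] = str(ret_path)
        summary["retrenchment"] = [
            {
                "excluded_responders": r.n_responders_excluded,
                "excluded_non_responders": r.n_non_responders_excluded,
                "n_included": r.n_included,
                "pct_variance": round(r.grs_percent_variance, 4),
                "grs_p": r.grs_p,
            }
            for r in rows
        ]

    summary_path = out / "summary.json"
    summary_path.write_text(json.dumps(summary, indent=2, sort_keys=True) + "\n")
    artifacts["summary"] = str(summary_path)
    manifest_path = out / "manifest.json"
    manifest_path.write_text(
        json.dumps({"artifacts": artifacts, "seed": config.seed},
                   indent=2, sort_keys=True) + "\n"
    )
    return PipelineResult(summary=summary, artifacts=artifacts, out_dir=out)


def plot_grs_distribution(grs: scoring.GrsVector, path: str | Path) -> None:
    """Bar chart of the integer GRS distribution, annotated with n."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    hist = scoring.grs_distribution(grs)
    fig, ax = plt.subplots(figsize=(7, 4))
    ax.bar(list(hist.keys()), list(hist.values()), color="#4878a8")
    ax.set_xlabel("Genetic risk score")
    ax.set_ylabel("Number of participants")
    ax.set_title(f"GRS distribution — {grs.panel_name} (n = {grs.n})")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
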