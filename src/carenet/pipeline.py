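"""End-to-end study runs: simulate or ingest, build, measure, score, model.

A run is described by a :class:`RunManifest` (inputs or simulation config,
build rule, stages, seed, output directory).  :func:`run_study` executes
the full sequence — patient descriptives, network metric table and
summary, metric correlations, continuity models (total score and the
relational-base subscale), social-integration models — writing plain CSV
and text renderings plus GraphML exports and a JSON manifest, and returns
everything in memory as a :class:`RunBundle`.

The default build rule is the main analysis rule (participants only,
"sometimes or often"); the two sensitivity variants (full matrix;
often-only) are the same pipeline with a different rule, and
:func:`sensitivity_compare` lays two runs side by side.
"""

from __future__ import annotations

import dataclasses
import datetime
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd

import carenet
from carenet.network_build import DirectedNetwork, build_network, summarize_build, write_graphml
from carenet.network_metrics import correlation_matrix, metrics_table
from carenet.outcome_models import (
    ModelResult,
    fit_continuity_bivariate,
    fit_continuity_stepwise,
    fit_six_model,
    render_model_tables,
)
from carenet.patient_scores import outcome_table, DEFAULT_SUBSCALE_MAP
from carenet.survey_io import analysis_set, read_patients, read_roster, read_ties
from carenet.synthetic_data import SimulationConfig, generate_study

__all__ = ["RunManifest", "RunBundle", "run_study", "sensitivity_compare", "DEFAULT_ANALYSIS_METRICS"]

logger = logging.getLogger("carenet.pipeline")

#: Network exposures entered in the outcome models, mirroring the usual
#: regression-table rows: size, social-service share, dissimilarity,
#: centralization, clustering, density and the four Coleman indices.
DEFAULT_ANALYSIS_METRICS: tuple[str, ...] = (
    "n_services",
    "prop_social_services",
    "dissimilarity_index",
    "degree_centralization",
    "clustering",
    "density",
    "coleman_primary_care",
    "coleman_crisis_outreach",
    "coleman_social_services",
    "coleman_psychiatric_ward",
)


@dataclass
class RunManifest:
    """What to run and where.  Either ``simulate`` or the three input paths."""

    out_dir: str | Path
    simulate: Optional[SimulationConfig] = None
    services_path: Optional[str | Path] = None
    ties_path: Optional[str | Path] = None
    patients_path: Optional[str | Path] = None
    threshold: str = "sometimes_or_often"
    scope: str = "participants_only"
    analysis_metrics: tuple[str, ...] = DEFAULT_ANALYSIS_METRICS
    fit_models: bool = True
    six_model2_stage: str = "stepwise"  # or "multivariate" (forced entry)
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if self.simulate is None and not (self.services_path and self.ties_path and self.patients_path):
            raise ValueError("provide either a simulation config or all three input paths")
        if self.simulate is not None and self.seed is not None:
            self.simulate = dataclasses.replace(self.simulate, seed=int(self.seed))


@dataclass
class RunBundle:
    """All outputs of one run, in memory, plus the files written."""

    manifest: RunManifest
    networks: list[DirectedNetwork]
    metric_rows: pd.DataFrame
    metric_summary: pd.DataFrame
    patient_table: pd.DataFrame
    continuity_models: list[ModelResult]
    six_models: list[ModelResult]
    files: dict[str, str] = field(default_factory=dict)


def _group_by_network(items, key) -> dict[str, list]:
    out: dict[str, list] = {}
    for it in items:
        out.setdefault(key(it), []).append(it)
    return out


def run_study(manifest: RunManifest) -> RunBundle:
    """Execute the full pipeline described by ``manifest``.

    Stage order: (1) tabulate patient characteristics and outcomes;
    (2) build the networks under the manifest's rule and describe their
    structure (metric table, summary, Pearson correlations); (3) regress
    patient outcomes on network exposures (Model 1 bivariate per metric,
    Model 2 stepwise), for continuity (linear mixed) and social
    integration (random-intercept proportional odds).
    """
    out = Path(manifest.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    files: dict[str, str] = {}

    log_path = out / "run.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    try:
        if manifest.simulate is not None:
            logger.info("simulating study with seed %s", manifest.simulate.seed)
            data_dir = out / "data"
            study = generate_study(manifest.simulate, data_dir)
            manifest.services_path = data_dir / "services.csv"
            manifest.ties_path = data_dir / "ties.csv"
            manifest.patients_path = data_dir / "patients.csv"

        roster = read_roster(manifest.services_path)
        ties = read_ties(manifest.ties_path, roster)
        patients = read_patients(manifest.patients_path)
        complete = analysis_set(patients)
        logger.info(
            "parsed %d services (%d participated), %d tie records, %d patients (%d complete, %d excluded)",
            len(roster),
            sum(1 for s in roster if s.participated),
            len(ties),
            len(patients),
            len(complete),
            len(patients) - len(complete),
        )

        # stage 1: patient descriptives
        table1 = outcome_table(complete, DEFAULT_SUBSCALE_MAP)
        table1.to_csv(out / "table1_patients.csv")
        files["table1_patients"] = str(out / "table1_patients.csv")

        # stage 2: networks and structure
        roster_by_net = _group_by_network(roster, lambda s: s.network_id)
        ties_by_net = _group_by_network(ties, lambda t: t.network_id)
        networks = []
        for net_id in sorted(roster_by_net):
            nw = build_network(
                roster_by_net[net_id],
                ties_by_net.get(net_id, []),
                threshold=manifest.threshold,
                scope=manifest.scope,
            )
            logger.info("built %s", summarize_build(nw))
            networks.append(nw)
        graph_dir = out / "graphs"
        graph_dir.mkdir(exist_ok=True)
        for nw in networks:
            write_graphml(nw, graph_dir / f"{nw.network_id}.graphml")

        metric_rows, metric_summary = metrics_table(networks)
        metric_rows.to_csv(out / "table2_metrics.csv")
        metric_summary.to_csv(out / "table2_summary.csv")
        files["table2_metrics"] = str(out / "table2_metrics.csv")
        files["table2_summary"] = str(out / "table2_summary.csv")
        if len(networks) >= 3:
            corr = correlation_matrix(metric_rows, [m for m in manifest.analysis_metrics if m in metric_rows])
            corr.starred().to_csv(out / "table3_correlations.csv")
            files["table3_correlations"] = str(out / "table3_correlations.csv")
            if corr.dropped:
                logger.warning("metrics constant across networks, not correlated: %s", corr.dropped)

        continuity_models: list[ModelResult] = []
        six_models: list[ModelResult] = []
        if manifest.fit_models:
            usable = [m for m in manifest.analysis_metrics if _usable(metric_rows, m)]
            skipped = sorted(set(manifest.analysis_metrics) - set(usable))
            if skipped:
                logger.warning("metrics unusable for models (constant or too many missing): %s", skipped)

            for outcome in ("continuity", "continuity:relational_base"):
                for m in usable:
                    continuity_models.append(fit_continuity_bivariate(complete, m, metric_rows, outcome))
                cands = [
                    r.selected[0]
                    for r in continuity_models
                    if r.outcome == outcome and r.stage == "bivariate" and r.pvalues[r.selected[0]] < 0.05
                ]
                logger.info("%s: Model-1-significant metrics: %s", outcome, cands)
                continuity_models.append(fit_continuity_stepwise(complete, cands, metric_rows, outcome))

            for m in usable:
                six_models.append(fit_six_model(complete, [m], metric_rows, stage="bivariate"))
            six_cands = [
                r.selected[0] for r in six_models if r.stage == "bivariate" and r.pvalues[r.selected[0]] < 0.05
            ]
            logger.info("six: Model-1-significant metrics: %s", six_cands)
            if six_cands:
                six_models.append(
                    fit_six_model(complete, six_cands, metric_rows, stage=manifest.six_model2_stage)
                )

            t4, t4_txt = render_model_tables(continuity_models)
            t4.to_csv(out / "table4_continuity.csv", index=False)
            (out / "table4_continuity.txt").write_text(t4_txt)
            files["table4_continuity"] = str(out / "table4_continuity.csv")
            if six_models:
                t5, t5_txt = render_model_tables(six_models)
                t5.to_csv(out / "table5_six.csv", index=False)
                (out / "table5_six.txt").write_text(t5_txt)
                files["table5_six"] = str(out / "table5_six.csv")

        manifest_record = {
            "version": carenet.__version__,
            "timestamp": datetime.datetime.now(datetime.timezone.utc).isoformat(),
            "threshold": manifest.threshold,
            "scope": manifest.scope,
            "seed": manifest.simulate.seed if manifest.simulate is not None else manifest.seed,
            "inputs": {
                "services": str(manifest.services_path),
                "ties": str(manifest.ties_path),
                "patients": str(manifest.patients_path),
            },
            "analysis_metrics": list(manifest.analysis_metrics),
            "files": files,
        }
        (out / "manifest.json").write_text(json.dumps(manifest_record, indent=2))
        files["manifest"] = str(out / "manifest.json")
    except Exception:
        logger.exception("pipeline stage failed; partial outputs preserved in %s", out)
        raise
    finally:
        logger.removeHandler(handler)
        handler.close()

    return RunBundle(
        manifest=manifest,
        networks=networks,
        metric_rows=metric_rows,
        metric_summary=metric_summary,
        patient_table=table1,
        continuity_models=continuity_models,
        six_models=six_models,
        files=files,
    )


def _usable(metric_rows: pd.DataFrame, metric: str) -> bool:
    if metric not in metric_rows.columns:
        return False
    col = metric_rows[metric].dropna()
    return len(col) >= 2 and col.nunique() > 1


def sensitivity_compare(bundle_a: RunBundle, bundle_b: RunBundle, alpha: float = 0.05) -> pd.DataFrame:
    """Side-by-side coefficient deltas between two runs of the same study.

    One row per (outcome, stage, covariate) present in either run's model
    tables, with both estimates, their difference (b - a), and whether
    significance at ``alpha`` flipped.  Raises when the two bundles
    modeled different outcome sets.
    """

    def tidy(bundle: RunBundle) -> pd.DataFrame:
        table, _ = render_model_tables(bundle.continuity_models + bundle.six_models)
        return table[~table["row"].isin(["icc", "aic"])]

    ta, tb = tidy(bundle_a), tidy(bundle_b)
    if set(ta["outcome"]) != set(tb["outcome"]):
        raise ValueError(
            f"outcome sets differ: {sorted(set(ta['outcome']))} vs {sorted(set(tb['outcome']))}"
        )
    merged = ta.merge(tb, on=["outcome", "stage", "model", "row"], how="outer", suffixes=("_a", "_b"))
    merged["delta"] = merged["estimate_b"] - merged["estimate_a"]
    merged["significant_a"] = merged["p_value_a"] < alpha
    merged["significant_b"] = merged["p_value_b"] < alpha
    merged["significance_flip"] = merged["significant_a"] != merged["significant_b"]
    return merged
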