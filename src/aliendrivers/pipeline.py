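"""End-to-end orchestration: clean → trends → outliers → network → models → varpart.

A single :class:`PipelineConfig` drives the whole analysis, either from
CSV inputs (records + predictor table) or from the synthetic generator.
One master seed fans out to per-stage seeds through
``numpy.random.SeedSequence(seed).spawn``, so each stage is individually
reproducible and two runs with the same config produce identical tables.
Every run writes a JSON manifest recording the config hash, seed, package
versions and the SHA-256 of each output file.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .models import (
    filter_collinear,
    fit_glm,
    forward_select,
    influence_diagnostics,
    kfold_cv,
    overdispersion_test,
    standardize,
)
from .network import build_country_graph, jaccard_matrix, network_metrics, write_graph_outputs
from .outliers import outlier_table
from .records import (
    PredictorTable,
    build_occurrence_matrix,
    clean_records,
    composition_summary,
    read_predictor_table,
    read_species_records,
    write_cleaned_records,
)
from .simulate import SynthConfig, generate_dataset
from .trends import trend_table
from .varpart import partition_with_tests

logger = logging.getLogger(__name__)

STAGES = ("data", "trends", "outliers", "network", "models", "varpart")


class PipelineStageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    """Everything the pipeline needs; seed is mandatory."""

    seed: int
    outdir: str = "pipeline_out"
    synthetic: bool = True
    synth: SynthConfig | None = None
    records_path: str | None = None
    predictors_path: str | None = None
    european_countries: list[str] | None = None
    alpha: float = 0.05
    vif_threshold: float = 10.0
    criterion: str = "aicc"
    family_m1: str = "negative_binomial"
    family_m2: str = "gaussian"
    trend_response: str = "S"  # S | tau
    network_threshold: float = 0.0
    outlier_method: str = "proportional"
    n_perm: int = 10_000
    cv_folds: int = 5
    log_response_varpart: bool = False

    def __post_init__(self) -> None:
        if self.synth is None and self.synthetic:
            self.synth = SynthConfig(seed=self.seed)
        if not self.synthetic:
            for path in (self.records_path, self.predictors_path):
                if path is None or not Path(path).exists():
                    raise FileNotFoundError(f"input file not found: {path}")
        if self.trend_response not in ("S", "tau"):
            raise ValueError("trend_response must be 'S' or 'tau'")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text())
        synth = raw.pop("synth", None)
        if synth is not None:
            synth = SynthConfig(**synth)
        return cls(synth=synth, **raw)

    def canonical_json(self) -> str:
        def default(o):
            if dataclasses.is_dataclass(o):
                return dataclasses.asdict(o)
            raise TypeError(type(o))

        return json.dumps(dataclasses.asdict(self), sort_keys=True, default=default)


def _stage_seeds(seed: int) -> dict[str, int]:
    ss = np.random.SeedSequence(seed)
    spawned = ss.spawn(len(STAGES))
    return {
        stage: int(s.generate_state(1)[0] % 2**31)
        for stage, s in zip(STAGES, spawned)
    }


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_csv(frame: pd.DataFrame, path: Path, index: bool = False) -> None:
    frame.to_csv(path, index=index, float_format="%.10g")


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage; returns the manifest dict (also written to disk)."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seeds = _stage_seeds(config.seed)
    outputs: list[Path] = []
    stage = "data"
    try:
        # ------------------------------------------------------------ data
        if config.synthetic:
            synth = dataclasses.replace(config.synth, seed=seeds["data"])
            dataset = generate_dataset(synth)
            records = dataset.records
            predictors = dataset.predictors
            regions = dataset.regions
            series = dataset.annual_series
            report = None
        else:
            raw = read_species_records(config.records_path)
            europe = config.european_countries or sorted(
                {r.country for r in raw}
            )
            records, report = clean_records(raw, europe)
            predictors = read_predictor_table(config.predictors_path)
            regions = pd.Series(
                "unknown", index=predictors.countries, name="region"
            )
            series = None
        matrix = build_occurrence_matrix(records)
        richness = matrix.richness.reindex(predictors.countries).fillna(0).astype(int)

        write_cleaned_records(records, outdir / "cleaned_records.csv")
        outputs.append(outdir / "cleaned_records.csv")
        for level in ("phylum", "class"):
            comp = composition_summary(records, level)
            _write_csv(comp, outdir / f"composition_{level}.csv")
            outputs.append(outdir / f"composition_{level}.csv")
        if report is not None:
            report.to_json(outdir / "cleaning_report.json")
            outputs.append(outdir / "cleaning_report.json")

        # ---------------------------------------------------------- trends
        stage = "trends"
        if series is None:
            from .records import annual_first_records

            series = {}
            for country in matrix.countries:
                try:
                    series[country] = annual_first_records(records, country)
                except ValueError:
                    logger.warning("no dated records for %s; skipped", country)
        trends = trend_table(series, sig_level=config.alpha)
        _write_csv(trends, outdir / "trends.csv")
        outputs.append(outdir / "trends.csv")

        # -------------------------------------------------------- outliers
        stage = "outliers"
        observed = richness
        out_tab = outlier_table(
            predictors.data,
            observed,
            alpha=config.alpha,
            method=config.outlier_method,
        )
        _write_csv(out_tab, outdir / "outliers.csv")
        outputs.append(outdir / "outliers.csv")

        # --------------------------------------------------------- network
        stage = "network"
        sim = jaccard_matrix(matrix)
        sim.to_frame().to_csv(outdir / "similarity_matrix.csv", float_format="%.10g")
        outputs.append(outdir / "similarity_matrix.csv")
        graph = build_country_graph(
            sim,
            matrix.richness,
            regions.reindex(matrix.countries).fillna("unknown"),
            threshold=config.network_threshold,
        )
        write_graph_outputs(graph, outdir)
        outputs += [outdir / "network.graphml", outdir / "network_edges.csv"]
        metrics = network_metrics(graph)
        _write_csv(metrics, outdir / "network_metrics.csv")
        outputs.append(outdir / "network_metrics.csv")

        # ---------------------------------------------------------- models
        stage = "models"
        Xz = standardize(predictors.data)
        Xz_table = PredictorTable(data=Xz, categories=predictors.categories)
        filtered, vif_report = filter_collinear(Xz_table, config.vif_threshold)
        vif_frame = pd.DataFrame(
            {
                "predictor": list(vif_report.vif),
                "vif": list(vif_report.vif.values()),
            }
        )
        vif_frame["removed"] = False
        removed_frame = pd.DataFrame(
            {
                "predictor": [n for n, _ in vif_report.removed],
                "vif": [v for _, v in vif_report.removed],
                "removed": True,
            }
        )
        _write_csv(pd.concat([removed_frame, vif_frame]), outdir / "vif_report.csv")
        outputs.append(outdir / "vif_report.csv")

        model_summary: dict[str, dict] = {}
        trend_resp = trends.set_index("country")[config.trend_response].reindex(
            filtered.countries
        )
        responses = {
            "m1": (richness.reindex(filtered.countries), config.family_m1),
            "m2": (trend_resp, config.family_m2),
        }
        for name, (y, family) in responses.items():
            trace = forward_select(
                y, filtered, family=family, criterion=config.criterion
            )
            design = filtered.data[trace.final_predictors]
            fit = fit_glm(y, design, family=family, criterion=config.criterion)
            coef = fit.coefficients.copy()
            coef.insert(0, "term", coef.index)
            _write_csv(coef, outdir / f"{name}_coefficients.csv")
            outputs.append(outdir / f"{name}_coefficients.csv")
            trace_frame = pd.DataFrame(
                trace.steps, columns=["added", "criterion_value"]
            )
            _write_csv(trace_frame, outdir / f"{name}_selection_trace.csv")
            outputs.append(outdir / f"{name}_selection_trace.csv")
            diag = influence_diagnostics(fit, design)
            _write_csv(diag, outdir / f"{name}_influence.csv")
            outputs.append(outdir / f"{name}_influence.csv")
            cv = kfold_cv(
                y, design, family=family, k=config.cv_folds, seed=seeds["models"]
            )
            summary = {
                "family": family,
                "selected": trace.final_predictors,
                "criterion": config.criterion,
                "criterion_value": fit.criterion_value,
                "theta": fit.theta,
                "cv_mean_deviance": cv.mean_deviance,
            }
            if family in ("negative_binomial", "poisson") and not (y < 0).any():
                disp, p, flag = overdispersion_test(y, design, alpha=config.alpha)
                summary["overdispersion"] = {
                    "dispersion": disp,
                    "p_value": p,
                    "overdispersed": flag,
                }
            model_summary[name] = summary
        (outdir / "models_summary.json").write_text(
            json.dumps(model_summary, indent=2, default=float) + "\n"
        )
        outputs.append(outdir / "models_summary.json")

        # --------------------------------------------------------- varpart
        stage = "varpart"
        blocks = {
            label: standardize(frame.reindex(richness.index))
            for label, frame in predictors.blocks().items()
        }
        response = (
            np.log1p(richness.to_numpy(dtype=float))
            if config.log_response_varpart
            else richness.to_numpy(dtype=float)
        )
        vp = partition_with_tests(
            response, blocks, n_perm=config.n_perm, seed=seeds["varpart"]
        )
        _write_csv(vp.to_frame(), outdir / "varpart_fractions.csv")
        outputs.append(outdir / "varpart_fractions.csv")
        vp_json = {
            "blocks": vp.blocks,
            "marginal_r2adj": {
                "+".join(sorted(k)): v for k, v in vp.marginal_r2adj.items()
            },
            "venn_fractions": {
                "&".join(sorted(k)): v for k, v in vp.venn_fractions.items()
            },
            "residual": vp.residual,
            "p_values": vp.p_values,
            "n_permutations": vp.n_permutations,
        }
        (outdir / "varpart.json").write_text(
            json.dumps(vp_json, indent=2, default=float) + "\n"
        )
        outputs.append(outdir / "varpart.json")

    except Exception as exc:
        (outdir / "FAILED").write_text(f"stage {stage}: {exc}\n")
        raise PipelineStageError(stage, exc) from exc

    manifest = {
        "package_version": __version__,
        "seed": config.seed,
        "stage_seeds": seeds,
        "config_sha256": hashlib.sha256(
            config.canonical_json().encode()
        ).hexdigest(),
        "outputs": {
            str(p.relative_to(outdir)): _sha256(p) for p in sorted(set(outputs))
        },
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return manifest
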