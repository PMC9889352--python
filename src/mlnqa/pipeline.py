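"""Pipeline orchestration: simulate → classify → tabulate → charts →
regression, with a reproducible run manifest.

Every stage output is a pure function of the inputs and the seed, so two
runs with the same config and seed produce byte-identical non-image
outputs. Failures are recorded in the manifest with the failing stage name
and the run exits nonzero.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd

import mlnqa
from mlnqa.classifier import classified_frame, classify_corpus
from mlnqa.control_charts import DEFAULT_ALPHAS, build_chart, render_chart
from mlnqa.lexicon import (
    load_default_diagnosis_lexicon,
    load_default_site_lexicon,
    load_lexicon,
)
from mlnqa.rate_tables import provider_rates, tabulate_by_station, tabulate_groups
from mlnqa.regression import fit_category_model, roc_from_model, trim_design
from mlnqa.report_io import filter_inclusion, read_corpus
from mlnqa.synthetic import SyntheticConfig, generate_corpus

DEFAULT_OUTCOMES = (
    "benign",
    "suspicious",
    "malignant",
    "insufficient",
    "adenocarcinoma",
    "squamous_cell_carcinoma",
    "non_small_cell_carcinoma",
    "small_cell_carcinoma",
)


class PipelineError(RuntimeError):
    """A pipeline stage failed; the manifest names the stage."""


@dataclass
class RunConfig:
    """Declarative run configuration (YAML-loadable)."""

    corpus_path: str | None = None  # if None, simulate
    synthetic: dict = field(default_factory=dict)  # SyntheticConfig overrides
    dx_lexicon: str | None = None  # TSV path; None = packaged
    dx_categories: str | None = None
    site_lexicon: str | None = None
    site_categories: str | None = None
    min_n: int = 250
    min_station: int = 20
    alphas: tuple[float, ...] = DEFAULT_ALPHAS
    normalization: str = "indirect"  # raw|indirect
    outcomes: tuple[str, ...] = DEFAULT_OUTCOMES
    render_images: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        self.alphas = tuple(sorted((float(a) for a in self.alphas), reverse=True))

    def config_hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def load_run_config(path: str | Path) -> RunConfig:
    import yaml

    with open(path, encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    return RunConfig(**raw)


def _json_dump(obj, path: Path) -> None:
    path.write_text(json.dumps(obj, sort_keys=True, indent=2, default=str) + "\n", encoding="utf-8")


def run_pipeline(config: RunConfig, outdir: str | Path, seed: int | None = None) -> dict:
    """Execute all stages, writing artifacts and a manifest to ``outdir``.

    Returns the manifest. On stage failure the manifest (already written)
    records the stage and error, and :class:`PipelineError` is raised.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if seed is not None:
        config = dataclasses.replace(config, seed=seed)
    manifest: dict = {
        "package_version": mlnqa.__version__,
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "config": dataclasses.asdict(config),
        "stages": {},
    }
    stage = "init"
    try:
        stage = "lexicons"
        if config.dx_lexicon:
            dx_lex = load_lexicon(config.dx_lexicon, "diagnosis", config.dx_categories)
        else:
            dx_lex = load_default_diagnosis_lexicon()
        if config.site_lexicon:
            site_lex = load_lexicon(config.site_lexicon, "site", config.site_categories)
        else:
            site_lex = load_default_site_lexicon()
        manifest["stages"][stage] = {"status": "ok", "dx_entries": len(dx_lex.entries), "site_entries": len(site_lex.entries)}

        stage = "corpus"
        if config.corpus_path:
            records = read_corpus(config.corpus_path)
            truth = None
        else:
            syn = SyntheticConfig(seed=config.seed, **config.synthetic)
            records, truth = generate_corpus(
                syn,
                corpus_path=outdir / "corpus.jsonl",
                truth_path=outdir / "truth.jsonl",
                dx_lex=dx_lex,
                site_lex=site_lex,
            )
        records = filter_inclusion(records)
        manifest["stages"][stage] = {"status": "ok", "n_records": len(records)}

        stage = "classify"
        classified = classify_corpus(records, dx_lex, site_lex)
        cf = classified_frame(classified)
        cf.to_csv(outdir / "classified.csv", index=False)
        manifest["stages"][stage] = {
            "status": "ok",
            "n_unclassified": int((cf["exclusive_group"] == "unclassified").sum()),
            "n_changed_by_addendum": int(cf["changed_by_addendum"].sum()),
        }

        stage = "tables"
        groups = tabulate_groups(cf)
        groups.to_frame().to_csv(outdir / "table_groups.tsv", sep="\t", index=False)
        _json_dump(
            {"counts": groups.counts, "total": groups.total, "fractions": groups.display_fractions()},
            outdir / "table_groups.json",
        )
        crosstab = tabulate_by_station(cf, min_records=config.min_station)
        crosstab.display().to_csv(outdir / "table_stations.tsv", sep="\t")
        _json_dump(json.loads(crosstab.display().to_json(orient="columns")), outdir / "table_stations.json")
        manifest["stages"][stage] = {"status": "ok"}

        stage = "rates_charts"
        chart_meta = {}
        chart_dir = outdir / "charts"
        chart_dir.mkdir(exist_ok=True)
        for role in ("pathologist", "sps"):
            table = provider_rates(cf, role, min_n=config.min_n)
            table.rows.to_csv(outdir / f"provider_rates_{role}.tsv", sep="\t")
            for group in ("benign", "suspicious", "malignant", "insufficient"):
                chart = build_chart(table, group, alphas=config.alphas, mode=config.normalization)
                _json_dump(chart.to_dict(), chart_dir / f"chart_{role}_{group}.json")
                if config.render_images:
                    render_chart(chart, "control_chart", chart_dir / f"chart_{role}_{group}.svg")
                    render_chart(chart, "funnel", chart_dir / f"funnel_{role}_{group}.svg")
                chart_meta[f"{role}/{group}"] = {repr(a): c for a, c in chart.outlier_counts.items()}
        manifest["stages"][stage] = {"status": "ok", "outliers": chart_meta}

        stage = "regression"
        design = trim_design(cf, min_n=config.min_n, min_station=config.min_station)
        reg_out = {
            "n_input": design.n_input,
            "n_retained": design.n_retained,
            "levels": {f: len(lv) for f, lv in design.levels.items()},
            "factor_test_kind": "likelihood_ratio",
            "models": {},
        }
        for outcome in config.outcomes:
            try:
                model = fit_category_model(design, outcome)
            except Exception as exc:  # degenerate outcome: recorded, not fatal
                reg_out["models"][outcome] = {"error": str(exc)}
                continue
            roc = roc_from_model(model)
            roc.points.to_csv(outdir / f"roc_{outcome}.tsv", sep="\t", index=False)
            reg_out["models"][outcome] = {
                "converged": model.converged,
                "separation_flag": model.separation_flag,
                "llf": model.llf,
                "n": model.n,
                "roc_area": roc.area,
                "factor_tests": [dataclasses.asdict(t) for t in model.factor_tests],
                "coefficients": model.coefficients.to_dict(orient="records"),
            }
        _json_dump(reg_out, outdir / "regression.json")
        manifest["stages"][stage] = {"status": "ok"}
    except Exception as exc:
        manifest["stages"][stage] = {"status": "error", "error": str(exc)}
        _json_dump(manifest, outdir / "manifest.json")
        raise PipelineError(f"stage {stage!r} failed: {exc}") from exc

    _json_dump(manifest, outdir / "manifest.json")
    return manifest
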