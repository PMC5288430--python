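"""End-to-end driver: simulate -> score SES -> metrics -> fit -> report.

All stage outputs are delimited text with a header row; a JSON manifest
records the configuration echo and package version so a run can be
reproduced exactly from its output directory.
"""

from __future__ import annotations

import dataclasses
import json
import os
import sys
from dataclasses import dataclass, field
from typing import Optional

import pandas as pd
import yaml

from . import __version__
from .generate import GeneratorConfig, generate_cohort
from .io import read_cohort, write_cohort, write_table
from .metrics import compute_metrics_table
from .models import (descriptive_tests, exposure_anova, fit_model_sequence,
                     interaction_test, school_aggregates)
from .ses import score_cohort

EXIT_VALIDATION = 2
EXIT_NUMERICAL = 3


@dataclass
class RunConfig:
    """Configuration of a full pipeline run.

    ``exposure_variant`` switches the separation sets between exact
    geodesic distance ("exact", default) and raw walk reachability
    ("walk"); ``distance_mode`` switches the relative-distance geodesics
    between directed (default) and symmetrized.
    """

    out_dir: str = "results/run"
    seed: int = 0
    national_fas_mean: float = 1.0
    exposure_variant: str = "exact"
    distance_mode: str = "directed"
    model_method: str = "fe"          # "fe" | "re"
    outcomes: tuple = ("regular",)
    generator: GeneratorConfig = field(default_factory=GeneratorConfig)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        gen = d.pop("generator", {})
        if isinstance(gen, dict):
            gen_kwargs = dict(gen)
            if "roster_size_range" in gen_kwargs:
                gen_kwargs["roster_size_range"] = tuple(
                    gen_kwargs["roster_size_range"])
            for k in ("ses_category_probs", "out_degree_probs"):
                if k in gen_kwargs:
                    gen_kwargs[k] = tuple(gen_kwargs[k])
            gen = GeneratorConfig(**gen_kwargs)
        cfg = cls(generator=gen, **{k: (tuple(v) if k == "outcomes" else v)
                                    for k, v in d.items()})
        return cfg

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path: str) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)


def simulate_stage(cfg: RunConfig, cohort_dir: str) -> None:
    gen = dataclasses.replace(cfg.generator, seed=cfg.seed)
    records, edges = generate_cohort(gen)
    write_cohort(records, edges, cohort_dir)


def metrics_stage(cfg: RunConfig, cohort_dir: str, out_path: str) -> pd.DataFrame:
    records, edges = read_cohort(cohort_dir)
    records, composites = score_cohort(records, cfg.national_fas_mean)
    table = compute_metrics_table(
        records, edges, composites,
        variant=cfg.exposure_variant, distance_mode=cfg.distance_mode)
    write_table(table, out_path)
    return table


def fit_stage(cfg: RunConfig, table: pd.DataFrame, out_dir: str) -> dict:
    results = {}
    for outcome in cfg.outcomes:
        fits = fit_model_sequence(table, outcome, method=cfg.model_method)
        rows = []
        for f in fits:
            merged = f.coefficients.merge(f.odds_ratios, on="term")
            merged.insert(0, "model", f.model_id)
            merged.insert(1, "outcome", outcome)
            merged["n_used"] = f.n_used
            merged["loglik"] = f.loglik
            rows.append(merged)
        df = pd.concat(rows, ignore_index=True)
        write_table(df, os.path.join(out_dir, f"models_{outcome}.csv"))
        vc_rows = [
            {"model": f.model_id, "component": k, "variance": v[0], "sd": v[1]}
            for f in fits for k, v in f.variance_components.items()
        ]
        if vc_rows:
            write_table(pd.DataFrame(vc_rows),
                        os.path.join(out_dir, f"varcomp_{outcome}.csv"))
        results[outcome] = fits
    return results


def run_pipeline(cfg: RunConfig) -> dict:
    """Run every stage; returns a dict of in-memory results.

    Deterministic given ``cfg.seed``.  Any stage failure is re-raised with
    the stage name prepended.
    """
    out = cfg.out_dir
    os.makedirs(out, exist_ok=True)
    cohort_dir = os.path.join(out, "cohort")
    stages = {}

    def run(name, fn, *args):
        try:
            return fn(*args)
        except Exception as err:
            raise type(err)(f"stage {name!r}: {err}") from err

    run("simulate", simulate_stage, cfg, cohort_dir)
    table = run("metrics", metrics_stage, cfg, cohort_dir,
                os.path.join(out, "metrics.csv"))
    stages["metrics"] = table

    stages["models"] = run("fit", fit_stage, cfg, table, out)
    wald, p = run("interaction", interaction_test, table)
    write_table(pd.DataFrame([{"wald_chi2": wald, "p": p}]),
                os.path.join(out, "interaction_test.csv"))
    stages["interaction"] = (wald, p)
    anova = run("anova", exposure_anova, table)
    write_table(anova, os.path.join(out, "exposure_by_ses.csv"))
    stages["anova"] = anova
    desc = run("descriptives", descriptive_tests, table)
    write_table(desc, os.path.join(out, "descriptive_tests.csv"))
    stages["descriptives"] = desc
    agg, corr = run("school_aggregates", school_aggregates, table)
    write_table(agg, os.path.join(out, "school_aggregates.csv"))
    write_table(corr, os.path.join(out, "school_correlations.csv"))
    stages["school_aggregates"] = (agg, corr)

    manifest = {
        "silnet_version": __version__,
        "config": cfg.to_dict(),
        "tables": sorted(f for f in os.listdir(out) if f.endswith(".csv")),
    }
    with open(os.path.join(out, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    stages["manifest"] = manifest
    return stages
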