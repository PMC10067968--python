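"""Configuration-driven orchestration of the full analysis.

``run_pipeline`` chains the stages — load (or simulate), cross-validate,
fit the final clock, per-stratum EWAS, overlap and enrichment — into one
run directory with a manifest recording input hashes, parameters and the
package version. Given a fixed seed the outputs are byte-identical across
runs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .clock import ElasticNetConfig, fit_clock
from .crossval import run_cv
from .enrich import (
    DEFAULT_FLANK_KB,
    DEFAULT_GENESET_P_MAX,
    DEFAULT_MIN_OVERLAP,
    alignable_background,
    geneset_enrichment,
    island_shift_test,
    read_gmt,
    region_enrichment,
    results_to_frame,
    state_enrichment,
)
from .ewas import DEFAULT_N_PER_DIRECTION, DEFAULT_P_THRESHOLD, overlap_sets, run_ewas, select_top
from .io import Dataset, load_dataset, serialize_clock
from .preselect import DEFAULT_K, DEFAULT_MIN_STRATUM_SIZE, preselect_cpgs, stratify
from .simulate import SimConfig, simulate_dataset

logger = logging.getLogger(__name__)


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class PipelineConfig:
    # inputs: either the three file paths, or simulate=True
    sheet: str | None = None
    beta: str | None = None
    annotation: str | None = None
    gene_sets: str | None = None  # GMT path, optional
    simulate: bool = False
    sim: dict = field(default_factory=dict)  # SimConfig overrides
    out_dir: str = "pinnclock_run"
    scheme: str = "LOOCV"
    tissue_filter: str = "both"
    k_preselect: int = DEFAULT_K
    min_stratum_size: int = DEFAULT_MIN_STRATUM_SIZE
    clock: dict = field(default_factory=dict)  # ElasticNetConfig overrides
    p_threshold: float = DEFAULT_P_THRESHOLD
    n_per_direction: int = DEFAULT_N_PER_DIRECTION
    flank_kb: float = DEFAULT_FLANK_KB
    geneset_p_max: float = DEFAULT_GENESET_P_MAX
    min_overlap: int = DEFAULT_MIN_OVERLAP
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        raw.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**raw)

    def validate(self) -> None:
        if not self.simulate and (self.sheet is None or self.beta is None):
            raise ValueError("either set simulate: true or provide sheet and beta paths")
        for name in ("p_threshold", "n_per_direction", "flank_kb", "geneset_p_max",
                     "min_overlap", "k_preselect", "min_stratum_size"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


def derive_seeds(seed: int, n: int) -> list[int]:
    """Derive n independent per-stage seeds (< 2**31) from one global seed."""
    state = np.random.SeedSequence(seed).generate_state(n, dtype=np.uint32)
    return [int(s % (2**31)) for s in state]


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _stage(name):
    def wrap(fn):
        def inner(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except StageError:
                raise
            except Exception as exc:
                raise StageError(f"[{name}] {exc}") from exc
        return inner
    return wrap


def _json_dump(obj, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute the configured stages; returns the run directory."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = derive_seeds(config.seed, 4)
    manifest: dict = {
        "package_version": __version__,
        "parameters": {k: v for k, v in asdict(config).items()},
        "stage_seeds": {"simulate": seeds[0], "clock_cv": seeds[1]},
        "inputs": {},
    }

    # ---- load or simulate ----------------------------------------------
    @_stage("input")
    def _input() -> Dataset:
        if config.simulate:
            sim_kwargs = dict(config.sim)
            sim_kwargs.setdefault("seed", seeds[0])
            if "age_range" in sim_kwargs:
                sim_kwargs["age_range"] = tuple(sim_kwargs["age_range"])
            ds, truth = simulate_dataset(SimConfig(**sim_kwargs))
            truth.to_frame().to_csv(out / "truth.csv", index=False)
            return ds
        for key in ("sheet", "beta", "annotation", "gene_sets"):
            p = getattr(config, key)
            if p is not None:
                path = Path(p)
                if not path.exists():
                    raise FileNotFoundError(f"{key} path does not exist: {p}")
                manifest["inputs"][key] = _sha256(path)
        return load_dataset(config.sheet, config.beta, config.annotation)

    dataset = _input()

    clock_cfg = ElasticNetConfig(**{"seed": seeds[1], **config.clock})

    # ---- cross-validation ------------------------------------------------
    @_stage("crossval")
    def _cv():
        report = run_cv(
            dataset,
            scheme=config.scheme,
            k_preselect=config.k_preselect,
            clock_config=clock_cfg,
            tissue_filter=config.tissue_filter,
            min_stratum_size=config.min_stratum_size,
        )
        report.predictions.to_csv(out / f"cv_{report.scheme.lower()}_predictions.csv", index=False)
        (out / f"cv_{report.scheme.lower()}_summary.json").write_text(report.to_json() + "\n")
        return report

    cv_report = _cv()

    # ---- final clock on all samples ---------------------------------------
    @_stage("clock")
    def _final_clock():
        ds = dataset
        if config.tissue_filter != "both":
            keep = ds.samples.loc[ds.samples["tissue"] == config.tissue_filter, "sample_id"]
            ds = ds.subset_samples(keep)
        panel = preselect_cpgs(
            ds, ds.sample_ids, (), k=config.k_preselect,
            min_stratum_size=config.min_stratum_size,
        )
        (out / "preselected_cpgs.txt").write_text(
            "\n".join([f"# k={config.k_preselect} seed={config.seed}"] + panel) + "\n"
        )
        model = fit_clock(ds, ds.sample_ids, panel, clock_cfg)
        serialize_clock(model, out / "clock.txt")
        return model

    model = _final_clock()

    # ---- per-stratum EWAS + overlap ---------------------------------------
    @_stage("ewas")
    def _ewas():
        strata = stratify(dataset.samples, min_stratum_size=max(4, config.min_stratum_size))
        tissue_strata = [s for s in strata if s.tissue_scope != "combined"]
        tables, tops = {}, {}
        for st in tissue_strata:
            table = run_ewas(dataset, st, p_threshold=config.p_threshold)
            table.to_csv(out / f"ewas_{st.species}_{st.tissue_scope}.csv", index_label="cpg_id")
            tables[st.name] = table
            tops[st.name] = select_top(table, config.n_per_direction, config.p_threshold)
        if len(tops) >= 2:
            for direction in ("positive", "negative"):
                rep = overlap_sets({k: getattr(v, direction) for k, v in tops.items()})
                _json_dump(rep, out / f"overlap_{direction}.json")
        return tables, tops

    ewas_tables, top_sets = _ewas()

    # ---- enrichment --------------------------------------------------------
    if dataset.annotation is not None and ewas_tables:
        @_stage("enrich")
        def _enrich():
            ann = dataset.annotation
            species = sorted(dataset.samples["species"].unique())
            bg_all = set(ann["cpg_id"]) & set(dataset.beta.index)
            bg_aligned = alignable_background(ann, species) & bg_all
            rows = []
            for name, tops in top_sets.items():
                table = ewas_tables[name]
                both = {"positive": [c for c in tops.positive if c in bg_all],
                        "negative": [c for c in tops.negative if c in bg_all]}
                for res in region_enrichment(both, ann, bg_all):
                    rows.append({"stratum": name, "analysis": "region", **res.__dict__})
                shift = island_shift_test(table, ann)
                rows.append({
                    "stratum": name, "analysis": "island_shift", "category": "island-vs-nonisland",
                    "p": shift["p"], "odds_ratio": float("nan"), "fold": shift["t"],
                    "set_size": shift["groups"]["island"]["n"],
                    "background_size": shift["groups"]["non-island"]["n"],
                    "overlap": 0, "odds_ratio_corrected": float("nan"), "direction": "",
                })
                top_aligned = [c for c in tops.positive + tops.negative if c in bg_aligned]
                if bg_aligned:
                    for res in state_enrichment(top_aligned, ann, bg_aligned):
                        rows.append({"stratum": name, "analysis": "state", **res.__dict__})
                if config.gene_sets:
                    gs = read_gmt(config.gene_sets)
                    for res in geneset_enrichment(
                        tops.positive + tops.negative, gs, ann,
                        background=bg_aligned or bg_all,
                        flank_kb=config.flank_kb,
                        p_max=config.geneset_p_max,
                        min_overlap=config.min_overlap,
                    ):
                        rows.append({"stratum": name, "analysis": "geneset", **res.__dict__})
            pd.DataFrame(rows).to_csv(out / "enrichment.csv", index=False)
            return rows

        _enrich()

    # ---- manifest + summary -------------------------------------------------
    summary = {
        "scheme": cv_report.scheme,
        "crossval": cv_report.summary_dict(),
        "final_clock": {
            "n_cpgs": model.n_cpgs,
            "intercept": model.intercept,
            "lambda": model.lambda_,
            "alpha": model.alpha,
        },
        "ewas": {
            name: {
                "n_significant": int((t["direction"] != "none").sum()),
                "n_top_positive": len(top_sets[name].positive),
                "n_top_negative": len(top_sets[name].negative),
            }
            for name, t in ewas_tables.items()
        },
    }
    _json_dump(summary, out / "summary.json")
    _json_dump(manifest, out / "manifest.json")
    return out
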