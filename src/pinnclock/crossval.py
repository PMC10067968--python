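"""Cross-validation schemes and accuracy metrics for the age clocks.

Three schemes estimate out-of-sample accuracy, each rerunning CpG
pre-selection *inside* the fold so no test information leaks into the
panel:

* **LOOCV** — leave one sample out;
* **LOAOCV** — leave one animal out (all of an animal's samples, e.g. its
  blood and skin pair, form one test fold);
* **LOSOCV** — leave one species out, estimating how well the clock
  extrapolates to species absent from training.

Accuracy is summarised by the Pearson correlation between predicted and
chronological age and by the **median** absolute error (MAE) in years.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd
from scipy import stats

from .clock import ElasticNetConfig, fit_clock, predict_age
from .io import Dataset
from .preselect import DEFAULT_K, DEFAULT_MIN_STRATUM_SIZE, preselect_cpgs

logger = logging.getLogger(__name__)

SCHEMES = ("LOOCV", "LOAOCV", "LOSOCV")


@dataclass(frozen=True)
class FoldSpec:
    fold_id: int
    test_ids: frozenset[str]
    train_ids: frozenset[str]

    def __post_init__(self) -> None:
        if not self.test_ids:
            raise ValueError("empty test set")
        if self.test_ids & self.train_ids:
            raise ValueError("test and train sets overlap")


@dataclass
class CVReport:
    """Out-of-fold predictions plus overall and per-group accuracy."""

    scheme: str
    predictions: pd.DataFrame  # sample_id, species, tissue, age_years, predicted_age, fold_id
    pearson_r: float
    mae: float
    per_species: pd.DataFrame
    per_tissue: pd.DataFrame
    n_skipped_folds: int = 0
    mean_absolute_error: float = float("nan")

    def summary_dict(self) -> dict:
        def _clean(x):
            return None if (isinstance(x, float) and math.isnan(x)) else x

        return {
            "scheme": self.scheme,
            "n_samples": int(len(self.predictions)),
            "pearson_r": _clean(round(self.pearson_r, 10) if not math.isnan(self.pearson_r) else self.pearson_r),
            "mae_years": _clean(round(self.mae, 10)),
            "mean_absolute_error_years": _clean(round(self.mean_absolute_error, 10)),
            "n_skipped_folds": self.n_skipped_folds,
            "per_species": {
                str(row["species"]): {"pearson_r": _clean(row["pearson_r"]), "mae_years": _clean(row["mae_years"]), "n": int(row["n"])}
                for _, row in self.per_species.iterrows()
            },
            "per_tissue": {
                str(row["tissue"]): {"pearson_r": _clean(row["pearson_r"]), "mae_years": _clean(row["mae_years"]), "n": int(row["n"])}
                for _, row in self.per_tissue.iterrows()
            },
        }

    def to_json(self) -> str:
        return json.dumps(self.summary_dict(), indent=2, sort_keys=True)


def make_folds(samples: pd.DataFrame, scheme: str) -> list[FoldSpec]:
    """Build the fold partition for a scheme over the analysed samples."""
    scheme = scheme.upper()
    if scheme not in SCHEMES:
        raise ValueError(f"scheme must be one of {SCHEMES}")
    if len(samples) < 2:
        raise ValueError("need at least two samples")
    all_ids = set(samples["sample_id"])
    if scheme == "LOOCV":
        groups = [{s} for s in samples["sample_id"]]
    elif scheme == "LOAOCV":
        groups = [set(g["sample_id"]) for _, g in samples.groupby("animal_id", sort=True)]
    else:
        if samples["species"].nunique() < 2:
            raise ValueError("LOSOCV requires at least two species")
        groups = [set(g["sample_id"]) for _, g in samples.groupby("species", sort=True)]
    return [
        FoldSpec(fold_id=i, test_ids=frozenset(test), train_ids=frozenset(all_ids - test))
        for i, test in enumerate(groups)
    ]


def compute_metrics(true_ages, predicted_ages) -> tuple[float, float]:
    """(Pearson r, median absolute error). r is NaN when either side is constant."""
    t = np.asarray(true_ages, float)
    p = np.asarray(predicted_ages, float)
    if t.shape != p.shape or len(t) == 0:
        raise ValueError("equal non-zero lengths required")
    mae = float(np.median(np.abs(p - t)))
    if np.ptp(t) == 0 or np.ptp(p) == 0:
        return float("nan"), mae
    r = float(np.clip(np.corrcoef(t, p)[0, 1], -1.0, 1.0))
    return r, mae


def _group_metrics(df: pd.DataFrame, by: str, min_n: int = 3) -> pd.DataFrame:
    rows = []
    for key, g in df.groupby(by, sort=True):
        if len(g) < min_n:
            continue
        r, mae = compute_metrics(g["age_years"], g["predicted_age"])
        rows.append({by: key, "pearson_r": r, "mae_years": mae, "n": len(g)})
    return pd.DataFrame(rows, columns=[by, "pearson_r", "mae_years", "n"])


def run_cv(
    dataset: Dataset,
    scheme: str,
    k_preselect: int = DEFAULT_K,
    clock_config: ElasticNetConfig | None = None,
    tissue_filter: str = "both",
    min_stratum_size: int = DEFAULT_MIN_STRATUM_SIZE,
) -> CVReport:
    """Run {preselect -> fit -> predict} over every fold of a scheme.

    ``tissue_filter`` restricts the analysed samples first ("blood", "skin"
    or "both"), supporting tissue-specific clocks. Folds whose training set
    cannot support pre-selection or fitting are skipped with a warning and
    excluded from the metrics; their count is reported.
    """
    clock_config = clock_config or ElasticNetConfig()
    if tissue_filter not in ("blood", "skin", "both"):
        raise ValueError("tissue_filter must be 'blood', 'skin' or 'both'")
    ds = dataset
    if tissue_filter != "both":
        keep = dataset.samples.loc[dataset.samples["tissue"] == tissue_filter, "sample_id"]
        ds = dataset.subset_samples(keep)

    folds = make_folds(ds.samples, scheme)
    meta = ds.samples.set_index("sample_id")
    rows = []
    skipped = 0
    for fold in folds:
        try:
            panel = preselect_cpgs(
                ds, fold.train_ids, fold.test_ids, k=k_preselect,
                min_stratum_size=min_stratum_size,
            )
            model = fit_clock(ds, fold.train_ids, panel, clock_config)
        except ValueError as exc:
            logger.warning("fold %d skipped: %s", fold.fold_id, exc)
            skipped += 1
            continue
        test = [s for s in ds.beta.columns if s in fold.test_ids]
        preds = predict_age(model, ds.beta[test])
        for sid in test:
            rows.append(
                {
                    "sample_id": sid,
                    "species": meta.at[sid, "species"],
                    "tissue": meta.at[sid, "tissue"],
                    "age_years": float(meta.at[sid, "age_years"]),
                    "predicted_age": float(preds[sid]),
                    "fold_id": fold.fold_id,
                }
            )
    if not rows:
        raise ValueError("all folds were skipped; no predictions to score")
    pred_df = pd.DataFrame(rows)
    r, mae = compute_metrics(pred_df["age_years"], pred_df["predicted_age"])
    mean_ae = float(np.mean(np.abs(pred_df["predicted_age"] - pred_df["age_years"])))
    return CVReport(
        scheme=scheme.upper(),
        predictions=pred_df,
        pearson_r=r,
        mae=mae,
        per_species=_group_metrics(pred_df, "species"),
        per_tissue=_group_metrics(pred_df, "tissue"),
        n_skipped_folds=skipped,
        mean_absolute_error=mean_ae,
    )
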