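"""Leakage-safe pre-selection of age-related CpGs.

Arrays measure tens of thousands of CpGs but only a few hundred samples are
available, so the clock is fit on a pre-selected panel of CpGs that
correlate with age. To keep cross-validation honest the selection must be a
pure function of the *training* samples: per species-tissue stratum (blood,
skin, and blood+skin combined) a Fisher-transformed correlation-test Z
statistic ``z = atanh(r) * sqrt(n - 3)`` is computed for every CpG, strata
containing any test sample are removed, the remaining per-stratum Z values
are meta-analysed by their median, and CpGs are ranked by absolute median Z.

:class:`AgeCorrelationSelector` exposes the same procedure as a
scikit-learn feature selector (samples x CpGs in, reduced matrix out).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.feature_selection import SelectorMixin
from sklearn.utils.validation import check_is_fitted, validate_data

from .io import Dataset

logger = logging.getLogger(__name__)

#: |r| is clamped to this before atanh so perfect correlations stay finite
R_CLAMP = 1.0 - 1e-12

DEFAULT_K = 4000
DEFAULT_MIN_STRATUM_SIZE = 5


class InsufficientDataError(ValueError):
    """Too few complete observations to compute a correlation."""


class UndefinedCorrelationError(ValueError):
    """One of the vectors is constant; Pearson r is undefined."""


@dataclass(frozen=True)
class Stratum:
    """A species x tissue grouping within which age correlations are taken."""

    species: str
    tissue_scope: str  # "blood", "skin" or "combined"
    member_sample_ids: frozenset[str]

    @property
    def name(self) -> str:
        return f"{self.species}:{self.tissue_scope}"

    def __len__(self) -> int:
        return len(self.member_sample_ids)


def stratify(
    samples: pd.DataFrame,
    min_stratum_size: int = DEFAULT_MIN_STRATUM_SIZE,
) -> list[Stratum]:
    """Enumerate per-species blood / skin / combined strata.

    The combined stratum of a species exists only when that species has both
    tissues; strata smaller than ``min_stratum_size`` are dropped with a log
    note.
    """
    if len(samples) == 0:
        raise ValueError("empty sample list")
    strata: list[Stratum] = []
    for sp, grp in samples.groupby("species", sort=True):
        tissues = set(grp["tissue"])
        candidates: list[tuple[str, pd.DataFrame]] = []
        for t in ("blood", "skin"):
            if t in tissues:
                candidates.append((t, grp[grp["tissue"] == t]))
        if {"blood", "skin"} <= tissues:
            candidates.append(("combined", grp))
        for scope, members in candidates:
            if len(members) < min_stratum_size:
                logger.info(
                    "dropping stratum %s:%s with %d < %d samples",
                    sp, scope, len(members), min_stratum_size,
                )
                continue
            strata.append(
                Stratum(
                    species=str(sp),
                    tissue_scope=scope,
                    member_sample_ids=frozenset(members["sample_id"]),
                )
            )
    return strata


def correlation_z(values: Sequence[float], ages: Sequence[float]) -> float:
    """Fisher Z statistic of the Pearson correlation between a CpG and age.

    ``z = atanh(r) * sqrt(n - 3)`` over pairwise-complete observations, with
    r clamped to +/-(1 - 1e-12). Approximately standard normal when the true
    correlation is zero.
    """
    v = np.asarray(values, float)
    a = np.asarray(ages, float)
    if v.shape != a.shape:
        raise ValueError("values and ages must have equal length")
    ok = np.isfinite(v) & np.isfinite(a)
    v, a = v[ok], a[ok]
    n = len(v)
    if n < 4:
        raise InsufficientDataError(f"need >= 4 complete pairs, got {n}")
    if np.ptp(v) == 0 or np.ptp(a) == 0:
        raise UndefinedCorrelationError("constant input: correlation undefined")
    r = float(np.corrcoef(v, a)[0, 1])
    r = float(np.clip(r, -R_CLAMP, R_CLAMP))
    return float(np.arctanh(r) * np.sqrt(n - 3))


def _corr_z_matrix(betas: np.ndarray, ages: np.ndarray) -> np.ndarray:
    """Vectorised per-row Fisher Z against age, pairwise-complete over NaNs.

    ``betas`` is CpGs x samples. Rows with < 4 complete pairs or zero
    variance (in either variable) get NaN.
    """
    mask = np.isfinite(betas)
    n = mask.sum(axis=1).astype(float)
    a = np.where(mask, ages[None, :], 0.0)
    b = np.where(mask, betas, 0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean_b = b.sum(1) / n
        mean_a = a.sum(1) / n
        cov = (b * a).sum(1) / n - mean_b * mean_a
        var_b = (b * b).sum(1) / n - mean_b**2
        var_a = (a * a).sum(1) / n - mean_a**2
        # tiny negative variances arise from cancellation on constant rows
        var_b = np.where(var_b < 1e-18, np.nan, var_b)
        var_a = np.where(var_a < 1e-18, np.nan, var_a)
        r = cov / np.sqrt(var_b * var_a)
        r = np.clip(r, -R_CLAMP, R_CLAMP)
        z = np.arctanh(r) * np.sqrt(n - 3)
    z[n < 4] = np.nan
    return z


def meta_median_z(
    dataset: Dataset,
    strata: Iterable[Stratum],
    sample_ids: Iterable[str] | None = None,
) -> pd.DataFrame:
    """Per-CpG, per-stratum correlation Z table with its median.

    Returns a DataFrame indexed by cpg_id with one ``z:<stratum>`` column per
    stratum plus ``median_z`` and ``n_strata_used``. CpGs computable in zero
    strata are dropped (their count is logged); an empty result is fatal.

    ``sample_ids`` optionally restricts each stratum's members (used to
    confine the computation to training samples).
    """
    strata = list(strata)
    if not strata:
        raise ValueError("need at least one stratum")
    allowed = set(sample_ids) if sample_ids is not None else None
    ages_all = dataset.ages()
    cols = {}
    for st in strata:
        members = st.member_sample_ids if allowed is None else st.member_sample_ids & allowed
        members = [s for s in dataset.beta.columns if s in members]
        if len(members) < 4:
            cols[f"z:{st.name}"] = np.full(dataset.n_cpgs, np.nan)
            continue
        sub = dataset.beta[members].to_numpy(float)
        ages = ages_all.loc[members].to_numpy(float)
        if np.ptp(ages) == 0:
            cols[f"z:{st.name}"] = np.full(dataset.n_cpgs, np.nan)
            continue
        cols[f"z:{st.name}"] = _corr_z_matrix(sub, ages)
    table = pd.DataFrame(cols, index=dataset.beta.index)
    n_used = table.notna().sum(axis=1)
    table["median_z"] = table.median(axis=1, skipna=True)
    table["n_strata_used"] = n_used
    dropped = int((n_used == 0).sum())
    if dropped:
        logger.info("dropping %d CpGs computable in zero strata", dropped)
    table = table[n_used >= 1]
    if table.empty:
        raise ValueError("all CpGs dropped: no stratum yields a computable correlation")
    return table


def preselect_cpgs(
    dataset: Dataset,
    train_ids: Iterable[str],
    test_ids: Iterable[str] = (),
    k: int = DEFAULT_K,
    min_stratum_size: int = DEFAULT_MIN_STRATUM_SIZE,
) -> list[str]:
    """Rank CpGs by |median Z| over training-only strata; return the top k.

    Strata are built from train + test membership; any stratum containing a
    test sample is removed, so the returned list is a pure function of the
    training samples. Ties in |median Z| break lexicographically on cpg_id.
    """
    train = set(train_ids)
    test = set(test_ids)
    if train & test:
        raise ValueError("train and test sample sets overlap")
    members = train | test
    samples = dataset.samples[dataset.samples["sample_id"].isin(members)]
    strata = stratify(samples, min_stratum_size=min_stratum_size)
    kept = [st for st in strata if not (st.member_sample_ids & test)]
    removed = len(strata) - len(kept)
    if removed:
        logger.info("removed %d/%d strata overlapping the test set", removed, len(strata))
    if not kept:
        raise ValueError(
            "every stratum overlaps the test set; enlarge the training set or "
            "use a different cross-validation scheme"
        )
    table = meta_median_z(dataset, kept, sample_ids=train)
    # stable sort on cpg_id first gives the lexicographic tie-break
    order = (
        table.assign(abs_z=table["median_z"].abs())
        .sort_index()
        .sort_values("abs_z", ascending=False, kind="mergesort")
    )
    return list(order.index[: min(k, len(order))])


class AgeCorrelationSelector(SelectorMixin, BaseEstimator):
    """Scikit-learn feature selector wrapping the median-Z pre-selection.

    Expects ``X`` of shape (n_samples, n_cpgs) and ``y`` = age in years.
    Strata are taken from the ``strata`` fit parameter: an array of stratum
    labels per sample is expanded to one stratum per label; pass ``None`` to
    treat all samples as one stratum.

    Parameters
    ----------
    k : int, default 4000
        Number of CpGs to retain (ranked by absolute median Z).
    min_stratum_size : int, default 5
        Strata with fewer samples are ignored.

    Attributes
    ----------
    median_z_ : ndarray of shape (n_features_in_,)
        Median Fisher Z per CpG (NaN when computable in no stratum).
    ranking_ : ndarray of int
        Feature indices ranked best-first.
    """

    def __init__(self, k: int = DEFAULT_K, min_stratum_size: int = DEFAULT_MIN_STRATUM_SIZE):
        self.k = k
        self.min_stratum_size = min_stratum_size

    def fit(self, X, y, strata=None):
        X = validate_data(self, X, ensure_all_finite="allow-nan")
        y = np.asarray(y, float)
        if strata is None:
            strata = np.zeros(len(y), dtype=int)
        strata = np.asarray(strata)
        zs = []
        for lab in np.unique(strata):
            sel = strata == lab
            if sel.sum() < max(4, self.min_stratum_size):
                continue
            ages = y[sel]
            if np.ptp(ages) == 0:
                continue
            zs.append(_corr_z_matrix(X[sel].T, ages))
        if not zs:
            raise ValueError("no stratum large enough for a correlation test")
        zmat = np.vstack(zs)
        with np.errstate(all="ignore"):
            self.median_z_ = np.nanmedian(zmat, axis=0)
        abs_z = np.abs(self.median_z_)
        abs_z = np.where(np.isnan(abs_z), -np.inf, abs_z)
        self.ranking_ = np.argsort(-abs_z, kind="stable")
        n_keep = min(self.k, int(np.isfinite(self.median_z_).sum()))
        self._support = np.zeros(X.shape[1], dtype=bool)
        self._support[self.ranking_[:n_keep]] = True
        return self

    def _get_support_mask(self):
        check_is_fitted(self)
        return self._support
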