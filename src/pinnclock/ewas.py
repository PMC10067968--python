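"""Per-stratum epigenome-wide association of methylation with age.

For every CpG within one species-tissue stratum the Pearson correlation
with chronological age is tested (two-sided t test, ``t = r *
sqrt((n-2)/(1-r^2))`` on n-2 degrees of freedom) and the Fisher-transformed
score ``z = atanh(r) * sqrt(n-3)`` is recorded. Downstream analyses use the
top CpGs per direction of association at a nominal significance threshold
(default p < 0.005, 500 CpGs per direction), and Venn-style overlaps of
those top sets across strata.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .io import Dataset
from .preselect import R_CLAMP, Stratum, _corr_z_matrix

DEFAULT_P_THRESHOLD = 0.005
DEFAULT_N_PER_DIRECTION = 500

EWAS_COLUMNS = ("n", "r", "p", "z_fisher", "direction")


@dataclass
class TopSets:
    """Top age-associated CpGs per direction, ordered by significance."""

    positive: list[str]
    negative: list[str]

    def __post_init__(self) -> None:
        if set(self.positive) & set(self.negative):
            raise ValueError("positive and negative top sets overlap")


def _pearson_p(r: np.ndarray, n: np.ndarray) -> np.ndarray:
    """Two-sided p of the correlation t test with n-2 df."""
    r = np.clip(r, -R_CLAMP, R_CLAMP)
    df = n - 2
    with np.errstate(invalid="ignore", divide="ignore"):
        t = r * np.sqrt(df / (1.0 - r * r))
        p = 2.0 * stats.t.sf(np.abs(t), df)
    # keep p in (0, 1]: the test statistic can overflow for |r| at the clamp
    return np.clip(p, np.finfo(float).tiny, 1.0)


def run_ewas(
    dataset: Dataset,
    stratum: Stratum,
    p_threshold: float = DEFAULT_P_THRESHOLD,
    fdr: bool = False,
) -> pd.DataFrame:
    """EWAS of age within one stratum.

    Returns a DataFrame indexed by cpg_id with columns ``n, r, p, z_fisher,
    direction`` (direction is the sign of r at nominal significance, else
    "none"). CpGs with fewer than 4 complete pairs or zero variance are
    marked unavailable (NaN statistics, direction "none"). Set ``fdr`` to
    add a Benjamini-Hochberg ``q`` column (never used for selection).
    """
    members = [s for s in dataset.beta.columns if s in stratum.member_sample_ids]
    if len(members) < 4:
        raise ValueError(f"stratum {stratum.name} has {len(members)} < 4 samples")
    ages = dataset.ages(members).to_numpy(float)
    if np.ptp(ages) == 0:
        raise ValueError(f"stratum {stratum.name} has constant age")

    betas = dataset.beta[members].to_numpy(float)
    mask = np.isfinite(betas)
    n = mask.sum(axis=1)

    # pairwise-complete r per CpG (shares the masked-moment kernel with
    # pre-selection; z there already encodes r via atanh)
    z = _corr_z_matrix(betas, ages)
    with np.errstate(invalid="ignore"):
        r = np.tanh(z / np.sqrt(np.maximum(n - 3, 1)))
    p = np.where(np.isfinite(r), _pearson_p(r, n), np.nan)

    direction = np.where(
        np.isfinite(p) & (p < p_threshold),
        np.where(r > 0, "positive", "negative"),
        "none",
    )
    table = pd.DataFrame(
        {"n": n, "r": r, "p": p, "z_fisher": z, "direction": direction},
        index=dataset.beta.index,
    )
    if fdr:
        ok = table["p"].notna()
        q = np.full(len(table), np.nan)
        q[ok.to_numpy()] = stats.false_discovery_control(table.loc[ok, "p"])
        table["q"] = q
    return table


def select_top(
    table: pd.DataFrame,
    n_per_direction: int = DEFAULT_N_PER_DIRECTION,
    p_threshold: float = DEFAULT_P_THRESHOLD,
) -> TopSets:
    """Top CpGs per direction: p < threshold, sorted by (p, cpg_id), truncated."""
    if table.empty:
        raise ValueError("empty EWAS table")
    out = {}
    for sign, name in ((1, "positive"), (-1, "negative")):
        passed = table[(table["p"] < p_threshold) & (np.sign(table["r"]) == sign)]
        ranked = passed.sort_index().sort_values("p", kind="mergesort")
        out[name] = list(ranked.index[:n_per_direction])
    return TopSets(**out)


def overlap_sets(named_sets: Mapping[str, set[str] | list[str]]) -> dict:
    """Exact Venn partition of >= 2 named CpG sets.

    Returns ``{"regions": {membership-key: count}, "intersection": [...],
    "union_size": int}`` where a membership key like ``"a&b"`` counts
    elements in exactly those sets. Region counts sum to the union size.
    """
    names = list(named_sets)
    if len(names) != len(set(names)):
        raise ValueError("duplicate set names")
    if len(names) < 2:
        raise ValueError("need at least two named sets")
    sets = {k: set(v) for k, v in named_sets.items()}
    union = set().union(*sets.values())
    regions: dict[str, int] = {}
    for r in range(1, len(names) + 1):
        for combo in combinations(names, r):
            inside = set.intersection(*(sets[c] for c in combo))
            outside = set().union(*(sets[c] for c in names if c not in combo)) if r < len(names) else set()
            regions["&".join(combo)] = len(inside - outside)
    full = sorted(set.intersection(*sets.values()))
    assert sum(regions.values()) == len(union)
    return {"regions": regions, "intersection": full, "union_size": len(union)}
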