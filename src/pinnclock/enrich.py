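"""Category-level enrichment of top age-related CpGs.

Four analyses, each against an explicit CpG background:

* **Gene-region odds ratios** — per region class (promoter, exon, ...), a
  2x2 Fisher exact test of top-set membership against region membership,
  with a Haldane-Anscombe 0.5 correction applied to the reported odds
  ratio when a cell is zero (the p value stays exact).
* **CpG-island shift** — Welch t test comparing the Fisher-z age
  associations of island vs non-island CpGs.
* **Chromatin-state enrichment** — upper-tail hypergeometric test per
  state, on a background restricted to CpGs alignable in all analysed
  species.
* **Gene-set enrichment** — CpGs mapped to genes within a 50 kb flank of
  the TSS; per gene set, an upper-tail hypergeometric test on the gene
  universe reachable from the background CpGs, filtered at p < 1e-5 and a
  minimum overlap of 3 genes.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .io import parse_alignable_species

DEFAULT_FLANK_KB = 50
DEFAULT_GENESET_P_MAX = 1e-5
DEFAULT_MIN_OVERLAP = 3


@dataclass(frozen=True)
class EnrichmentResult:
    category: str
    set_size: int
    background_size: int
    overlap: int
    odds_ratio: float  # may be inf when an off-cell is empty
    p: float
    fold: float = float("nan")
    odds_ratio_corrected: float = float("nan")
    direction: str = ""

    def __post_init__(self) -> None:
        if not 0 < self.p <= 1:
            raise ValueError(f"p must lie in (0, 1], got {self.p}")


def results_to_frame(results: Iterable[EnrichmentResult]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in results])


# ---------------------------------------------------------------------------
# gene-region odds ratios (Fisher exact, two-sided)
# ---------------------------------------------------------------------------

def _fisher_2x2(a: int, b: int, c: int, d: int) -> tuple[float, float, float]:
    """(uncorrected OR, Haldane-Anscombe OR, two-sided exact p)."""
    res = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    if min(a, b, c, d) == 0:
        or_corr = ((a + 0.5) * (d + 0.5)) / ((b + 0.5) * (c + 0.5))
    else:
        or_corr = (a * d) / (b * c)
    or_raw = float(res.statistic)  # conditional-free sample OR; inf when b*c == 0
    return or_raw, float(or_corr), float(res.pvalue)


def region_enrichment(
    top_sets: Mapping[str, Iterable[str]],
    annotation: pd.DataFrame,
    background: Iterable[str],
) -> list[EnrichmentResult]:
    """Fisher exact 2x2 per region class x direction over the background.

    ``top_sets`` maps direction names (e.g. "positive"/"negative") to CpG
    lists; each must be a subset of ``background``.
    """
    bg = set(background)
    ann = annotation.set_index("cpg_id")["region_class"]
    ann = ann[ann.index.isin(bg)]
    results = []
    for direction, cpgs in top_sets.items():
        top = set(cpgs)
        if not top <= bg:
            raise ValueError(f"top set {direction!r} is not a subset of the background")
        for region in sorted(ann.unique()):
            in_class = set(ann.index[ann == region])
            a = len(top & in_class)
            b = len(top - in_class)
            c = len(in_class - top)
            d = len(bg) - a - b - c
            or_raw, or_corr, p = _fisher_2x2(a, b, c, d)
            results.append(
                EnrichmentResult(
                    category=str(region),
                    set_size=len(top),
                    background_size=len(bg),
                    overlap=a,
                    odds_ratio=or_raw,
                    odds_ratio_corrected=or_corr,
                    p=p,
                    direction=str(direction),
                )
            )
    return results


# ---------------------------------------------------------------------------
# CpG-island shift of the Fisher-z distribution
# ---------------------------------------------------------------------------

def island_shift_test(
    ewas_table: pd.DataFrame,
    annotation: pd.DataFrame,
    welch: bool = True,
) -> dict:
    """Compare z_fisher of island vs non-island CpGs (two-sample t test).

    Returns the t statistic, two-sided p, and per-group box-plot summaries
    (n, mean, median, quartiles).
    """
    status = annotation.set_index("cpg_id")["island_status"]
    z = ewas_table["z_fisher"].dropna()
    common = z.index.intersection(status.index)
    z = z.loc[common]
    groups = {}
    for label in ("island", "non-island"):
        vals = z[status.loc[common] == label]
        if len(vals) < 2:
            raise ValueError(f"group {label!r} has {len(vals)} < 2 CpGs with defined z")
        groups[label] = vals.to_numpy(float)
    t, p = stats.ttest_ind(groups["island"], groups["non-island"], equal_var=not welch)
    summaries = {
        label: {
            "n": int(len(v)),
            "mean": float(np.mean(v)),
            "median": float(np.median(v)),
            "q25": float(np.percentile(v, 25)),
            "q75": float(np.percentile(v, 75)),
        }
        for label, v in groups.items()
    }
    return {"t": float(t), "p": float(p), "groups": summaries}


# ---------------------------------------------------------------------------
# chromatin-state enrichment (upper-tail hypergeometric)
# ---------------------------------------------------------------------------

def hypergeom_upper(N: int, K: int, n: int, k: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N, K, n)."""
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def alignable_background(annotation: pd.DataFrame, species: Iterable[str]) -> set[str]:
    """CpGs whose probes align to *all* the given species."""
    wanted = set(species)
    ok = annotation["alignable_species"].map(
        lambda v: wanted <= parse_alignable_species(v)
    )
    return set(annotation.loc[ok, "cpg_id"])


def state_enrichment(
    top: Iterable[str],
    annotation: pd.DataFrame,
    background: Iterable[str],
) -> list[EnrichmentResult]:
    """Hypergeometric enrichment of each chromatin state within the top set."""
    bg = set(background)
    top = set(top)
    if not top <= bg:
        raise ValueError("top set is not a subset of the background")
    states = annotation.set_index("cpg_id")["chromatin_state"]
    states = states[states.index.isin(bg)]
    N, n = len(bg), len(top)
    results = []
    for state in sorted(states.unique()):
        members = set(states.index[states == state])
        K = len(members)
        if K == 0:
            continue
        k = len(top & members)
        expected = n * K / N
        fold = (k / n) / (K / N) if n and K else float("nan")
        results.append(
            EnrichmentResult(
                category=str(state),
                set_size=n,
                background_size=N,
                overlap=k,
                odds_ratio=float("nan"),
                p=hypergeom_upper(N, K, n, k),
                fold=fold,
            )
        )
    return results


# ---------------------------------------------------------------------------
# gene-set enrichment with 50 kb gene assignment
# ---------------------------------------------------------------------------

def read_gmt(path: str | Path) -> dict[str, set[str]]:
    """Read named gene sets from a GMT file (name, description, genes...)."""
    gene_sets: dict[str, set[str]] = {}
    for line in Path(path).read_text().splitlines():
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3 or not parts[0]:
            continue
        gene_sets[parts[0]] = {g for g in parts[2:] if g}
    if not gene_sets:
        raise ValueError(f"no gene sets parsed from {path}")
    return gene_sets


def cpgs_to_genes(
    cpgs: Iterable[str],
    annotation: pd.DataFrame,
    flank_kb: float = DEFAULT_FLANK_KB,
) -> set[str]:
    """Genes with a TSS within ``flank_kb`` of any of the given CpGs."""
    ann = annotation.set_index("cpg_id")
    idx = ann.index.intersection(pd.Index(set(cpgs)))
    sub = ann.loc[idx]
    near = sub["distance_to_tss"].abs() <= flank_kb * 1000
    genes = sub.loc[near, "gene_symbol"]
    return {g for g in genes if isinstance(g, str) and g}


def geneset_enrichment(
    top: Iterable[str],
    gene_sets: Mapping[str, Iterable[str]],
    annotation: pd.DataFrame,
    background: Iterable[str] | None = None,
    flank_kb: float = DEFAULT_FLANK_KB,
    p_max: float = DEFAULT_GENESET_P_MAX,
    min_overlap: int = DEFAULT_MIN_OVERLAP,
) -> list[EnrichmentResult]:
    """Hypergeometric gene-set enrichment of the genes near top CpGs.

    The gene universe is the set of genes reachable (same flank rule) from
    the background CpGs, so a restricted CpG background propagates to the
    gene level. Results failing ``p < p_max`` or ``overlap >= min_overlap``
    are removed.
    """
    if not gene_sets:
        raise ValueError("gene_sets is empty")
    bg_cpgs = set(background) if background is not None else set(annotation["cpg_id"])
    universe = cpgs_to_genes(bg_cpgs, annotation, flank_kb)
    if not universe:
        raise ValueError("empty background gene universe")
    hits = cpgs_to_genes(top, annotation, flank_kb) & universe
    N, n = len(universe), len(hits)
    results = []
    for name in sorted(gene_sets):
        members = set(gene_sets[name]) & universe
        K = len(members)
        if K == 0:
            continue
        k = len(hits & members)
        p = hypergeom_upper(N, K, n, k)
        if k < min_overlap or p >= p_max:
            continue
        fold = (k / n) / (K / N) if n else float("nan")
        results.append(
            EnrichmentResult(
                category=name,
                set_size=n,
                background_size=N,
                overlap=k,
                odds_ratio=float("nan"),
                p=p,
                fold=fold,
            )
        )
    return results
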