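"""Core data types and text-file I/O.

The package works on three delimited-text inputs:

* a **sample sheet** (``sample_id, animal_id, species, tissue, age_years``
  plus an optional ``origin`` column),
* a **beta matrix** of methylation fractions in ``[0, 1]`` (CpGs by samples,
  orientation auto-detected by matching labels against the sample sheet),
* an optional **CpG annotation** table (gene, region class, distance to the
  transcription start site, CpG-island status, chromatin state, and the set
  of species a probe aligns to).

In memory the beta matrix is a :class:`pandas.DataFrame` indexed by CpG id
with one column per sample; missing probe values are ``NaN``. A fitted age
clock is a sparse linear model (:class:`ClockModel`) serialized to a
two-section plain-text format: a key/value header followed by one
``cpg_id,coefficient,training_mean`` row per retained CpG.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

TISSUES = ("blood", "skin")
ORIGINS = ("captive", "wild", "unknown")
REGION_CLASSES = (
    "promoter",
    "5'UTR",
    "exon",
    "intron",
    "intergenic-upstream",
    "intergenic-downstream",
    "3'UTR",
    "unknown",
)
ISLAND_STATUSES = ("island", "non-island")

SHEET_REQUIRED_COLUMNS = ("sample_id", "animal_id", "species", "tissue", "age_years")
ANNOTATION_COLUMNS = (
    "cpg_id",
    "gene_symbol",
    "region_class",
    "distance_to_tss",
    "island_status",
    "chromatin_state",
    "alignable_species",
)

CLOCK_FORMAT_VERSION = 1


class ValidationError(ValueError):
    """Input table violates a structural or range invariant."""


class FormatError(ValueError):
    """File cannot be parsed in the expected layout."""


class ConsistencyError(ValueError):
    """Tables that must describe the same cohort do not overlap."""


@dataclass(frozen=True)
class SampleRecord:
    """One profiled sample: a tissue from an animal at a known age."""

    sample_id: str
    animal_id: str
    species: str
    tissue: str
    age_years: float
    origin: str = "unknown"

    def __post_init__(self) -> None:
        if self.tissue not in TISSUES:
            raise ValidationError(
                f"sample {self.sample_id!r}: tissue must be one of {TISSUES}, got {self.tissue!r}"
            )
        if self.origin not in ORIGINS:
            raise ValidationError(
                f"sample {self.sample_id!r}: origin must be one of {ORIGINS}, got {self.origin!r}"
            )
        if not math.isfinite(self.age_years) or self.age_years < 0:
            raise ValidationError(
                f"sample {self.sample_id!r}: age_years must be finite and >= 0, got {self.age_years}"
            )


@dataclass
class Dataset:
    """A beta matrix bound to its validated sample sheet and annotation.

    Attributes
    ----------
    beta
        CpGs x samples DataFrame of methylation fractions; NaN = missing.
    samples
        One row per sample, indexed 0..n-1, columns as in the sample sheet.
    annotation
        Optional per-CpG annotation (may be None for clock-only use).
    """

    beta: pd.DataFrame
    samples: pd.DataFrame
    annotation: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.validate()

    # -- accessors -------------------------------------------------------
    @property
    def sample_ids(self) -> list[str]:
        return list(self.samples["sample_id"])

    @property
    def cpg_ids(self) -> list[str]:
        return list(self.beta.index)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_cpgs(self) -> int:
        return len(self.beta)

    def ages(self, sample_ids: Iterable[str] | None = None) -> pd.Series:
        """Chronological ages in years, indexed by sample id."""
        s = self.samples.set_index("sample_id")["age_years"].astype(float)
        if sample_ids is None:
            return s
        return s.loc[list(sample_ids)]

    def subset_samples(self, sample_ids: Iterable[str]) -> "Dataset":
        """Restrict to the given samples (order follows the current sheet)."""
        keep = set(sample_ids)
        samples = self.samples[self.samples["sample_id"].isin(keep)].reset_index(drop=True)
        beta = self.beta[samples["sample_id"].tolist()]
        return Dataset(beta=beta, samples=samples, annotation=self.annotation)

    # -- validation ------------------------------------------------------
    def validate(self) -> None:
        validate_sample_sheet(self.samples)
        validate_beta(self.beta)
        sheet_ids = set(self.samples["sample_id"])
        beta_ids = set(self.beta.columns)
        if sheet_ids != beta_ids:
            raise ConsistencyError(
                "beta matrix columns and sample sheet ids differ: "
                f"{sorted(sheet_ids ^ beta_ids)[:10]} ..."
            )
        if self.annotation is not None:
            missing = set(self.beta.index) - set(self.annotation["cpg_id"])
            if missing:
                logger.warning(
                    "annotation lacks %d of %d beta CpGs; downstream annotation-based "
                    "analyses use the intersection",
                    len(missing),
                    len(self.beta.index),
                )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Dataset):
            return NotImplemented
        a = self.samples.sort_values("sample_id").reset_index(drop=True)
        b = other.samples.sort_values("sample_id").reset_index(drop=True)
        if sorted(a.columns) != sorted(b.columns):
            return False
        if not a[sorted(a.columns)].equals(b[sorted(b.columns)]):
            return False
        sa = self.beta.sort_index(axis=0).sort_index(axis=1)
        sb = other.beta.sort_index(axis=0).sort_index(axis=1)
        if not sa.index.equals(sb.index) or not sa.columns.equals(sb.columns):
            return False
        va, vb = sa.to_numpy(float), sb.to_numpy(float)
        return bool(np.array_equal(va, vb, equal_nan=True))


@dataclass
class ClockModel:
    """Sparse linear age predictor: ``age = intercept + sum_j w_j * beta_j``.

    ``weights`` holds only the CpGs with nonzero elastic-net coefficients
    (years per unit beta). ``training_means`` stores the training-set mean
    beta of each weighted CpG so masked probes can be imputed at predict
    time. ``alpha`` is the elastic-net mixing parameter and ``lambda_`` the
    selected penalty strength.
    """

    intercept: float
    weights: dict[str, float]
    preselected_cpgs: list[str] = field(default_factory=list)
    alpha: float = 0.5
    lambda_: float = float("nan")
    training_means: dict[str, float] = field(default_factory=dict)
    training_meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.preselected_cpgs:
            self.preselected_cpgs = sorted(self.weights)
        self.validate()

    def validate(self) -> None:
        pre = set(self.preselected_cpgs)
        for cpg, w in self.weights.items():
            if w == 0.0:
                raise ValidationError(f"clock weight for {cpg!r} is exactly zero")
            if cpg not in pre:
                raise ValidationError(f"weighted CpG {cpg!r} not in preselected set")

    @property
    def n_cpgs(self) -> int:
        return len(self.weights)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ClockModel):
            return NotImplemented
        return (
            self.intercept == other.intercept
            and self.weights == other.weights
            and self.alpha == other.alpha
            and (
                self.lambda_ == other.lambda_
                or (math.isnan(self.lambda_) and math.isnan(other.lambda_))
            )
            and self.training_means == other.training_means
            and self.preselected_cpgs == other.preselected_cpgs
        )


# ---------------------------------------------------------------------------
# table validation helpers
# ---------------------------------------------------------------------------

def validate_sample_sheet(sheet: pd.DataFrame) -> None:
    missing = [c for c in SHEET_REQUIRED_COLUMNS if c not in sheet.columns]
    if missing:
        raise FormatError(f"sample sheet missing required columns: {missing}")
    dup = sheet["sample_id"][sheet["sample_id"].duplicated()]
    if len(dup):
        raise ValidationError(f"duplicate sample_id values: {sorted(set(dup))}")
    ages = pd.to_numeric(sheet["age_years"], errors="coerce")
    bad = sheet["sample_id"][~np.isfinite(ages) | (ages < 0)]
    if len(bad):
        raise ValidationError(f"non-finite or negative age_years for samples: {list(bad)}")
    bad_t = sheet["sample_id"][~sheet["tissue"].isin(TISSUES)]
    if len(bad_t):
        raise ValidationError(f"tissue not in {TISSUES} for samples: {list(bad_t)}")
    # one animal, one species
    nsp = sheet.groupby("animal_id")["species"].nunique()
    conflicted = nsp[nsp > 1].index.tolist()
    if conflicted:
        raise ValidationError(f"animals assigned to multiple species: {conflicted}")
    if "origin" in sheet.columns:
        bad_o = sheet["sample_id"][~sheet["origin"].isin(ORIGINS)]
        if len(bad_o):
            raise ValidationError(f"origin not in {ORIGINS} for samples: {list(bad_o)}")


def validate_beta(beta: pd.DataFrame) -> None:
    if beta.index.duplicated().any():
        raise ValidationError("duplicate CpG ids in beta matrix")
    if beta.columns.duplicated().any():
        raise ValidationError("duplicate sample ids in beta matrix")
    vals = beta.to_numpy(float)
    with np.errstate(invalid="ignore"):
        bad = (vals < 0.0) | (vals > 1.0)
    if bad.any():
        rows, cols = np.nonzero(bad)
        cells = [
            f"({beta.index[r]}, {beta.columns[c]}) = {vals[r, c]!r}"
            for r, c in list(zip(rows, cols))[:10]
        ]
        raise ValidationError(
            f"{bad.sum()} beta values outside [0, 1]; first offenders: {cells}"
        )


def validate_annotation(ann: pd.DataFrame) -> None:
    missing = [c for c in ANNOTATION_COLUMNS if c not in ann.columns]
    if missing:
        raise FormatError(f"annotation missing required columns: {missing}")
    if ann["cpg_id"].duplicated().any():
        dups = ann["cpg_id"][ann["cpg_id"].duplicated()]
        raise ValidationError(f"duplicate annotation rows for CpGs: {sorted(set(dups))[:10]}")
    bad = ann.loc[~ann["region_class"].isin(REGION_CLASSES), "cpg_id"]
    if len(bad):
        raise ValidationError(f"region_class outside closed enum for CpGs: {list(bad)[:10]}")
    bad = ann.loc[~ann["island_status"].isin(ISLAND_STATUSES), "cpg_id"]
    if len(bad):
        raise ValidationError(f"island_status outside closed enum for CpGs: {list(bad)[:10]}")


# ---------------------------------------------------------------------------
# loading
# ---------------------------------------------------------------------------

def _sniff_sep(path: Path) -> str:
    with open(path) as fh:
        header = fh.readline()
    if not header.strip():
        raise FormatError(f"{path}:1: empty header line")
    return "\t" if header.count("\t") >= header.count(",") and "\t" in header else ","


def _read_delimited(path: str | Path) -> pd.DataFrame:
    """Read a CSV/TSV with a header row; float parsing is round-trip exact."""
    path = Path(path)
    try:
        return pd.read_csv(
            path, sep=_sniff_sep(path), index_col=0, float_precision="round_trip"
        )
    except FormatError:
        raise
    except Exception as exc:  # pandas raises many parse error types
        raise FormatError(f"cannot parse {path}: {exc}") from exc


def read_sample_sheet(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    try:
        sheet = pd.read_csv(
            path, sep=_sniff_sep(path), dtype={"sample_id": str, "animal_id": str},
            float_precision="round_trip",
        )
    except FormatError:
        raise
    except Exception as exc:
        raise FormatError(f"cannot parse sample sheet {path}: {exc}") from exc
    if "origin" not in sheet.columns:
        sheet = sheet.copy()
        sheet["origin"] = "unknown"
    validate_sample_sheet(sheet)
    sheet["age_years"] = sheet["age_years"].astype(float)
    return sheet.reset_index(drop=True)


def read_beta_matrix(path: str | Path, sample_ids: Iterable[str] | None = None) -> pd.DataFrame:
    """Read a beta matrix, orienting it CpGs x samples.

    Orientation is decided by matching row/column labels against the sample
    sheet ids when given; otherwise rows are assumed to be CpGs (the
    canonical layout of array series matrices).
    """
    df = _read_delimited(path)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    if sample_ids is not None:
        ids = set(map(str, sample_ids))
        col_hits = len(ids & set(df.columns))
        row_hits = len(ids & set(df.index))
        if row_hits > col_hits:
            df = df.T
    df = df.apply(pd.to_numeric, errors="coerce")
    validate_beta(df)
    return df


def read_annotation(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    try:
        ann = pd.read_csv(
            path, sep=_sniff_sep(path), dtype={"cpg_id": str},
            float_precision="round_trip",
        )
    except FormatError:
        raise
    except Exception as exc:
        raise FormatError(f"cannot parse annotation {path}: {exc}") from exc
    ann["gene_symbol"] = ann.get("gene_symbol", pd.Series(dtype=str)).fillna("")
    validate_annotation(ann)
    return ann.reset_index(drop=True)


def parse_alignable_species(value: str) -> set[str]:
    """Split a semicolon-separated species list into a set of tokens."""
    if not isinstance(value, str) or not value.strip():
        return set()
    return {tok.strip() for tok in value.split(";") if tok.strip()}


def load_dataset(
    sample_sheet_path: str | Path,
    beta_path: str | Path,
    annotation_path: str | Path | None = None,
) -> Dataset:
    """Load and cross-validate the three input tables into a :class:`Dataset`.

    Samples present in only one of the sheet and the beta matrix are dropped
    with a logged warning; zero overlap is a fatal consistency error.
    """
    sheet = read_sample_sheet(sample_sheet_path)
    beta = read_beta_matrix(beta_path, sample_ids=sheet["sample_id"])
    sheet_ids = set(sheet["sample_id"])
    beta_ids = set(beta.columns)
    common = sheet_ids & beta_ids
    if not common:
        raise ConsistencyError(
            f"no overlapping sample ids between {sample_sheet_path} and {beta_path}"
        )
    dropped = sorted((sheet_ids | beta_ids) - common)
    if dropped:
        logger.warning("dropping %d samples present in only one table: %s", len(dropped), dropped)
    sheet = sheet[sheet["sample_id"].isin(common)].reset_index(drop=True)
    beta = beta[sheet["sample_id"].tolist()]
    annotation = read_annotation(annotation_path) if annotation_path is not None else None
    return Dataset(beta=beta, samples=sheet, annotation=annotation)


# ---------------------------------------------------------------------------
# clock serialization
# ---------------------------------------------------------------------------

def serialize_clock(model: ClockModel, path: str | Path) -> None:
    """Write a clock to the two-section text format (header; coefficient rows).

    Floats are written with :func:`repr`, which preserves 17 significant
    digits, so a write/read round trip is bit-identical.
    """
    model.validate()
    path = Path(path)
    lines = [
        "# pinnclock epigenetic age clock",
        f"format_version: {CLOCK_FORMAT_VERSION}",
        f"intercept: {model.intercept!r}",
        f"alpha: {model.alpha!r}",
        f"lambda: {model.lambda_!r}",
        f"n_cpgs: {len(model.weights)}",
    ]
    for key in sorted(model.training_meta):
        lines.append(f"meta.{key}: {model.training_meta[key]}")
    lines.append("[coefficients]")
    lines.append("cpg_id,coefficient,training_mean")
    for cpg in sorted(model.weights):
        mean = model.training_means.get(cpg, float("nan"))
        lines.append(f"{cpg},{model.weights[cpg]!r},{mean!r}")
    if model.preselected_cpgs and set(model.preselected_cpgs) != set(model.weights):
        lines.append("[preselection]")
        lines.extend(model.preselected_cpgs)
    path.write_text("\n".join(lines) + "\n")


def deserialize_clock(path: str | Path) -> ClockModel:
    path = Path(path)
    header: dict[str, str] = {}
    weights: dict[str, float] = {}
    means: dict[str, float] = {}
    preselected: list[str] = []
    section = "header"
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        if line == "[coefficients]":
            section = "coefficients"
            continue
        if line == "[preselection]":
            section = "preselection"
            continue
        if section == "header":
            if ":" not in line:
                raise FormatError(f"{path}:{lineno}: expected 'key: value', got {line!r}")
            key, _, value = line.partition(":")
            header[key.strip()] = value.strip()
        elif section == "coefficients":
            if line.startswith("cpg_id,"):
                continue
            parts = line.split(",")
            if len(parts) != 3:
                raise FormatError(f"{path}:{lineno}: expected 3 comma-separated fields")
            cpg, coef_s, mean_s = parts
            coef = float(coef_s)
            if coef == 0.0:
                raise ValidationError(f"{path}:{lineno}: zero coefficient for {cpg!r}")
            weights[cpg] = coef
            means[cpg] = float(mean_s)
        else:
            preselected.append(line)
    for required in ("intercept", "alpha", "lambda", "n_cpgs"):
        if required not in header:
            raise FormatError(f"{path}: header field {required!r} missing")
    if int(header["n_cpgs"]) != len(weights):
        raise FormatError(
            f"{path}: header declares {header['n_cpgs']} CpGs but file has {len(weights)}"
        )
    meta = {k[5:]: v for k, v in header.items() if k.startswith("meta.")}
    means = {k: v for k, v in means.items() if not math.isnan(v)}
    return ClockModel(
        intercept=float(header["intercept"]),
        weights=weights,
        preselected_cpgs=preselected or sorted(weights),
        alpha=float(header["alpha"]),
        lambda_=float(header["lambda"]),
        training_means=means,
        training_meta=meta,
    )


# ---------------------------------------------------------------------------
# dataset writing (used by the simulator and the CLI)
# ---------------------------------------------------------------------------

def write_dataset(
    dataset: Dataset,
    sheet_path: str | Path,
    beta_path: str | Path,
    annotation_path: str | Path | None = None,
    float_format: str | None = None,
) -> None:
    dataset.samples.to_csv(sheet_path, index=False)
    dataset.beta.to_csv(beta_path, index_label="cpg_id", float_format=float_format)
    if annotation_path is not None and dataset.annotation is not None:
        dataset.annotation.to_csv(annotation_path, index=False)
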