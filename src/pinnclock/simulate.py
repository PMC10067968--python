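"""Synthetic multi-species methylation cohorts with known age signal.

The generator emulates a wildlife methylation-array study: several species,
blood and skin samples (some animals contribute both tissues), ages spanning
birth to ~48 years, and a minority of CpGs whose methylation drifts
monotonically with age. Effects act in logit space so beta values stay in
(0, 1) with the heteroscedastic, boundary-compressed noise typical of array
data:

    mu_ij = expit(b0_j + s_j * age_i + u_{j,species(i)} + v_{j,tissue(i)})
    beta_ij ~ Beta(mu_ij * precision, (1 - mu_ij) * precision)

where ``s_j`` is nonzero only for designated age CpGs (half positive, half
negative), ``u`` and ``v`` are per-CpG species and tissue offsets, and
baselines ``b0_j`` follow the bimodal distribution of array beta values.
Everything is deterministic given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .io import Dataset, REGION_CLASSES, write_dataset

SPECIES_POOL = (
    "california_sea_lion",
    "harbor_seal",
    "pacific_walrus",
    "grey_seal",
    "steller_sea_lion",
    "harp_seal",
)

CHROMATIN_STATES = ("TSS", "PromF", "Enh", "Tx", "ReprPC", "Het", "Quies")
_STATE_PROBS = (0.05, 0.10, 0.15, 0.20, 0.10, 0.10, 0.30)
_REGION_PROBS = (0.12, 0.06, 0.14, 0.30, 0.12, 0.12, 0.06, 0.08)


@dataclass(frozen=True)
class SimConfig:
    """Study-design parameters of a simulated cohort.

    Defaults describe a ~150-sample, 3-species, 2-tissue cohort with ages
    spanning 0-48 years and 10% of CpGs carrying age trends.
    """

    n_species: int = 3
    animals_per_species: int = 30
    tissue_scheme: float = 2 / 3  # fraction of animals contributing both tissues
    age_range: tuple[float, float] = (0.0, 48.0)
    n_cpgs: int = 4000
    n_age_cpgs: int = 400
    slope_scale: float = 0.05  # logit units per year
    species_sd: float = 0.5  # logit units
    tissue_sd: float = 0.5  # logit units
    precision: float = 60.0  # beta-distribution concentration
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_species < 1 or self.animals_per_species < 1 or self.n_cpgs < 1:
            raise ValueError("counts must be positive")
        if not 0 <= self.n_age_cpgs <= self.n_cpgs:
            raise ValueError("n_age_cpgs must lie in [0, n_cpgs]")
        if not 0 <= self.tissue_scheme <= 1:
            raise ValueError("tissue_scheme must lie in [0, 1]")
        lo, hi = self.age_range
        if not (0 <= lo < hi):
            raise ValueError("age_range must satisfy 0 <= min < max")
        for name in ("slope_scale", "species_sd", "tissue_sd", "precision"):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be finite and non-negative")
        if self.precision <= 0:
            raise ValueError("precision must be positive")


@dataclass
class SimTruth:
    """Ground truth of a simulated dataset: which CpGs age, and how."""

    age_cpg_ids: list[str]
    slopes: dict[str, float]  # cpg_id -> logit-slope (only age CpGs)
    species_offsets: pd.DataFrame = field(repr=False)  # CpGs x species
    tissue_offsets: pd.DataFrame = field(repr=False)  # CpGs x tissues

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "cpg_id": self.age_cpg_ids,
                "slope": [self.slopes[c] for c in self.age_cpg_ids],
            }
        )


def _baselines(rng: np.random.Generator, n: int) -> np.ndarray:
    """Bimodal logit baselines: modes near beta 0.1 and 0.9, uniform middle."""
    comp = rng.choice(3, size=n, p=(0.4, 0.4, 0.2))
    b0 = np.empty(n)
    b0[comp == 0] = logit(0.1) + rng.normal(0.0, 0.5, (comp == 0).sum())
    b0[comp == 1] = logit(0.9) + rng.normal(0.0, 0.5, (comp == 1).sum())
    b0[comp == 2] = logit(rng.uniform(0.2, 0.8, (comp == 2).sum()))
    return b0


def simulate_dataset(config: SimConfig) -> tuple[Dataset, SimTruth]:
    """Draw one cohort. Returns the dataset and its generating truth."""
    rng = np.random.default_rng(config.seed)
    species = list(SPECIES_POOL[: config.n_species])
    if config.n_species > len(SPECIES_POOL):
        species += [f"species_{i}" for i in range(len(SPECIES_POOL) + 1, config.n_species + 1)]

    # ---- sample sheet --------------------------------------------------
    rows = []
    lo, hi = config.age_range
    sample_counter = 0
    n_animals = config.animals_per_species
    n_both = int(round(config.tissue_scheme * n_animals))
    for sp_idx, sp in enumerate(species):
        # exact tissue composition per species (which animals is random):
        # n_both animals give blood+skin, the rest alternate single tissues
        both_flags = np.zeros(n_animals, bool)
        both_flags[rng.choice(n_animals, size=n_both, replace=False)] = True
        single_tissues = rng.permutation(
            ["blood", "skin"] * (n_animals // 2 + 1)
        )[: n_animals - n_both]
        single_iter = iter(single_tissues)
        for a in range(n_animals):
            animal_id = f"{sp}_a{a + 1:03d}"
            age = float(rng.uniform(lo, hi))
            tissues = ("blood", "skin") if both_flags[a] else (next(single_iter),)
            origin = "wild" if rng.random() < 0.7 else "captive"
            for t in tissues:
                sample_counter += 1
                rows.append(
                    {
                        "sample_id": f"s{sample_counter:04d}",
                        "animal_id": animal_id,
                        "species": sp,
                        "tissue": t,
                        "age_years": round(age, 3),
                        "origin": origin,
                    }
                )
    sheet = pd.DataFrame(rows)
    n_samples = len(sheet)
    ages = sheet["age_years"].to_numpy(float)

    # ---- CpG effects ----------------------------------------------------
    n = config.n_cpgs
    cpg_ids = np.array([f"cg{j + 1:07d}" for j in range(n)])
    b0 = _baselines(rng, n)

    slopes = np.zeros(n)
    age_idx = rng.choice(n, size=config.n_age_cpgs, replace=False)
    n_pos = config.n_age_cpgs // 2
    signs = np.concatenate([np.ones(n_pos), -np.ones(config.n_age_cpgs - n_pos)])
    magnitudes = config.slope_scale * rng.uniform(0.5, 1.5, config.n_age_cpgs)
    slopes[age_idx] = signs * magnitudes

    sp_off = rng.normal(0.0, config.species_sd, (n, len(species)))
    ti_off = np.column_stack([np.zeros(n), rng.normal(0.0, config.tissue_sd, n)])

    sp_col = sheet["species"].map({s: i for i, s in enumerate(species)}).to_numpy()
    ti_col = sheet["tissue"].map({"blood": 0, "skin": 1}).to_numpy()

    # ---- betas ----------------------------------------------------------
    eta = (
        b0[:, None]
        + slopes[:, None] * ages[None, :]
        + sp_off[:, sp_col]
        + ti_off[:, ti_col]
    )
    mu = expit(eta)
    a_par = mu * config.precision
    b_par = (1.0 - mu) * config.precision
    betas = rng.beta(a_par, b_par)
    # beta variates can underflow to exactly 0/1 near extreme means
    np.clip(betas, 1e-9, 1.0 - 1e-9, out=betas)

    beta_df = pd.DataFrame(betas, index=cpg_ids, columns=sheet["sample_id"].tolist())

    # ---- annotation ------------------------------------------------------
    annotation = pd.DataFrame(
        {
            "cpg_id": cpg_ids,
            "gene_symbol": [f"GENE{rng.integers(1, max(n // 8, 2)):05d}" for _ in range(n)],
            "region_class": rng.choice(REGION_CLASSES, size=n, p=_REGION_PROBS),
            "distance_to_tss": np.rint(
                np.clip(rng.laplace(0.0, 30_000.0, n), -200_000, 200_000)
            ).astype(int),
            "island_status": rng.choice(["island", "non-island"], size=n, p=(0.3, 0.7)),
            "chromatin_state": rng.choice(CHROMATIN_STATES, size=n, p=_STATE_PROBS),
            "alignable_species": ";".join(species),
        }
    )

    dataset = Dataset(beta=beta_df, samples=sheet, annotation=annotation)
    order = np.argsort(age_idx)
    truth = SimTruth(
        age_cpg_ids=[str(cpg_ids[j]) for j in age_idx[order]],
        slopes={str(cpg_ids[j]): float(slopes[j]) for j in age_idx},
        species_offsets=pd.DataFrame(sp_off, index=cpg_ids, columns=species),
        tissue_offsets=pd.DataFrame(ti_off, index=cpg_ids, columns=["blood", "skin"]),
    )
    return dataset, truth


def write_simulation(
    config: SimConfig,
    out_dir: str | Path,
    prefix: str = "sim",
) -> dict[str, Path]:
    """Simulate and write the three standard input files plus a truth CSV."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    dataset, truth = simulate_dataset(config)
    paths = {
        "sheet": out / f"{prefix}_samples.csv",
        "beta": out / f"{prefix}_beta.csv",
        "annotation": out / f"{prefix}_annotation.csv",
        "truth": out / f"{prefix}_truth.csv",
        "config": out / f"{prefix}_config.csv",
    }
    write_dataset(dataset, paths["sheet"], paths["beta"], paths["annotation"])
    truth.to_frame().to_csv(paths["truth"], index=False)
    cfg = asdict(config)
    cfg["age_range"] = f"{config.age_range[0]}..{config.age_range[1]}"
    pd.Series(cfg).rename("value").to_csv(paths["config"], index_label="parameter")
    return paths
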