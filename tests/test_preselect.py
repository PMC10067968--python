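import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pinnclock import (
    Dataset,
    SimConfig,
    correlation_z,
    meta_median_z,
    preselect_cpgs,
    simulate_dataset,
    stratify,
)
from pinnclock.preselect import (
    AgeCorrelationSelector,
    InsufficientDataError,
    UndefinedCorrelationError,
)


def _sheet(rows):
    df = pd.DataFrame(rows, columns=["sample_id", "animal_id", "species", "tissue", "age_years"])
    df["origin"] = "unknown"
    return df


class TestStratify:
    def test_both_tissues_gives_three_strata(self):
        rows = [(f"s{i}", f"a{i}", "seal", "blood", i) for i in range(6)]
        rows += [(f"t{i}", f"b{i}", "seal", "skin", i) for i in range(6)]
        strata = stratify(_sheet(rows), min_stratum_size=5)
        assert sorted(s.tissue_scope for s in strata) == ["blood", "combined", "skin"]
        combined = next(s for s in strata if s.tissue_scope == "combined")
        assert len(combined) == 12

    def test_single_tissue_species_has_no_combined(self):
        rows = [(f"s{i}", f"a{i}", "seal", "blood", i) for i in range(6)]
        strata = stratify(_sheet(rows), min_stratum_size=5)
        assert [s.tissue_scope for s in strata] == ["blood"]

    def test_small_strata_dropped(self):
        rows = [(f"s{i}", f"a{i}", "seal", "blood", i) for i in range(3)]
        assert stratify(_sheet(rows), min_stratum_size=5) == []

    def test_empty_sheet_is_error(self):
        with pytest.raises(ValueError):
            stratify(_sheet([]))


class TestCorrelationZ:
    def test_orthogonal_values_give_zero(self):
        ages = [0.0, 1.0, 2.0, 3.0, 4.0]
        values = [0.6, 0.4, 0.5, 0.4, 0.6]  # even around the centre: r = 0
        assert correlation_z(values, ages) == pytest.approx(0.0, abs=1e-12)

    def test_worked_example(self):
        # Pearson r of (0.10,0.30,0.20,0.40) vs (0,1,2,3) is 0.8 by direct
        # evaluation; z = atanh(0.8) * sqrt(4-3)
        z = correlation_z([0.10, 0.30, 0.20, 0.40], [0.0, 1.0, 2.0, 3.0])
        assert z == pytest.approx(np.arctanh(0.8), rel=1e-12)

    @given(
        st.lists(st.floats(0.01, 0.99), min_size=5, max_size=12, unique=True),
        st.integers(0, 2**31 - 1),
    )
    @settings(max_examples=25, deadline=None)
    def test_antisymmetry(self, values, age_seed):
        ages = np.random.default_rng(age_seed).uniform(0, 40, len(values)).tolist()
        if np.ptp(ages) == 0:
            return
        flipped = [1.0 - v for v in values]
        z1 = correlation_z(values, ages)
        z2 = correlation_z(flipped, ages)
        assert z1 == pytest.approx(-z2, rel=1e-9, abs=1e-9)

    def test_too_few_pairs(self):
        with pytest.raises(InsufficientDataError):
            correlation_z([0.1, 0.2, 0.3], [1.0, 2.0, 3.0])

    def test_constant_values(self):
        with pytest.raises(UndefinedCorrelationError):
            correlation_z([0.5] * 5, [1.0, 2.0, 3.0, 4.0, 5.0])

    def test_missing_pairs_dropped(self):
        z_full = correlation_z([0.1, 0.3, 0.2, 0.4], [0, 1, 2, 3])
        z_nan = correlation_z([0.1, 0.3, 0.2, 0.4, np.nan], [0, 1, 2, 3, 4])
        assert z_full == z_nan


class TestMetaMedianZ:
    def test_median_definitions(self, small_dataset):
        strata = stratify(small_dataset.samples)
        table = meta_median_z(small_dataset, strata)
        zcols = [c for c in table.columns if c.startswith("z:")]
        expected = table[zcols].median(axis=1, skipna=True)
        pd.testing.assert_series_equal(table["median_z"], expected, check_names=False)
        assert (table["n_strata_used"] >= 1).all()

    def test_single_stratum_median_is_that_z(self, small_dataset):
        strata = [stratify(small_dataset.samples)[0]]
        table = meta_median_z(small_dataset, strata)
        zcol = [c for c in table.columns if c.startswith("z:")][0]
        pd.testing.assert_series_equal(table["median_z"], table[zcol], check_names=False)

    @pytest.mark.parametrize(
        "zs,expected", [((1.0, 2.0, 5.0), 2.0), ((1.0, 3.0), 2.0)]
    )
    def test_median_even_odd(self, zs, expected):
        assert float(np.median(zs)) == expected  # documents the convention used


class TestPreselect:
    def test_k_larger_than_available(self, small_dataset):
        panel = preselect_cpgs(small_dataset, small_dataset.sample_ids, (), k=10_000)
        assert len(panel) == small_dataset.n_cpgs

    def test_ranking_is_monotone_in_abs_median_z(self, small_dataset):
        strata = stratify(small_dataset.samples)
        table = meta_median_z(small_dataset, strata)
        panel = preselect_cpgs(small_dataset, small_dataset.sample_ids, (), k=50)
        abs_z = table.loc[panel, "median_z"].abs().to_numpy()
        assert (np.diff(abs_z) <= 1e-12).all()

    def test_leakage_invariance(self, small_dataset):
        ids = small_dataset.sample_ids
        train, test = ids[:60], ids[60:]
        panel = preselect_cpgs(small_dataset, train, test, k=40)
        noisy = small_dataset.beta.copy()
        rng = np.random.default_rng(99)
        noisy.loc[:, test] = rng.uniform(0, 1, (small_dataset.n_cpgs, len(test)))
        perturbed = Dataset(
            beta=noisy, samples=small_dataset.samples, annotation=small_dataset.annotation
        )
        assert preselect_cpgs(perturbed, train, test, k=40) == panel

    def test_recovers_planted_age_cpgs(self):
        cfg = SimConfig(
            n_cpgs=100, n_age_cpgs=10, slope_scale=0.08, animals_per_species=24, seed=7
        )
        ds, truth = simulate_dataset(cfg)
        assert ds.n_samples == 120
        panel = preselect_cpgs(ds, ds.sample_ids, (), k=10)
        assert len(set(panel) & set(truth.age_cpg_ids)) >= 9

    def test_matches_bruteforce_oracle_on_small_data(self):
        """Selection order equals an independent per-stratum reimplementation."""
        cfg = SimConfig(n_cpgs=50, n_age_cpgs=5, animals_per_species=5, seed=21)
        ds, _ = simulate_dataset(cfg)
        strata = stratify(ds.samples, min_stratum_size=5)
        ages = ds.ages()
        medians = {}
        for cpg in ds.cpg_ids:
            zs = []
            for stt in strata:
                members = sorted(stt.member_sample_ids)
                v = ds.beta.loc[cpg, members].to_numpy()
                a = ages.loc[members].to_numpy()
                r = np.corrcoef(v, a)[0, 1]
                r = np.clip(r, -(1 - 1e-12), 1 - 1e-12)
                zs.append(np.arctanh(r) * np.sqrt(len(members) - 3))
            if zs:
                medians[cpg] = np.median(zs)
        expected = sorted(medians, key=lambda c: (-abs(medians[c]), c))
        got = preselect_cpgs(ds, ds.sample_ids, (), k=len(expected))
        assert got == expected

    def test_overlapping_train_test_rejected(self, small_dataset):
        ids = small_dataset.sample_ids
        with pytest.raises(ValueError):
            preselect_cpgs(small_dataset, ids[:10], ids[5:15], k=5)


class TestAgeCorrelationSelector:
    def test_sklearn_selector_agrees_with_functional_path(self, small_dataset):
        X = small_dataset.beta.to_numpy().T
        y = small_dataset.ages().to_numpy()
        sheet = small_dataset.samples
        labels = (sheet["species"] + ":" + sheet["tissue"]).to_numpy()
        sel = AgeCorrelationSelector(k=25).fit(X, y, strata=labels)
        assert sel.transform(X).shape == (len(y), 25)
        assert sel.get_support().sum() == 25

    def test_clonable_params(self):
        from sklearn.base import clone

        sel = AgeCorrelationSelector(k=7, min_stratum_size=6)
        assert clone(sel).get_params() == sel.get_params()
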