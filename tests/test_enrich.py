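from fractions import Fraction
from math import comb

import numpy as np
import pandas as pd
import pytest

from pinnclock.enrich import (
    EnrichmentResult,
    alignable_background,
    cpgs_to_genes,
    geneset_enrichment,
    hypergeom_upper,
    island_shift_test,
    read_gmt,
    region_enrichment,
    state_enrichment,
    _fisher_2x2,
)


# ---------------------------------------------------------------------------
# brute-force oracles
# ---------------------------------------------------------------------------

def fisher_two_sided_bruteforce(a, b, c, d):
    """Enumerate all tables with the observed margins; sum masses <= observed."""
    r1, c1, n = a + b, a + c, a + b + c + d
    denom = comb(n, c1)
    masses = {}
    for k in range(max(0, c1 - (n - r1)), min(r1, c1) + 1):
        masses[k] = Fraction(comb(r1, k) * comb(n - r1, c1 - k), denom)
    obs = masses[a]
    # the standard tie rule: include tables whose mass is within a relative
    # epsilon of the observed mass
    return float(sum(m for m in masses.values() if float(m) <= float(obs) * (1 + 1e-7)))


def hypergeom_upper_bruteforce(N, K, n, k):
    total = Fraction(0)
    for x in range(k, min(K, n) + 1):
        if n - x <= N - K:
            total += Fraction(comb(K, x) * comb(N - K, n - x), comb(N, n))
    return float(total)


@pytest.fixture()
def annotation():
    rng = np.random.default_rng(12)
    n = 200
    return pd.DataFrame(
        {
            "cpg_id": [f"cg{i:04d}" for i in range(n)],
            "gene_symbol": [f"G{i % 40:03d}" for i in range(n)],
            "region_class": rng.choice(["promoter", "intron", "exon"], n, p=[0.5, 0.3, 0.2]),
            "distance_to_tss": rng.integers(-80_000, 80_000, n),
            "island_status": rng.choice(["island", "non-island"], n),
            "chromatin_state": rng.choice(["TSS", "Enh", "Quies"], n),
            "alignable_species": "seal;walrus",
        }
    )


class TestExactTests:
    def test_worked_fisher_cell(self):
        # margins (2,2)x(2,2): table masses are (1,4,1)/6; two-sided p = 2/6
        _, _, p = _fisher_2x2(2, 0, 0, 2)
        assert p == pytest.approx(1 / 3, abs=1e-12)

    def test_worked_hypergeom_cell(self):
        # C(5,4)*C(5,0)/C(10,4) = 5/210
        assert hypergeom_upper(10, 5, 4, 4) == pytest.approx(5 / 210, abs=1e-12)

    def test_fisher_matches_bruteforce_exhaustively(self):
        """Two-sided Fisher p agrees with exact enumeration for all urns N <= 25."""
        for N in range(2, 26):
            for r1 in range(N + 1):
                for c1 in range(N + 1):
                    for a in range(max(0, r1 + c1 - N), min(r1, c1) + 1):
                        b, c, d = r1 - a, c1 - a, N - r1 - c1 + a
                        got = _fisher_2x2(a, b, c, d)[2]
                        want = fisher_two_sided_bruteforce(a, b, c, d)
                        assert abs(got - want) < 1e-10, (a, b, c, d)

    def test_hypergeom_matches_bruteforce_exhaustively(self):
        for N in range(1, 26):
            for K in range(N + 1):
                for n in range(N + 1):
                    for k in range(max(0, K + n - N), min(K, n) + 1):
                        got = hypergeom_upper(N, K, n, k)
                        want = hypergeom_upper_bruteforce(N, K, n, k)
                        assert abs(got - want) < 1e-10, (N, K, n, k)

    def test_hypergeom_monotone_in_overlap(self):
        ps = [hypergeom_upper(100, 30, 20, k) for k in range(0, 21)]
        assert ps[0] == 1.0
        assert all(a >= b for a, b in zip(ps, ps[1:]))


class TestRegionEnrichment:
    def test_all_top_in_promoter(self, annotation):
        bg = set(annotation["cpg_id"])
        promoters = annotation.loc[annotation["region_class"] == "promoter", "cpg_id"]
        top = set(promoters.iloc[:20])
        results = region_enrichment({"positive": top}, annotation, bg)
        res = next(r for r in results if r.category == "promoter")
        assert res.overlap == 20
        assert res.odds_ratio_corrected > 1
        K = int((annotation["region_class"] == "promoter").sum())
        # the two-sided exact p contains the upper hypergeometric tail
        tail = hypergeom_upper(len(bg), K, 20, 20)
        assert res.p >= tail * (1 - 1e-9)
        assert res.p < 1e-4

    def test_null_draw_or_near_one(self, annotation):
        rng = np.random.default_rng(7)
        bg = list(annotation["cpg_id"])
        ors = []
        for _ in range(30):
            top = set(rng.choice(bg, size=40, replace=False))
            results = region_enrichment({"positive": top}, annotation, set(bg))
            ors.extend(r.odds_ratio_corrected for r in results)
        assert 0.5 < np.median(ors) < 2.0

    def test_top_outside_background_rejected(self, annotation):
        with pytest.raises(ValueError):
            region_enrichment({"positive": {"not_a_cpg"}}, annotation, set(annotation["cpg_id"]))


class TestIslandShift:
    def _ewas_like(self, z, ids):
        return pd.DataFrame({"z_fisher": z}, index=ids)

    def test_identical_groups_give_t_zero(self):
        ann = pd.DataFrame(
            {
                "cpg_id": ["a", "b", "c", "d", "e", "f"],
                "island_status": ["island"] * 3 + ["non-island"] * 3,
            }
        )
        table = self._ewas_like([1.0, 2.0, 3.0, 1.0, 2.0, 3.0], ann["cpg_id"])
        res = island_shift_test(table, ann)
        assert res["t"] == pytest.approx(0.0, abs=1e-12)
        assert res["p"] == pytest.approx(1.0, abs=1e-12)

    def test_shifted_groups_detected(self, annotation):
        rng = np.random.default_rng(1)
        status = annotation.set_index("cpg_id")["island_status"]
        z = rng.normal(size=len(annotation)) + (status == "island").to_numpy() * 1.0
        table = self._ewas_like(z, annotation["cpg_id"])
        res = island_shift_test(table, annotation)
        assert res["p"] < 1e-4
        assert res["groups"]["island"]["mean"] > res["groups"]["non-island"]["mean"]
        for g in res["groups"].values():
            assert g["q25"] <= g["median"] <= g["q75"]

    def test_shift_power_over_seeds(self, annotation):
        """n=500 per group, unit sd, +1 shift: p < 1e-6 in every replicate."""
        big = pd.DataFrame(
            {
                "cpg_id": [f"cg{i}" for i in range(1000)],
                "island_status": ["island"] * 500 + ["non-island"] * 500,
            }
        )
        for seed in range(20):
            rng = np.random.default_rng(seed)
            z = np.concatenate([rng.normal(1.0, 1.0, 500), rng.normal(0.0, 1.0, 500)])
            table = self._ewas_like(z, big["cpg_id"])
            assert island_shift_test(table, big)["p"] < 1e-6

    def test_single_member_group_rejected(self):
        ann = pd.DataFrame(
            {"cpg_id": ["a", "b", "c"], "island_status": ["island", "non-island", "non-island"]}
        )
        table = pd.DataFrame({"z_fisher": [1.0, 2.0, 3.0]}, index=["a", "b", "c"])
        with pytest.raises(ValueError):
            island_shift_test(table, ann)


class TestStateEnrichment:
    def test_expected_overlap_gives_fold_one(self, annotation):
        bg = set(annotation["cpg_id"])
        states = annotation.set_index("cpg_id")["chromatin_state"]
        tss = list(states.index[states == "TSS"])
        other = list(states.index[states != "TSS"])
        K, N = len(tss), len(bg)
        # build a top set whose TSS share equals the background share
        n_top = 20
        k = round(n_top * K / N)
        top = set(tss[:k]) | set(other[: n_top - k])
        res = next(r for r in state_enrichment(top, annotation, bg) if r.category == "TSS")
        assert res.fold == pytest.approx(1.0, abs=0.2)

    def test_zero_overlap_p_is_one(self, annotation):
        states = annotation.set_index("cpg_id")["chromatin_state"]
        top = set(states.index[states == "Quies"])
        res = next(
            r for r in state_enrichment(top, annotation, set(annotation["cpg_id"]))
            if r.category == "TSS"
        )
        assert res.overlap == 0 and res.p == 1.0

    def test_alignable_background_filter(self, annotation):
        ann = annotation.copy()
        ann.loc[:49, "alignable_species"] = "seal"
        bg = alignable_background(ann, ["seal", "walrus"])
        assert len(bg) == len(ann) - 50


class TestGenesetEnrichment:
    def test_flank_rule(self, annotation):
        near = annotation[annotation["distance_to_tss"].abs() <= 50_000]
        genes = cpgs_to_genes(annotation["cpg_id"], annotation, flank_kb=50)
        assert genes == set(near["gene_symbol"])

    def test_filters_enforced(self, annotation):
        bg = set(annotation["cpg_id"])
        universe = cpgs_to_genes(bg, annotation)
        target_genes = sorted(universe)[:5]
        top_cpgs = annotation.loc[
            annotation["gene_symbol"].isin(target_genes)
            & (annotation["distance_to_tss"].abs() <= 50_000),
            "cpg_id",
        ]
        gene_sets = {
            "hit_set": set(target_genes),
            "whole_universe": set(universe),
            "two_gene_overlap": set(target_genes[:2]),
        }
        results = geneset_enrichment(top_cpgs, gene_sets, annotation, background=bg)
        names = {r.category for r in results}
        assert "whole_universe" not in names  # p = 1 there
        assert "two_gene_overlap" not in names  # overlap < 3
        if "hit_set" in names:
            res = next(r for r in results if r.category == "hit_set")
            assert res.overlap >= 3 and res.p < 1e-5

    def test_marginal_results_filtered(self, annotation):
        # overlap of 3 but weak p must be dropped
        bg = set(annotation["cpg_id"])
        universe = sorted(cpgs_to_genes(bg, annotation))
        big_set = set(universe[: len(universe) // 2])
        top = annotation["cpg_id"].iloc[:30]
        results = geneset_enrichment(top, {"half": big_set}, annotation, background=bg)
        assert all(r.p < 1e-5 and r.overlap >= 3 for r in results)

    def test_gmt_round_trip(self, tmp_path):
        path = tmp_path / "sets.gmt"
        path.write_text("setA\tdesc\tG1\tG2\tG3\nsetB\t-\tG9\n")
        gs = read_gmt(path)
        assert gs == {"setA": {"G1", "G2", "G3"}, "setB": {"G9"}}


class TestEnrichmentResult:
    def test_p_bounds_enforced(self):
        with pytest.raises(ValueError):
            EnrichmentResult("x", 1, 10, 1, 1.0, p=0.0)
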