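"""Gene sigma, pathway-bias classification, ORA, selectivity, and DE partitions."""

import math

import numpy as np
import pandas as pd
import pytest

from pparbias.pathway_bias import (
    PathwayDB,
    enrich_pathways,
    expected_false_positive_pathways,
    gene_sigma,
    partition_de_sets,
    pathway_bias,
    selectivity_index,
)
from pparbias.simulate import DESimSpec, build_pathway_db, simulate_de_tables


def make_de(genes, lfc_test, lfc_ref, padj_test=0.001, padj_ref=0.001, timepoint="24h"):
    rows = []
    for g, lt, lr in zip(genes, np.atleast_1d(lfc_test), np.atleast_1d(lfc_ref)):
        rows.append((g, "GW1929", timepoint, lt, padj_test))
        rows.append((g, "rosiglitazone", timepoint, lr, padj_ref))
    return pd.DataFrame(rows, columns=["gene_id", "ligand", "timepoint", "log2fc", "padj"])


class TestGeneSigma:
    def test_equal_effects_give_zero(self):
        assert gene_sigma(1.7, 1.7) == 0.0

    def test_stronger_reference_effect_is_positive(self):
        assert gene_sigma(-1.0, -2.0) == pytest.approx(math.log10(2.0))

    def test_epsilon_floor_keeps_sigma_finite(self):
        val = gene_sigma(0.0, 2.0)
        assert np.isfinite(val)
        assert val == pytest.approx(math.log10(2.0 / 0.01))

    def test_sign_independent_of_direction(self):
        assert gene_sigma(1.0, 2.0) == gene_sigma(-1.0, -2.0) == gene_sigma(1.0, -2.0)


class TestPathwayBias:
    def small_db(self):
        genes = [f"g{i}" for i in range(40)]
        return PathwayDB({"REF": set(genes[:20]), "PW": set(genes[20:])}), genes

    def test_identical_fold_changes_give_zero_bias_everywhere(self):
        db, genes = self.small_db()
        lfc = np.linspace(-2, 2, 40)
        lfc[lfc == 0] = 0.5
        de = make_de(genes, lfc, lfc)
        results = pathway_bias(de, db, "REF", "GW1929", "rosiglitazone", "24h")
        for r in results:
            assert r.mean_bias == pytest.approx(0.0, abs=1e-12)
            assert r.call == "unbiased"

    def test_reference_pathway_never_biased_against_itself(self):
        db, genes = self.small_db()
        rng = np.random.default_rng(0)
        de = make_de(genes, rng.normal(1, 0.5, 40), rng.normal(1, 0.5, 40))
        results = pathway_bias(de, db, "REF", "GW1929", "rosiglitazone", "24h")
        ref = next(r for r in results if r.pathway_id == "REF")
        assert ref.mean_bias == pytest.approx(0.0, abs=1e-12)
        assert ref.call == "unbiased"

    def test_inflated_reference_effects_called_toward_reference(self):
        db, genes = self.small_db()
        rng = np.random.default_rng(1)
        base = rng.normal(1.5, 0.3, 40)
        ref_lfc = base.copy()
        ref_lfc[20:] *= 2.0  # PW genes hit twice as hard by the reference ligand
        de = make_de(genes, base, ref_lfc)
        results = pathway_bias(de, db, "REF", "GW1929", "rosiglitazone", "24h")
        pw = next(r for r in results if r.pathway_id == "PW")
        assert pw.call == "biased-toward-reference"
        assert pw.mean_bias == pytest.approx(math.log10(2.0), abs=0.05)

    def test_small_pathway_is_indeterminate(self):
        genes = [f"g{i}" for i in range(10)]
        db = PathwayDB({"REF": set(genes[:9]), "TINY": {genes[9], "absent_gene"}})
        de = make_de(genes, np.ones(10), np.full(10, 2.0))
        results = pathway_bias(de, db, "REF", "GW1929", "rosiglitazone", "24h")
        tiny = next(r for r in results if r.pathway_id == "TINY")
        assert tiny.call == "indeterminate"

    def test_invariant_to_gene_order_and_pathway_labels(self):
        db, genes = self.small_db()
        rng = np.random.default_rng(3)
        de = make_de(genes, rng.normal(1, 0.4, 40), rng.normal(1, 0.4, 40))
        shuffled = de.sample(frac=1.0, random_state=4).reset_index(drop=True)
        a = pathway_bias(de, db, "REF", "GW1929", "rosiglitazone", "24h")
        b = pathway_bias(shuffled, db, "REF", "GW1929", "rosiglitazone", "24h")
        assert {r.pathway_id: r.mean_bias for r in a} == pytest.approx(
            {r.pathway_id: r.mean_bias for r in b})

    def test_nonsignificant_genes_are_excluded(self):
        db, genes = self.small_db()
        de = make_de(genes, np.ones(40), np.full(40, 2.0), padj_test=0.5, padj_ref=0.5)
        with pytest.raises(ValueError, match="scorable"):
            pathway_bias(de, db, "REF", "GW1929", "rosiglitazone", "24h")

    def test_planted_bias_recovered_in_simulation(self):
        db = build_pathway_db(n_pathways=20, n_genes=4000, seed=2)
        target = next(pid for pid in db if pid != "AMPK" and len(db[pid]) >= 30)
        hits = 0
        for s in range(60):
            de, _ = simulate_de_tables(DESimSpec(
                n_genes=4000, pathway_db=db, seed=900 + s,
                ligand_specific_fraction=0.0,
                planted_pathway_bias=((target, 0.3),)))
            res = pathway_bias(de, db, "AMPK", "GW1929", "rosiglitazone", "24h")
            r = next(x for x in res if x.pathway_id == target)
            hits += r.call == "biased-toward-reference"
        assert hits / 60 >= 0.9


class TestExpectedFalsePositives:
    def test_study_scale(self):
        assert expected_false_positive_pathways(98, 0.05) == pytest.approx(2.45)

    def test_zero_alpha(self):
        assert expected_false_positive_pathways(98, 0.0) == 0.0


class TestEnrichment:
    def test_de_equals_universe_gives_p_one(self):
        universe = {f"g{i}" for i in range(30)}
        db = PathwayDB({"P1": {f"g{i}" for i in range(10)}})
        out = enrich_pathways(universe, universe, db)
        assert out["p"].iloc[0] == pytest.approx(1.0)

    def test_matches_exact_enumeration(self):
        """Hypergeometric tail equals exact combinatorial enumeration."""
        m, n_path, n_draw, k = 20, 5, 8, 4
        expected = sum(
            math.comb(n_path, j) * math.comb(m - n_path, n_draw - j)
            for j in range(k, min(n_path, n_draw) + 1)
        ) / math.comb(m, n_draw)
        universe = {f"g{i}" for i in range(m)}
        pathway = {f"g{i}" for i in range(n_path)}
        de_genes = {f"g{i}" for i in range(k)} | {f"g{i}" for i in range(n_path, n_path + n_draw - k)}
        out = enrich_pathways(de_genes, universe, PathwayDB({"P": pathway}))
        assert out["p"].iloc[0] == pytest.approx(expected, rel=1e-12)

    def test_disjoint_pathway_never_significant(self):
        universe = {f"g{i}" for i in range(100)}
        db = PathwayDB({"P": {f"g{i}" for i in range(50, 60)}})
        out = enrich_pathways({f"g{i}" for i in range(3)}, universe, db)
        assert out["p"].iloc[0] > 0.5
        assert not out["significant"].iloc[0]

    def test_bh_adjustment_is_monotone(self):
        rng = np.random.default_rng(8)
        universe = {f"g{i}" for i in range(200)}
        db = PathwayDB({f"P{j}": set(rng.choice(sorted(universe), 20, replace=False))
                        for j in range(15)})
        de_genes = set(rng.choice(sorted(universe), 40, replace=False))
        out = enrich_pathways(de_genes, universe, db)
        assert (out["padj"] >= out["p"] - 1e-15).all()

    def test_empty_de_set_gives_empty_table(self):
        out = enrich_pathways(set(), {"g1"}, PathwayDB({"P": {"g1"}}))
        assert out.empty


class TestSelectivityIndex:
    def test_equal_regulation_gives_zero(self):
        genes = [f"g{i}" for i in range(10)]
        de = make_de(genes, np.ones(10), np.ones(10))
        idx = selectivity_index(de, genes[:5], genes[5:], "GW1929", "24h")
        assert idx == pytest.approx(0.0)

    def test_antidiabetic_regulation_is_positive(self):
        genes = [f"g{i}" for i in range(10)]
        lfc = np.concatenate([np.full(5, 2.0), np.zeros(5)])
        de = make_de(genes, lfc, lfc)
        idx = selectivity_index(de, genes[:5], genes[5:], "GW1929", "24h")
        assert idx > 0

    def test_partial_agonist_ordering(self):
        """Weak regulation of the adverse set ranks the partial agonist highest."""
        genes = [f"g{i}" for i in range(20)]
        anti, adv = genes[:10], genes[10:]
        rows = []
        for lig, anti_eff, adv_eff in (("rosiglitazone", 1.0, 1.5),
                                       ("GW1929", 1.0, 1.4),
                                       ("MRL24", 0.8, 0.2)):
            for g in anti:
                rows.append((g, lig, "24h", anti_eff, 0.001))
            for g in adv:
                rows.append((g, lig, "24h", adv_eff, 0.001))
        de = pd.DataFrame(rows, columns=["gene_id", "ligand", "timepoint", "log2fc", "padj"])
        idx = {lig: selectivity_index(de, anti, adv, lig, "24h")
               for lig in ("rosiglitazone", "GW1929", "MRL24")}
        assert idx["MRL24"] > idx["GW1929"] > idx["rosiglitazone"]

    def test_missing_gene_set_is_an_error(self):
        genes = [f"g{i}" for i in range(4)]
        de = make_de(genes, np.ones(4), np.ones(4))
        with pytest.raises(ValueError, match="antidiabetic"):
            selectivity_index(de, ["absent"], genes[:2], "GW1929", "24h")


class TestPartitionDESets:
    def test_disjoint_sets_share_nothing(self):
        rows = []
        for i in range(5):
            rows.append((f"a{i}", "GW1929", "3h", 1.0, 0.001))
            rows.append((f"a{i}", "rosiglitazone", "3h", 1.0, 0.9))
            rows.append((f"b{i}", "GW1929", "3h", 1.0, 0.9))
            rows.append((f"b{i}", "rosiglitazone", "3h", 1.0, 0.001))
        de = pd.DataFrame(rows, columns=["gene_id", "ligand", "timepoint", "log2fc", "padj"])
        out = partition_de_sets(de, ["GW1929", "rosiglitazone"], ["3h"])
        counts = dict(zip(out["counts"]["ligand_set"], out["counts"]["n_genes"]))
        assert counts == {"GW1929": 5, "rosiglitazone": 5}

    def test_matches_brute_force_set_algebra(self):
        rng = np.random.default_rng(12)
        genes = [f"g{i}" for i in range(1000)]
        rows = []
        sig = {}
        for lig in ("A", "B"):
            flags = rng.random(1000) < 0.3
            sig[lig] = {g for g, f in zip(genes, flags) if f}
            for g, f in zip(genes, flags):
                rows.append((g, lig, "3h", 1.0, 0.001 if f else 0.5))
        de = pd.DataFrame(rows, columns=["gene_id", "ligand", "timepoint", "log2fc", "padj"])
        out = partition_de_sets(de, ["A", "B"], ["3h"])
        cells = out["cells"]["3h"]
        assert cells.get(frozenset(["A"]), set()) == sig["A"] - sig["B"]
        assert cells.get(frozenset(["B"]), set()) == sig["B"] - sig["A"]
        assert cells.get(frozenset(["A", "B"]), set()) == sig["A"] & sig["B"]

    def test_cross_timepoint_transitions(self):
        rows = []
        # g0: only-A at 3h -> both at 24h; g1: only-A at 3h -> neither at 24h
        for g, (p3a, p3b, p24a, p24b) in {
            "g0": (0.001, 0.9, 0.001, 0.001),
            "g1": (0.001, 0.9, 0.9, 0.9),
        }.items():
            rows += [(g, "A", "3h", 1.0, p3a), (g, "B", "3h", 1.0, p3b),
                     (g, "A", "24h", 1.0, p24a), (g, "B", "24h", 1.0, p24b)]
        de = pd.DataFrame(rows, columns=["gene_id", "ligand", "timepoint", "log2fc", "padj"])
        out = partition_de_sets(de, ["A", "B"], ["3h", "24h"])
        trans = out["transitions"]
        lookup = {(r.ligand, r.to_class): r.n_genes for r in trans.itertuples()}
        assert lookup[("A", "both")] == 1
        assert lookup[("A", "neither")] == 1
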