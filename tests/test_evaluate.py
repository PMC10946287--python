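"""Confusion-matrix metrics, containment matching and composition distances."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from ribodb.evaluate import (
    ConfusionCounts,
    bray_curtis,
    confusion_counts,
    evaluate_dataset,
    expand_clustered_name,
    metrics_from_counts,
    names_match,
    summarize_configurations,
    weighted_mean,
)
from ribodb.mockgen import build_mock_community, generate_fixture_database, simulate_assignment
from ribodb.taxio import SynonymEntry, SynonymMap, TaxonomyString

from .conftest import make_lineage, name_st


def brute_force_confusion(expected, assigned, rank):
    """Independent double loop over taxa x sequences (the defining tally)."""
    exp = {sid: t.label(rank) for sid, t in expected.items()}
    asn = {sid: t.label(rank) for sid, t in assigned.items()}
    taxa = sorted({l for l in exp.values() if l} | {l for l in asn.values() if l})
    out = {}
    for taxon in taxa:
        tp = fp = fn = tn = 0
        for sid in exp:
            ma = names_match(taxon, asn[sid])
            me = names_match(taxon, exp[sid])
            if ma and me:
                tp += 1
            elif ma:
                fp += 1
            elif me:
                fn += 1
            else:
                tn += 1
        out[taxon] = (tp, fp, fn, tn)
    return out


class TestExpandAndMatch:
    def test_expand_worked_species_label(self):
        assert expand_clustered_name(
            "Lactobacillus_crispatus:Limosilactobacillus_fermentum-oris"
        ) == {
            "Lactobacillus_crispatus",
            "Limosilactobacillus_fermentum",
            "Limosilactobacillus_oris",
        }

    def test_expand_plain_label(self):
        assert expand_clustered_name("Bacilli") == {"Bacilli"}

    def test_expand_unknown_is_empty(self):
        assert expand_clustered_name("Unknown") == frozenset()

    def test_containment_match_example(self):
        # clustered assignment contains the expected name
        assert names_match(
            "Amylolactobacillus amylophilus-Lactobacillus iners", "Lactobacillus iners"
        )

    def test_distinct_species_do_not_match(self):
        assert not names_match("Lactobacillus_iners", "Lactobacillus_jensenii")

    def test_empty_labels_match_nothing(self):
        assert not names_match("", "Lactobacillus_iners")
        assert not names_match("Lactobacillus_iners", "")

    @given(name_st, name_st)
    def test_symmetry(self, a, b):
        assert names_match(a, b) == names_match(b, a)

    @given(st.sets(name_st, min_size=1, max_size=5), name_st)
    def test_clustered_label_matches_each_member(self, names, other):
        from ribodb.cluster import merge_rank_names

        label = merge_rank_names(names)
        for name in names:
            assert names_match(label, name)
        assert names_match(label, other) == (other in names)


class TestConfusionCounts:
    def test_all_correct_species(self):
        tax = make_lineage("Lactobacillus", "Lactobacillus_iners")
        table = {f"q{i}": tax for i in range(3)}
        counts = confusion_counts(table, dict(table), "species")
        (c,) = [c for c in counts if c.taxon == "Lactobacillus_iners"]
        assert (c.tp, c.fp, c.fn, c.tn) == (3, 0, 0, 0)

    def test_misassignment_distributes_fn_fp_tn(self):
        # one L. iners read assigned as L. jensenii; a L. crispatus read correct
        iners = make_lineage("Lactobacillus", "Lactobacillus_iners")
        jensenii = make_lineage("Lactobacillus", "Lactobacillus_jensenii")
        crispatus = make_lineage("Lactobacillus", "Lactobacillus_crispatus")
        expected = {"q1": iners, "q2": crispatus}
        assigned = {"q1": jensenii, "q2": crispatus}
        by_taxon = {
            c.taxon: c for c in confusion_counts(expected, assigned, "species")
        }
        i = by_taxon["Lactobacillus_iners"]
        assert (i.tp, i.fp, i.fn, i.tn) == (0, 0, 1, 1)
        j = by_taxon["Lactobacillus_jensenii"]
        assert (j.tp, j.fp, j.fn, j.tn) == (0, 1, 0, 1)
        c = by_taxon["Lactobacillus_crispatus"]
        assert (c.tp, c.fp, c.fn, c.tn) == (1, 0, 0, 1)

    def test_id_mismatch_rejected(self):
        tax = make_lineage("G", "G_a")
        with pytest.raises(ValueError, match="sequence ids"):
            confusion_counts({"a": tax}, {"b": tax}, "species")

    @pytest.mark.parametrize("rank", ["genus", "species"])
    def test_matches_brute_force_on_random_tables(self, rank):
        db = generate_fixture_database(12, seed=31)
        rng = np.random.default_rng(5)
        for trial in range(20):
            mock = build_mock_community(db, n_taxa=6, seed=trial)
            expected = mock.expected_taxonomy()
            assigned = simulate_assignment(mock, db, 0.5, 0.1, seed=trial)
            got = {
                c.taxon: (c.tp, c.fp, c.fn, c.tn)
                for c in confusion_counts(expected, assigned, rank)
            }
            assert got == brute_force_confusion(expected, assigned, rank)
            n = len(expected)
            for c in confusion_counts(expected, assigned, rank):
                assert c.total == n


class TestMetrics:
    def test_hand_arithmetic(self):
        scores = metrics_from_counts(ConfusionCounts("t", tp=3, fp=1, fn=1, tn=5))
        assert scores.precision == 0.75
        assert scores.recall == 0.75
        assert scores.accuracy == 0.8
        assert scores.f1 == 0.75
        assert scores.undefined == frozenset()

    def test_perfect_counts(self):
        scores = metrics_from_counts(ConfusionCounts("t", tp=4, fp=0, fn=0, tn=6))
        assert (scores.precision, scores.recall, scores.f1, scores.accuracy) == (
            1.0, 1.0, 1.0, 1.0,
        )

    def test_degenerate_ratios_flagged_as_zero(self):
        scores = metrics_from_counts(ConfusionCounts("t", tp=0, fp=0, fn=0, tn=5))
        assert scores.precision == 0.0
        assert {"precision", "recall", "f1"} <= scores.undefined
        assert scores.accuracy == 1.0


class TestWeightedMean:
    def test_equal_weights_reduce_to_mean(self):
        assert weighted_mean([0.2, 0.4, 0.9], [1, 1, 1]) == pytest.approx(0.5)

    def test_direct_weighting(self):
        assert weighted_mean([1.0, 0.0], [0.9, 0.1]) == pytest.approx(0.9)

    @given(
        st.lists(st.floats(0, 1), min_size=1, max_size=10),
        st.integers(0, 2**31 - 1),
    )
    def test_matches_dot_product_oracle_and_bounds(self, scores, seed):
        rng = np.random.default_rng(seed)
        weights = rng.uniform(0.01, 1.0, size=len(scores))
        got = weighted_mean(scores, list(weights))
        expect = float(np.dot(scores, weights) / weights.sum())
        assert got == pytest.approx(expect)
        assert min(scores) - 1e-12 <= got <= max(scores) + 1e-12

    def test_zero_weights_return_zero(self):
        assert weighted_mean([1.0, 1.0], [0.0, 0.0]) == 0.0

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            weighted_mean([1.0], [1.0, 2.0])


class TestBrayCurtis:
    def test_identical_zero(self):
        assert bray_curtis({"a": 0.5, "b": 0.5}, {"a": 0.5, "b": 0.5}) == 0.0

    def test_disjoint_one(self):
        assert bray_curtis({"a": 1.0}, {"b": 1.0}) == pytest.approx(1.0)

    def test_closed_form_half(self):
        assert bray_curtis({"a": 0.5, "b": 0.5}, {"a": 1.0}) == pytest.approx(0.5)

    @given(
        st.dictionaries(name_st, st.floats(0.01, 1), min_size=1, max_size=6),
        st.dictionaries(name_st, st.floats(0.01, 1), min_size=1, max_size=6),
    )
    def test_matches_min_sum_formula_and_symmetry(self, e, a):
        got = bray_curtis(e, a)
        taxa = set(e) | set(a)
        shared = sum(min(e.get(t, 0.0), a.get(t, 0.0)) for t in taxa)
        total = sum(e.values()) + sum(a.values())
        assert got == pytest.approx(1 - 2 * shared / total)
        assert bray_curtis(a, e) == pytest.approx(got)
        assert 0.0 <= got <= 1.0


@pytest.fixture(scope="module")
def db():
    return generate_fixture_database(40, seed=50)


class TestEvaluateDataset:

    def test_zero_error_is_perfect(self, db):
        mock = build_mock_community(db, n_taxa=10, seed=1)
        table = simulate_assignment(mock, db, error_rate=0.0, seed=1)
        df = evaluate_dataset(mock, table)
        assert len(df) == len(mock.samples) * 7
        assert (df["f1"] == 1.0).all()
        assert (df["bray_curtis"] == 0.0).all()

    def test_known_error_rate_bounds_recall(self, db):
        mock = build_mock_community(db, n_taxa=30, seed=2)
        table = simulate_assignment(mock, db, error_rate=0.3, seed=2)
        df = evaluate_dataset(mock, table)
        species = df[df["rank"] == "species"]
        # sequence-level recall is bounced around by abundance weights but
        # stays in a broad band around 1 - error_rate
        assert 0.3 <= species["recall"].mean() <= 0.95

    def test_unification_applied_before_comparison(self, db):
        syn = SynonymMap(
            {"Bacteroidota": SynonymEntry("Bacteroidetes", 976, "Bacteria")}
        )
        old = make_lineage("G", "G_a").replace("phylum", "Bacteroidetes")
        new = old.replace("phylum", "Bacteroidota")
        from ribodb.mockgen import MockCommunity, MockTaxon

        mock = MockCommunity(
            name="m", seed=0,
            taxa=[MockTaxon("G_a", old, ("q1",))],
            samples=["S1"],
            abundance={"S1": {"G_a": 1.0}},
            sequences={"q1": "ACGT"},
        )
        df = evaluate_dataset(mock, {"q1": new}, syn)
        phylum = df[df["rank"] == "phylum"].iloc[0]
        assert phylum["f1"] == 1.0 and phylum["bray_curtis"] == 0.0

    def test_unassigned_mass_is_its_own_label(self, db):
        mock = build_mock_community(db, n_taxa=5, seed=3)
        table = simulate_assignment(mock, db, error_rate=0.0, unassigned_rate=1.0, seed=3)
        df = evaluate_dataset(mock, table)
        assert np.allclose(df["bray_curtis"], 1.0)
        assert (df["recall"] == 0.0).all()

    def test_missing_ids_rejected(self, db):
        mock = build_mock_community(db, n_taxa=5, seed=4)
        with pytest.raises(ValueError, match="lacks"):
            evaluate_dataset(mock, {})


class TestSummarize:
    @staticmethod
    def frame(f1_by_rank):
        rows = []
        for rank, f1 in f1_by_rank.items():
            for sample in ("S1", "S2"):
                rows.append(
                    {
                        "sample": sample, "rank": rank, "precision": f1,
                        "recall": f1, "f1": f1, "accuracy": f1, "bray_curtis": 0.1,
                    }
                )
        return pd.DataFrame(rows)

    def test_single_configuration_is_best(self):
        summary = summarize_configurations({"only": self.frame({"genus": 0.8})})
        assert summary["best"].all()

    def test_engineered_gap_finds_winner(self):
        summary = summarize_configurations(
            {
                "weak": self.frame({"genus": 0.6, "species": 0.2}),
                "strong": self.frame({"genus": 0.9, "species": 0.7}),
            }
        )
        winners = summary[summary["best"]]
        assert set(winners["configuration"]) == {"strong"}
        assert len(winners) == 2  # one winner per rank

    def test_means_match_recomputation(self):
        df_a = self.frame({"genus": 0.6})
        df_a.loc[0, "f1"] = 0.4  # make the mean non-trivial
        summary = summarize_configurations({"a": df_a})
        assert summary.loc[0, "f1_mean"] == pytest.approx(df_a["f1"].mean())
        assert summary.loc[0, "f1_std"] == pytest.approx(df_a["f1"].std())

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            summarize_configurations({})
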