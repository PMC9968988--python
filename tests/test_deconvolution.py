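"""Deconvolution cascade vs hand counts and a brute-force record-loop oracle."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from mmpscreen.datasets import load_gsk3b_inhibitors
from mmpscreen.deconvolution import (
    DeconvolutionConfig,
    filter_by_potency,
    mean_potency,
    potency_matrix,
    primary_target_counts,
    target_frequency,
    unique_offtargets,
    unique_targets,
)
from mmpscreen.errors import ConfigError, UnknownCompoundError

from conftest import make_annotations, random_annotation_records


# ---------------------------------------------------------------------------
# brute-force oracle: plain nested loops over (compound, target, pic50, primary)


def oracle_filter(records, pic50_min):
    return [r for r in records if r[2] is not None and r[2] >= pic50_min]


def oracle_unique_targets(records, compounds):
    return {t for c, t, p, prim in records if c in compounds}


def oracle_frequency(records, hits, min_frequency):
    counts = {}
    for c, t, p, prim in records:
        if c in hits:
            counts.setdefault(t, set()).add(c)
    return {t: len(cs) for t, cs in counts.items() if len(cs) >= min_frequency}


def oracle_mean_potency(records, target, compounds):
    vals = [p for c, t, p, prim in records if t == target and c in compounds and p is not None]
    return sum(vals) / len(vals) if vals else None


def oracle_primary_counts(records, hits):
    counts = {}
    for c, t, p, prim in records:
        if prim and c in hits:
            counts[t] = counts.get(t, 0) + 1
    return counts


def oracle_offtargets(records, compound, comparators, pic50_min):
    kept = oracle_filter(records, pic50_min)
    own = {t for c, t, p, prim in kept if c == compound}
    other = {t for c, t, p, prim in kept if c in comparators}
    return own - other


# ---------------------------------------------------------------------------


class TestFilterByPotency:
    def test_az3_gsk3b_retained_at_6(self):
        table, _ = load_gsk3b_inhibitors()
        filtered, _ = filter_by_potency(table, 6.0)
        assert ("AZ3" in filtered.compounds()) and ("GSK3B" in filtered.targets())

    def test_threshold_is_inclusive(self):
        table = make_annotations([("A", "T1", 6.0, False), ("B", "T1", 5.99, False)])
        filtered, report = filter_by_potency(table, 6.0)
        assert filtered.compounds() == {"A"}
        assert report.n_below_threshold == 1

    def test_six_record_hand_count(self):
        pics = [5.0, 6.0, 6.1, 7.5, None, 9.0]
        table = make_annotations(
            [(f"C{i}", f"T{i}", p, False) for i, p in enumerate(pics)]
        )
        filtered, report = filter_by_potency(table, 6.0)
        assert len(filtered) == 4
        assert report.n_missing_pic50 == 1


class TestUniqueTargets:
    def test_empty_compound_set(self, toy_annotations):
        assert unique_targets(toy_annotations, set()) == set()

    def test_union_by_hand(self):
        table = make_annotations(
            [("A", "T1", 7.0, False), ("A", "T2", 7.0, False),
             ("B", "T2", 7.0, False), ("B", "T3", 7.0, False)]
        )
        assert unique_targets(table, {"A", "B"}) == {"T1", "T2", "T3"}


class TestTargetFrequency:
    def test_no_hits_empty(self, toy_annotations):
        assert len(target_frequency(toy_annotations, set())) == 0

    def test_min_frequency_cut(self):
        table = make_annotations(
            [("A", "T1", 7, False), ("B", "T1", 7, False), ("C", "T1", 7, False),
             ("A", "T2", 7, False)]
        )
        freq = target_frequency(table, {"A", "B", "C"}, min_frequency=2)
        assert dict(zip(freq["target_id"], freq["hit_frequency"])) == {"T1": 3}

    def test_sorted_by_count_then_name(self):
        table = make_annotations(
            [("A", "T2", 7, False), ("A", "T1", 7, False), ("B", "T1", 7, False),
             ("B", "T3", 7, False), ("A", "T3", 7, False)]
        )
        freq = target_frequency(table, {"A", "B"})
        assert list(freq["target_id"]) == ["T1", "T3", "T2"]


class TestMeanPotency:
    def test_singleton(self):
        table = make_annotations([("A", "T1", 7.9, False)])
        assert mean_potency(table, "T1", {"A"}) == 7.9

    def test_gsk3b_mean_over_inhibitor_panel(self):
        table, _ = load_gsk3b_inhibitors()
        mean = mean_potency(table, "GSK3β", table.compounds())
        assert mean == pytest.approx(8.8867, abs=1e-3)

    def test_absent_target_is_none(self, toy_annotations):
        assert mean_potency(toy_annotations, "NOTATHING", {"A"}) is None


class TestPrimaryCounts:
    def test_inhibitor_panel_all_primary_gsk3b(self):
        table, _ = load_gsk3b_inhibitors()
        counts = primary_target_counts(table, table.compounds())
        assert dict(zip(counts["target_id"], counts["primary_count"])) == {"GSK3B": 6}

    def test_no_primaries_empty(self):
        table = make_annotations([("A", "T1", 7, False)])
        assert len(primary_target_counts(table, {"A"})) == 0

    def test_toy_counts(self):
        table = make_annotations(
            [("A", "T1", 7, True), ("B", "T1", 7, True), ("C", "T2", 7, True)]
        )
        counts = primary_target_counts(table, {"A", "B", "C"})
        assert dict(zip(counts["target_id"], counts["primary_count"])) == {"T1": 2, "T2": 1}


class TestPotencyMatrix:
    def test_one_by_one(self):
        table = make_annotations([("A", "T1", 7.9, False)])
        mat = potency_matrix(table, ["T1"], ["A"])
        assert mat.loc["T1", "A"] == 7.9

    def test_absent_cell_is_nan(self):
        table = make_annotations(
            [("A", "T1", 7, False), ("A", "T2", 8, False), ("B", "T1", 9, False)]
        )
        mat = potency_matrix(table, ["T1", "T2"], ["A", "B"])
        assert mat.notna().sum().sum() == 3
        assert np.isnan(mat.loc["T2", "B"])

    def test_transposition_symmetry(self):
        table = make_annotations(
            [("A", "T1", 7, False), ("B", "T2", 8, False)]
        )
        mat = potency_matrix(table, ["T1", "T2"], ["A", "B"])
        # swapping the roles of rows and columns transposes the layout
        assert mat.equals(mat.T.T)
        assert list(mat.index) == ["T1", "T2"] and list(mat.columns) == ["A", "B"]


class TestUniqueOfftargets:
    def test_identical_sets_empty(self):
        table = make_annotations(
            [("A", "T1", 7, False), ("B", "T1", 7, False)]
        )
        assert unique_offtargets(table, "A", {"B"}) == set()

    def test_set_difference_by_hand(self):
        table = make_annotations(
            [("A", "T1", 7, False), ("A", "T2", 7, False), ("A", "T3", 7, False),
             ("B", "T2", 7, False), ("C", "T3", 7, False)]
        )
        assert unique_offtargets(table, "A", {"B", "C"}) == {"T1"}

    def test_unknown_compound_raises(self, toy_annotations):
        with pytest.raises(UnknownCompoundError):
            unique_offtargets(toy_annotations, "NOPE", {"A"})

    def test_self_comparison_rejected(self, toy_annotations):
        with pytest.raises(ConfigError):
            unique_offtargets(toy_annotations, "A", {"A", "B"})

    @given(seed=st.integers(0, 30))
    def test_disjoint_from_every_comparator(self, seed):
        rng = np.random.default_rng(seed)
        records = random_annotation_records(rng, n_compounds=12, n_targets=8)
        table = make_annotations(records)
        compounds = sorted(table.compounds())
        compound, comparators = compounds[0], set(compounds[1:5])
        uniq = unique_offtargets(table, compound, comparators, 6.0)
        filtered, _ = filter_by_potency(table, 6.0)
        for s in comparators:
            assert not uniq & unique_targets(filtered, {s})


# ---------------------------------------------------------------------------
# oracle equivalence and monotonicity over random tables


@pytest.mark.parametrize("batch", range(4))
def test_every_operation_matches_brute_force_oracle(batch):
    """200 random tables (<= 50 compounds x 20 targets): pandas path == loops."""
    rng = np.random.default_rng(1000 + batch)
    for _ in range(50):
        n_c = int(rng.integers(1, 51))
        n_t = int(rng.integers(1, 21))
        records = random_annotation_records(rng, n_c, n_t, missing_rate=0.15)
        table = make_annotations(records)
        # the oracle operates on the same normalized record set
        records = list(
            table.df.itertuples(index=False, name=None)
        )  # (compound, target, pic50, primary)
        records = [
            (c, t, None if pd.isna(p) else p, b) for c, t, p, b in records
        ]
        compounds = sorted({r[0] for r in records})
        hits = set(rng.choice(compounds, size=max(1, len(compounds) // 3), replace=False))
        cut = float(rng.uniform(4, 9))
        min_freq = int(rng.integers(1, 4))

        filtered, _ = filter_by_potency(table, cut)
        kept = oracle_filter(records, cut)
        assert sorted(filtered.df.itertuples(index=False, name=None)) == sorted(
            (c, t, p, b) for c, t, p, b in kept
        )
        assert unique_targets(table, hits) == oracle_unique_targets(records, hits)
        freq = target_frequency(filtered, hits, min_freq)
        assert dict(zip(freq["target_id"], freq["hit_frequency"])) == oracle_frequency(
            kept, hits, min_freq
        )
        prim = primary_target_counts(table, hits)
        assert dict(zip(prim["target_id"], prim["primary_count"])) == oracle_primary_counts(
            records, hits
        )
        some_target = records[0][1]
        got = mean_potency(table, some_target, hits)
        want = oracle_mean_potency(records, some_target, hits)
        assert (got is None and want is None) or got == pytest.approx(want)
        if len(compounds) >= 2:
            c0, rest = compounds[0], set(compounds[1:4])
            assert unique_offtargets(table, c0, rest, cut) == oracle_offtargets(
                records, c0, rest, cut
            )
        # matrix spot check against direct lookup
        targets = sorted({r[1] for r in kept})[:5]
        mat = potency_matrix(filtered, targets, compounds[:5])
        for t in targets:
            for c in compounds[:5]:
                want = [p for cc, tt, p, _ in kept if cc == c and tt == t]
                cell = mat.loc[t, c]
                assert (np.isnan(cell) and not want) or cell == want[0]


@given(seed=st.integers(0, 100))
def test_raising_potency_cut_is_monotone(seed):
    rng = np.random.default_rng(seed)
    table = make_annotations(random_annotation_records(rng, 15, 10))
    hits = set(list(table.compounds())[:5])
    lo_cut, hi_cut = sorted(rng.uniform(4, 9, size=2))
    lo, _ = filter_by_potency(table, lo_cut)
    hi, _ = filter_by_potency(table, hi_cut)
    assert unique_targets(hi, hits) <= unique_targets(lo, hits)
    f_lo = dict(zip(*(target_frequency(lo, hits)[c] for c in ("target_id", "hit_frequency"))))
    f_hi = dict(zip(*(target_frequency(hi, hits)[c] for c in ("target_id", "hit_frequency"))))
    for t, n in f_hi.items():
        assert n <= f_lo.get(t, 0) or f_lo.get(t, 0) == 0 and n == 0
        assert n <= f_lo.get(t, 0)


def test_frequency_at_one_sums_to_hit_target_pairs():
    rng = np.random.default_rng(5)
    table = make_annotations(random_annotation_records(rng, 20, 10))
    filtered, _ = filter_by_potency(table, 6.0)
    hits = set(list(table.compounds())[:8])
    freq = target_frequency(filtered, hits, min_frequency=1)
    n_pairs = len(
        filtered.df[filtered.df["compound_id"].isin(hits)][["compound_id", "target_id"]]
        .drop_duplicates()
    )
    assert int(freq["hit_frequency"].sum()) == n_pairs


def test_config_validation():
    with pytest.raises(ConfigError):
        DeconvolutionConfig(pic50_min=float("nan"))
    with pytest.raises(ConfigError):
        DeconvolutionConfig(min_frequency=0)
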