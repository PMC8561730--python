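"""Lineage-tailored curation, completeness/redundancy, and quality gates."""

import itertools

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from dpannkit import (
    CompletenessReport,
    CopyNumberMatrix,
    CuratedCollection,
    CurationConfig,
    ValidationError,
    apply_quality_gates,
    compare_collections,
    curate_collection,
    estimate_completeness,
    filter_genomes_by_tier,
)
from dpannkit.curation import reports_to_frame


def brute_force_curation(counts, lineages, classic, min_overall, min_per_lineage):
    """Independent re-statement of the curation rule, marker by marker."""
    n, k = counts.shape
    kept = []
    for m in range(k):
        present = [counts[g, m] >= 1 for g in range(n)]
        if sum(present) / n < min_overall:
            continue
        ok = True
        for lin in classic:
            idx = [g for g in range(n) if lineages[g] == lin]
            if not idx:
                continue
            frac = sum(present[g] for g in idx) / len(idx)
            if not (frac > min_per_lineage):
                ok = False
                break
        if ok:
            kept.append(m)
    return kept


def _matrix(counts, lineages, priors=None):
    n, k = counts.shape
    gids = [f"g{i}" for i in range(n)]
    return CopyNumberMatrix(
        genome_ids=gids,
        marker_ids=[f"m{j}" for j in range(k)],
        counts=counts,
        lineage={g: lineages[i] for i, g in enumerate(gids)},
        prior_completeness=(
            {g: priors[i] for i, g in enumerate(gids)} if priors else None
        ),
    )


class TestTierFilter:
    def test_inclusive_boundary(self):
        mat = _matrix(np.ones((3, 2), dtype=int), "AAA", [40.0, 50.0, 90.0])
        assert filter_genomes_by_tier(mat, 50.0) == ["g1", "g2"]

    def test_749_vs_750_at_cutoff_75(self):
        mat = _matrix(np.ones((2, 1), dtype=int), "AA", [74.9, 75.0])
        assert filter_genomes_by_tier(mat, 75.0) == ["g1"]

    def test_unreachable_cutoff_warns_and_returns_empty(self):
        mat = _matrix(np.ones((2, 1), dtype=int), "AA", [40.0, 60.0])
        with pytest.warns(UserWarning):
            assert filter_genomes_by_tier(mat, 101.0) == []

    def test_missing_priors_listed(self):
        mat = _matrix(np.ones((2, 1), dtype=int), "AA")
        with pytest.raises(ValidationError):
            filter_genomes_by_tier(mat, 50.0)


class TestCurateCollection:
    def test_universal_marker_retained(self):
        mat = _matrix(np.ones((6, 2), dtype=int), "AAABBB")
        cfg = CurationConfig(classic_lineages=frozenset({"A", "B"}))
        coll = curate_collection(mat, cfg)
        assert coll.marker_ids == ["m0", "m1"]

    def test_marker_failing_one_classic_lineage_dropped(self):
        # 10 genomes: lineage A (5) carries m0 in 2/5 (40%), lineage B (5) in
        # 5/5, so m0 sits at 70% overall but fails the >50% test within A.
        counts = np.zeros((10, 2), dtype=int)
        counts[:, 1] = 1                # m1 universal, keeps the collection non-empty
        counts[[0, 1], 0] = 1           # A: 40%
        counts[[5, 6, 7, 8, 9], 0] = 1  # B: 100%
        cfg = CurationConfig(
            min_prevalence_overall=0.60, classic_lineages=frozenset({"A", "B"})
        )
        coll = curate_collection(_matrix(counts, "AAAAABBBBB"), cfg)
        assert coll.marker_ids == ["m1"]  # m0 fails the 40% < 50% lineage test

    def test_overall_boundary_074_dropped(self):
        # 50 genomes, marker in 37 => 74% < 75%
        counts = np.zeros((50, 2), dtype=int)
        counts[:, 1] = 1
        counts[:37, 0] = 1
        lineages = "A" * 50
        cfg = CurationConfig(classic_lineages=frozenset({"A"}))
        coll = curate_collection(_matrix(counts, lineages), cfg)
        assert "m0" not in coll.marker_ids

    def test_empty_classic_set_rejected(self):
        mat = _matrix(np.ones((2, 1), dtype=int), "AA")
        with pytest.raises(ValidationError):
            curate_collection(mat, CurationConfig(classic_lineages=frozenset()))

    def test_matches_brute_force_on_small_exhaustive(self):
        """Exhaustive {0,1,2} agreement at 2x3 with two lineages."""
        cfg = CurationConfig(classic_lineages=frozenset({"A", "B"}))
        lineages = "AB"
        for cells in itertools.product([0, 1, 2], repeat=6):
            counts = np.array(cells).reshape(2, 3)
            mat = _matrix(counts, lineages)
            expected = brute_force_curation(counts, lineages, ["A", "B"], 0.75, 0.50)
            try:
                got = [mat.marker_ids.index(m) for m in curate_collection(mat, cfg).marker_ids]
            except ValidationError:
                got = []
            assert got == expected, cells

    @given(
        thr_overall=st.floats(0.3, 1.0),
        thr_lineage=st.floats(0.3, 1.0),
        bump=st.floats(0.0, 0.5),
        seed=st.integers(0, 100),
    )
    def test_raising_thresholds_never_adds_markers(self, thr_overall, thr_lineage, bump, seed):
        rng = np.random.default_rng(seed)
        counts = rng.integers(0, 3, size=(8, 6))
        lineages = "AAAABBBB"
        mat = _matrix(counts, lineages)

        def markers(t_o, t_l):
            cfg = CurationConfig(
                min_prevalence_overall=min(t_o, 1.0),
                min_prevalence_per_lineage=min(t_l, 1.0),
                classic_lineages=frozenset({"A", "B"}),
            )
            try:
                return set(curate_collection(mat, cfg).marker_ids)
            except ValidationError:
                return set()

        loose = markers(thr_overall, thr_lineage)
        assert markers(min(thr_overall + bump, 1.0), thr_lineage) <= loose
        assert markers(thr_overall, min(thr_lineage + bump, 1.0)) <= loose


class TestCompareCollections:
    def _pair_setup(self, prev_a, prev_b):
        n = 10
        def mat(prev):
            counts = np.zeros((n, 1), dtype=int)
            counts[: int(round(prev * n)), 0] = 1
            return CopyNumberMatrix([f"g{i}" for i in range(n)], ["mk"], counts)

        return {"A": mat(prev_a), "B": mat(prev_b)}

    def test_higher_prevalence_variant_selected(self):
        mats = self._pair_setup(0.9, 0.6)
        rep = compare_collections(mats, [(("A", "mk"), ("B", "mk"))])
        sel = rep[rep.selected]
        assert list(sel.collection) == ["A"] and sel.prevalence.iloc[0] == 0.9

    def test_tie_breaks_by_priority(self):
        mats = self._pair_setup(0.8, 0.8)
        rep = compare_collections(mats, [(("A", "mk"), ("B", "mk"))], priority=["B", "A"])
        assert rep[rep.selected].collection.iloc[0] == "B"

    def test_singleton_class_passes_through(self):
        mats = self._pair_setup(0.7, 0.7)
        rep = compare_collections(mats, [(("A", "mk"), ("A", "mk"))])
        assert len(rep) == 1 and rep.selected.all()

    def test_unknown_marker_rejected(self):
        mats = self._pair_setup(0.5, 0.5)
        with pytest.raises(ValidationError):
            compare_collections(mats, [(("A", "nope"), ("B", "mk"))])


class TestEstimateCompleteness:
    def _mat_93(self, row):
        return CopyNumberMatrix(
            ["g1"], [f"m{j}" for j in range(93)], np.array([row])
        )

    def test_full_single_copy_genome(self):
        mat = self._mat_93([1] * 93)
        coll = CuratedCollection(marker_ids=list(mat.marker_ids))
        (rep,) = estimate_completeness(mat, coll)
        assert (rep.completeness_pct, rep.redundancy_pct) == (100.0, 0.0)

    def test_zero_row(self):
        mat = self._mat_93([0] * 93)
        coll = CuratedCollection(marker_ids=list(mat.marker_ids))
        (rep,) = estimate_completeness(mat, coll)
        assert (rep.completeness_pct, rep.redundancy_pct) == (0.0, 0.0)

    def test_89_of_93_one_duplicated_rounds_to_95_7_and_1_1(self):
        row = [1] * 88 + [2] + [0] * 4  # 89 present, one multi-copy
        mat = self._mat_93(row)
        coll = CuratedCollection(marker_ids=list(mat.marker_ids))
        (rep,) = estimate_completeness(mat, coll)
        frame = reports_to_frame([rep])
        assert frame.completeness_pct.iloc[0] == 95.7
        assert frame.redundancy_pct.iloc[0] == 1.1

    def test_markers_outside_collection_ignored(self, toy_matrix):
        coll = CuratedCollection(marker_ids=["m1", "m2"])
        reports = estimate_completeness(toy_matrix, coll)
        by_g = {r.genome_id: r for r in reports}
        assert by_g["g4"].completeness_pct == 50.0  # m1 absent, m2 present
        for r in reports:
            assert r.redundancy_pct <= r.completeness_pct

    def test_collection_marker_missing_from_matrix(self, toy_matrix):
        with pytest.raises(ValidationError):
            estimate_completeness(toy_matrix, CuratedCollection(marker_ids=["mX"]))


class TestQualityGates:
    def _report(self, c, r):
        return CompletenessReport("g", c, r, 0, 0, 1)

    def test_good_mag_passes_both_gates(self):
        verdicts = apply_quality_gates(self._report(95.7, 1.1), n_tRNA=21, len_16S_bp=1400)
        assert verdicts["report_gate"].passed and verdicts["species_gate"].passed

    def test_redundancy_exactly_10_splits_the_gates(self):
        verdicts = apply_quality_gates(self._report(92.0, 10.0), n_tRNA=20, len_16S_bp=1200)
        assert verdicts["report_gate"].passed
        assert not verdicts["species_gate"].passed
        assert any("redundancy" in c for c in verdicts["species_gate"].failed_criteria)

    def test_low_completeness_fails_report_gate(self):
        verdicts = apply_quality_gates(self._report(49.9, 0.0))
        assert not verdicts["report_gate"].passed

    @pytest.mark.parametrize(
        "c,r,trna,s16,species_ok",
        [
            (90.0, 9.9, 18, 1000, True),
            (89.9, 0.0, 21, 1400, False),
            (95.0, 0.0, 17, 1400, False),
            (95.0, 0.0, 18, 999, False),
        ],
    )
    def test_species_gate_boundaries(self, c, r, trna, s16, species_ok):
        verdicts = apply_quality_gates(self._report(c, r), n_tRNA=trna, len_16S_bp=s16)
        assert verdicts["species_gate"].passed is species_ok
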