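"""Copy-number matrix model, TSV round-trip, and HMMER hit collapsing."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from dpannkit import (
    CopyNumberMatrix,
    HitRecord,
    ParseError,
    ValidationError,
    marker_prevalence,
    matrix_from_hits,
    read_matrix_tsv,
    write_matrix_tsv,
)
from dpannkit.matrix import read_domtbl_hits

DOMTBL = """\
# target name        accession   tlen query name           accession   qlen   E-value  score  bias   #  of  c-Evalue  i-Evalue  score  bias  from    to  from    to  from    to  acc description of target
#------------------- ---------- ----- -------------------- ---------- ----- --------- ------ ----- --- --- --------- --------- ------ ----- ----- ----- ----- ----- ----- ----- ---- ---------------------
g1|p1                -            210 arCOG00001           -            120     1e-30  100.0   0.1   1   1     2e-30     1e-29   99.0   0.1     1   120     1   118     1   120 0.98 -
g1|p2                -            190 arCOG00001           -            120     1e-25   80.0   0.0   1   1     2e-25     1e-24   79.0   0.0     1   120     1   118     1   120 0.95 -
g2|p9                -            300 arCOG00002           -            150     1e-10   30.0   0.0   1   1     2e-10     1e-09   29.0   0.0     1   150     1   148     1   150 0.90 -
"""


class TestCopyNumberMatrix:
    def test_rejects_duplicate_ids(self):
        with pytest.raises(ValidationError):
            CopyNumberMatrix(["g1", "g1"], ["m1"], np.zeros((2, 1), dtype=int))
        with pytest.raises(ValidationError):
            CopyNumberMatrix(["g1"], ["m1", "m1"], np.zeros((1, 2), dtype=int))

    def test_rejects_negative_and_fractional_counts(self):
        with pytest.raises(ValidationError):
            CopyNumberMatrix(["g1"], ["m1"], np.array([[-1]]))
        with pytest.raises(ValidationError):
            CopyNumberMatrix(["g1"], ["m1"], np.array([[0.5]]))

    def test_lineage_must_cover_all_genomes(self):
        with pytest.raises(ValidationError, match="g2"):
            CopyNumberMatrix(
                ["g1", "g2"], ["m1"], np.ones((2, 1), dtype=int), lineage={"g1": "A"}
            )


class TestTsvRoundTrip:
    def test_minimal_matrix(self, tmp_path):
        path = tmp_path / "m.tsv"
        path.write_text("genome\tm1\ng1\t2\n")
        mat = read_matrix_tsv(path)
        assert mat.count("g1", "m1") == 2

    def test_duplicate_genome_row_errors(self, tmp_path):
        path = tmp_path / "m.tsv"
        path.write_text("genome\tm1\ng1\t2\ng1\t3\n")
        with pytest.raises(ParseError, match="g1"):
            read_matrix_tsv(path)

    def test_non_integer_cell_names_row_and_column(self, tmp_path):
        path = tmp_path / "m.tsv"
        path.write_text("genome\tm1\tm2\ng1\t1\tx\n")
        with pytest.raises(ParseError, match="m2"):
            read_matrix_tsv(path)

    @given(
        n=st.integers(1, 6),
        k=st.integers(1, 6),
        data=st.data(),
    )
    def test_round_trip_lossless(self, tmp_path_factory, n, k, data):
        counts = np.array(
            data.draw(
                st.lists(
                    st.lists(st.integers(0, 5), min_size=k, max_size=k),
                    min_size=n,
                    max_size=n,
                )
            )
        )
        mat = CopyNumberMatrix(
            [f"g{i}" for i in range(n)], [f"m{j}" for j in range(k)], counts
        )
        path = tmp_path_factory.mktemp("rt") / "m.tsv"
        write_matrix_tsv(mat, path)
        assert read_matrix_tsv(path) == mat


class TestMatrixFromHits:
    def _hit(self, protein, profile, evalue, genome):
        return HitRecord(protein, profile, evalue, genome)

    def test_no_hits_gives_zero_matrix(self):
        mat = matrix_from_hits([], 1e-20, genome_ids=["g1"], marker_ids=["m1"])
        assert mat.count("g1", "m1") == 0

    def test_distinct_proteins_counted(self):
        hits = [
            self._hit("g1|p1", "m1", 1e-30, "g1"),
            self._hit("g1|p2", "m1", 1e-30, "g1"),
            self._hit("g1|p1", "m1", 1e-40, "g1"),  # same protein twice: one copy
        ]
        mat = matrix_from_hits(hits, 1e-20)
        assert mat.count("g1", "m1") == 2

    def test_evalue_threshold_excludes_weak_hits(self):
        hits = [self._hit("g1|p1", "m1", 1e-10, "g1")]
        mat = matrix_from_hits(hits, 1e-20, genome_ids=["g1"], marker_ids=["m1"])
        assert mat.count("g1", "m1") == 0

    def test_per_profile_threshold_overrides_global(self):
        hits = [self._hit("g1|p1", "m1", 1e-10, "g1")]
        mat = matrix_from_hits(hits, 1e-20, profile_evalue_max={"m1": 1e-5})
        assert mat.count("g1", "m1") == 1

    def test_invalid_evalue_max(self):
        with pytest.raises(ValidationError):
            matrix_from_hits([], 0.0)

    @given(
        evalues=st.lists(
            st.floats(1e-50, 1e-1, allow_nan=False), min_size=1, max_size=20
        ),
        thr_lo=st.floats(1e-40, 1e-10),
        thr_hi_factor=st.floats(1.0, 1e10),
    )
    def test_monotone_in_threshold(self, evalues, thr_lo, thr_hi_factor):
        hits = [
            HitRecord(f"g1|p{i}", "m1", e, "g1") for i, e in enumerate(evalues)
        ]
        lo = matrix_from_hits(hits, thr_lo, genome_ids=["g1"], marker_ids=["m1"])
        hi = matrix_from_hits(
            hits, thr_lo * thr_hi_factor, genome_ids=["g1"], marker_ids=["m1"]
        )
        assert np.all(hi.counts >= lo.counts)

    def test_domtbl_ingestion(self, tmp_path):
        path = tmp_path / "hits.domtbl"
        path.write_text(DOMTBL)
        hits = read_domtbl_hits(path)
        assert {h.genome for h in hits} == {"g1", "g2"}
        mat = matrix_from_hits(hits, 1e-20)
        assert mat.count("g1", "arCOG00001") == 2
        assert mat.count("g2", "arCOG00002") == 0  # 1e-10 too weak at 1e-20


class TestPrevalence:
    def test_examples(self, toy_matrix):
        prev = marker_prevalence(toy_matrix)
        assert prev["m2"] == 1.0  # present in all genomes
        assert prev["m1"] == 0.75  # counts 1,1,2,0 -> 3 of 4
        assert prev["m4"] == 0.25

    def test_absent_everywhere_is_zero(self):
        mat = CopyNumberMatrix(["g1", "g2"], ["m1"], np.zeros((2, 1), dtype=int))
        assert marker_prevalence(mat)["m1"] == 0.0

    def test_empty_subset_errors(self, toy_matrix):
        with pytest.raises(ValidationError):
            marker_prevalence(toy_matrix, genome_subset=[])

    @given(st.lists(st.integers(1, 5), min_size=1, max_size=8))
    def test_invariant_to_extra_copies(self, copies):
        base = CopyNumberMatrix(
            [f"g{i}" for i in range(len(copies))], ["m1"],
            np.ones((len(copies), 1), dtype=int),
        )
        inflated = CopyNumberMatrix(
            base.genome_ids, base.marker_ids, np.array(copies).reshape(-1, 1)
        )
        assert marker_prevalence(base)["m1"] == marker_prevalence(inflated)["m1"]
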