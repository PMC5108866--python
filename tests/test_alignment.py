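"""Global alignment vs an exhaustive oracle, identity, MSA, gap filtering."""

import subprocess

import numpy as np
import pytest

from seqdigit.alignment import (AlignmentError, DEFAULT_SCORING,
                                MultipleAlignment, ScoringScheme,
                                complete_deletion, global_align,
                                identity_matrix, percent_identity,
                                progressive_align)
from seqdigit.seqio import FixtureConfig, SeqRecord, make_strain_family


def rec(s: str, rid: str = "x") -> SeqRecord:
    return SeqRecord(id=rid, description="", residues=s)


def brute_force_best_score(a: str, b: str, sc: ScoringScheme) -> float:
    """Enumerate every global alignment; affine gap of length L costs
    open + L*extend.  Exponential — toy strings only."""
    best = [-np.inf]

    def go(i, j, score, prev_op):
        if i == len(a) and j == len(b):
            best[0] = max(best[0], score)
            return
        if i < len(a) and j < len(b):
            s = sc.match if a[i] == b[j] else sc.mismatch
            go(i + 1, j + 1, score + s, "M")
        if i < len(a):
            open_cost = sc.gap_open if prev_op != "D" else 0.0
            go(i + 1, j, score - open_cost - sc.gap_extend, "D")
        if j < len(b):
            open_cost = sc.gap_open if prev_op != "I" else 0.0
            go(i, j + 1, score - open_cost - sc.gap_extend, "I")

    go(0, 0, 0.0, None)
    return best[0]


class TestGlobalAlign:
    def test_identical_strings(self):
        aln = global_align("ACGTACGT", "ACGTACGT")
        assert aln.mismatches == 0 and aln.gap_columns == 0
        assert aln.matches == 8

    def test_single_deletion_toy(self):
        aln = global_align("ACGT", "ACT")
        assert aln.gap_columns == 1 and aln.matches == 3
        assert aln.score == pytest.approx(3 * 5 - 10.5)

    def test_score_matches_exhaustive_enumeration(self):
        rng = np.random.default_rng(2)
        for _ in range(15):
            a = "".join(rng.choice(list("ACGT"), size=int(rng.integers(2, 7))))
            b = "".join(rng.choice(list("ACGT"), size=int(rng.integers(2, 7))))
            expected = brute_force_best_score(a, b, DEFAULT_SCORING)
            assert global_align(a, b).score == pytest.approx(expected)

    def test_score_symmetry(self):
        a, b = "ACGTTGCA", "AGGTTGA"
        assert global_align(a, b).score == global_align(b, a).score

    def test_empty_input_rejected(self):
        with pytest.raises(AlignmentError):
            global_align("", "ACGT")

    def test_rows_ungap_to_inputs(self):
        aln = global_align("ACGTTGCA", "AGGTTGA")
        assert aln.aligned_a.replace("-", "") == "ACGTTGCA"
        assert aln.aligned_b.replace("-", "") == "AGGTTGA"

    def test_invalid_scoring_rejected(self):
        with pytest.raises(AlignmentError):
            ScoringScheme(match=-1, mismatch=0)
        with pytest.raises(AlignmentError):
            ScoringScheme(gap_open=-2)


class TestPercentIdentity:
    def test_identical_records(self):
        aln = global_align("A" * 100, "A" * 100)
        assert percent_identity(aln) == 100.0

    def test_all_columns_arithmetic(self):
        from seqdigit.alignment import PairwiseAlignment

        aln = PairwiseAlignment(a_id="a", b_id="b",
                                aligned_a="A" * 99 + "-",
                                aligned_b="A" * 97 + "CC" + "A",
                                score=0.0, matches=97, mismatches=2,
                                gap_columns=1)
        assert percent_identity(aln) == 97.0
        assert percent_identity(aln, mode="ungapped",
                                rounding="none") == pytest.approx(9700 / 99)

    def test_swap_invariance(self):
        a, b = "ACGTTGCA" * 5, "AGGTTGAA" * 5
        assert percent_identity(global_align(a, b)) == \
            percent_identity(global_align(b, a))

    def test_identity_matrix_layout(self, small_family):
        df = identity_matrix(small_family[:3])
        assert np.all(np.diag(df.to_numpy()) == 100.0)
        assert np.array_equal(df.to_numpy(), df.to_numpy().T)

    def test_fixture_identity_tracks_divergence(self):
        """Mean ingroup identity over aligned residues ~ 100*(1-d)."""
        vals = []
        for seed in range(20):
            recs = make_strain_family(FixtureConfig(
                n_strains=3, length_range=(600, 620), divergence=0.02,
                outgroup_divergence=0.05, seed=seed))
            for i in range(3):
                for j in range(i + 1, 3):
                    vals.append(percent_identity(
                        global_align(recs[i], recs[j]),
                        mode="ungapped", rounding="none"))
        assert abs(np.mean(vals) - 98.0) < 1.0


class TestProgressiveAlign:
    def test_two_records_reduce_to_pairwise(self):
        a, b = rec("ACGTTGCA", "a"), rec("AGGTTGA", "b")
        msa = progressive_align([a, b])
        pair = global_align(a, b)
        assert msa.n_columns == pair.length
        assert msa.ungapped(0) == a.residues and msa.ungapped(1) == b.residues

    def test_identical_records_align_gap_free(self):
        recs = [rec("ACGT" * 25, f"r{i}") for i in range(4)]
        msa = progressive_align(recs)
        assert msa.n_columns == 100
        assert all("-" not in row for row in msa.rows)

    def test_family_rows_ungap_to_inputs(self, small_family, small_msa):
        msa, _, _ = small_msa
        for i, record in enumerate(small_family):
            assert msa.ungapped(i) == record.residues

    def test_width_bounded_by_ancestor(self, small_family, small_msa):
        """End-trimmed strains must align within the ancestor's length."""
        msa, _, _ = small_msa
        assert max(len(r) for r in small_family) <= msa.n_columns <= 620

    def test_single_record_rejected(self):
        with pytest.raises(AlignmentError):
            progressive_align([rec("ACGT")])

    def test_distances_agree_with_mafft(self, tmp_path, small_family):
        """Cross-check: p-distances after complete deletion agree with the
        same pipeline run over a mafft alignment."""
        from seqdigit.phylo import pairwise_distances
        from seqdigit.seqio import write_fasta

        fasta = tmp_path / "fam.fasta"
        write_fasta(small_family, fasta)
        out = subprocess.run(["mafft", "--auto", "--quiet", str(fasta)],
                             capture_output=True, text=True, check=True)
        rows, ids = {}, []
        for block in out.stdout.split(">")[1:]:
            lines = block.splitlines()
            ids.append(lines[0].split()[0])
            rows[ids[-1]] = "".join(lines[1:]).upper()
        theirs = MultipleAlignment(ids=tuple(ids),
                                   rows=tuple(rows[i] for i in ids))
        ours, _ = complete_deletion(progressive_align(small_family))
        theirs_f, _ = complete_deletion(theirs)
        d_ours = pairwise_distances(ours, "p").as_dataframe()
        d_mafft = pairwise_distances(theirs_f, "p").as_dataframe()
        ids_sorted = sorted(ids)
        np.testing.assert_allclose(
            d_ours.loc[ids_sorted, ids_sorted].to_numpy(),
            d_mafft.loc[ids_sorted, ids_sorted].to_numpy(), atol=2e-3)


class TestCompleteDeletion:
    def test_gap_free_is_identity(self):
        msa = MultipleAlignment(ids=("a", "b"),
                                rows=("ACGT" * 250, "ACGT" * 250))
        filtered, retained = complete_deletion(msa)
        assert retained.size == 1000 and filtered.rows == msa.rows

    def test_two_gap_columns_drop_to_eight(self):
        msa = MultipleAlignment(
            ids=("a", "b", "c"),
            rows=("ACGTACGTAC", "AC-TACGTAC", "ACGTAC-TAC"))
        filtered, retained = complete_deletion(msa)
        assert retained.size == 8
        assert filtered.n_columns == 8
        assert list(retained) == [1, 2, 4, 5, 6, 8, 9, 10]

    def test_ambiguity_columns_also_dropped(self):
        msa = MultipleAlignment(ids=("a", "b"), rows=("ANGT", "ACGT"))
        _, retained = complete_deletion(msa)
        assert list(retained) == [1, 3, 4]

    def test_idempotent(self, small_msa):
        _, filtered, _ = small_msa
        again, retained = complete_deletion(filtered)
        assert again.rows == filtered.rows
        assert retained.size == filtered.n_columns

    def test_everything_removed_is_an_error(self):
        msa = MultipleAlignment(ids=("a", "b"), rows=("A-", "-A"))
        with pytest.raises(AlignmentError):
            complete_deletion(msa)
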