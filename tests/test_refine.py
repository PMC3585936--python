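"""Anchor inference, region candidates, candidate choice, and splicing."""

import itertools

import numpy as np
import pytest

import framefix as ff
from framefix.model_io import GAP
from framefix.refine import (
    Block,
    RefineParams,
    Region,
    _run_external_aligner,
    align_region_sequence,
    align_region_structure,
    candidate_cons,
    infer_blocks,
    progressive_align,
    score_candidates,
    splice,
)
from framefix.staccato import _BLOSUM62

from conftest import alignment_from_strings


def spread_coords(n, step=3.8):
    """Well-spread, non-collinear backbone-like trace."""
    t = np.arange(n)
    return np.stack(
        [2.3 * np.cos(1.7 * t), 2.3 * np.sin(1.7 * t), step * t], axis=1
    )


class TestInferBlocks:
    def _flanked_run(self, run_len):
        """Alignment with `run_len` perfect core columns flanked by gapped ones."""
        base = spread_coords(run_len + 2)
        rows = ["W" + "A" * run_len + "W", "-" + "A" * run_len + "-"]
        coords = {0: base, 1: base[1:-1].copy()}
        return alignment_from_strings(rows, coords=coords)

    def test_seven_tight_columns_form_one_block(self):
        a = self._flanked_run(7)
        ann = infer_blocks(a)
        assert [(b.start, b.end) for b in ann.blocks] == [(1, 8)]

    def test_four_columns_are_too_short(self):
        a = self._flanked_run(4)
        ann = infer_blocks(a)
        assert ann.blocks == []
        # everything collapses to a single whole-alignment region
        assert len(ann.regions) == 1
        assert (ann.regions[0].col_start, ann.regions[0].col_end) == (0, 6)

    def test_gap_free_perfect_alignment_is_one_block(self):
        base = spread_coords(9)
        a = alignment_from_strings(
            ["ACDEFGHIK", "ACDEFGHIK"], coords={0: base, 1: base.copy()}
        )
        ann = infer_blocks(a)
        assert [(b.start, b.end) for b in ann.blocks] == [(0, 9)]
        assert ann.regions == []

    def test_loose_stretch_between_tight_runs_becomes_region(self):
        n = 16
        base = spread_coords(n)
        other = base.copy()
        other[6:10] += [0.0, 6.0, 0.0]  # 4 displaced columns in the middle
        a = alignment_from_strings(
            ["A" * n, "A" * n], coords={0: base, 1: other}
        )
        ann = infer_blocks(a)
        assert [(b.start, b.end) for b in ann.blocks] == [(0, 6), (10, 16)]
        assert len(ann.regions) == 1
        assert ann.regions[0].res_ranges == [(6, 10), (6, 10)]


class TestProgressiveAligner:
    def test_single_gap_goes_to_lower_penalty_position(self):
        assert progressive_align(["WGK", "WK"]) == ["WGK", "W-K"]

    def test_identical_sequences_align_gap_free(self):
        assert progressive_align(["WGKA", "WGKA", "WGKA"]) == ["WGKA"] * 3

    def test_empty_sequence_comes_out_all_gap(self):
        out = progressive_align(["WGK", "", "WGK"])
        assert out == ["WGK", "---", "WGK"]

    @staticmethod
    def _score_pairwise(row1, row2, go=-11.0, ge=-1.0):
        total = 0.0
        for a, b in zip(row1, row2):
            if a != "-" and b != "-":
                total += float(_BLOSUM62[a, b])
        for row in (row1, row2):
            run = 0
            for ch in row + "$":
                if ch == "-":
                    run += 1
                else:
                    if run:
                        total += go + ge * (run - 1)
                    run = 0
        return total

    @classmethod
    def _enumerate_best(cls, s1, s2):
        """Exhaustive optimum over all pairwise alignments (no gap-gap columns)."""
        best = [-np.inf]

        def rec(i, j, r1, r2):
            if i == len(s1) and j == len(s2):
                best[0] = max(best[0], cls._score_pairwise(r1, r2))
                return
            if i < len(s1) and j < len(s2):
                rec(i + 1, j + 1, r1 + s1[i], r2 + s2[j])
            if i < len(s1):
                rec(i + 1, j, r1 + s1[i], r2 + "-")
            if j < len(s2):
                rec(i, j + 1, r1 + "-", r2 + s2[j])

        rec(0, 0, "", "")
        return best[0]

    @pytest.mark.parametrize("seed", range(10))
    def test_pairwise_matches_exhaustive_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        aa = list("ARNDCQEGHILKMFPSTWYV")
        s1 = "".join(rng.choice(aa, size=rng.integers(1, 5)))
        s2 = "".join(rng.choice(aa, size=rng.integers(1, 5)))
        r1, r2 = progressive_align([s1, s2])
        assert self._score_pairwise(r1, r2) == pytest.approx(
            self._enumerate_best(s1, s2)
        )


def _block_and_region(n_block=10, region_len=(1, 1), offset=None):
    """Two-chain alignment: a perfect block then a region; chain 1's region
    residues optionally displaced by `offset`."""
    n0 = n_block + region_len[0]
    n1 = n_block + region_len[1]
    base = spread_coords(max(n0, n1))
    c0 = base[:n0].copy()
    c1 = base[:n1].copy()
    if offset is not None:
        c1[n_block:] += offset
    width = n_block + max(region_len)
    rows = []
    for ln in region_len:
        rows.append("A" * n_block + "C" * ln + "-" * (max(region_len) - ln))
    a = alignment_from_strings(rows, coords={0: c0, 1: c1})
    region = Region(
        col_start=n_block,
        col_end=width,
        res_ranges=[(n_block, n_block + region_len[0]),
                    (n_block, n_block + region_len[1])],
        left_block=Block(0, n_block),
    )
    return a, region


class TestStructuralExtension:
    def test_geometry_continuing_block_is_fully_accepted(self):
        a, region = _block_and_region(region_len=(3, 3))
        cand = align_region_structure(region, a)
        assert cand.shape == (2, 3)
        assert np.all(cand != GAP)

    def test_large_deviation_is_rejected_and_left_non_core(self):
        a, region = _block_and_region(region_len=(1, 1),
                                      offset=np.array([0.0, 30.0, 0.0]))
        cand = align_region_structure(region, a)
        # rejected trial -> each chain's residue in its own non-core column
        assert cand.shape == (2, 2)
        assert np.all(np.sum(cand != GAP, axis=0) == 1)

    def test_small_deviation_is_accepted(self):
        a, region = _block_and_region(region_len=(1, 1),
                                      offset=np.array([0.0, 3.0, 0.0]))
        cand = align_region_structure(region, a)
        assert cand.shape == (2, 1)
        assert np.all(cand != GAP)

    def test_unequal_chains_leave_leftovers_non_core(self):
        a, region = _block_and_region(region_len=(2, 1))
        cand = align_region_structure(region, a)
        core = np.all(cand != GAP, axis=0)
        assert core.sum() == 1  # one in-step column before chain 1 exhausts
        assert cand.shape[1] == 2

    def test_no_flanks_returns_current_columns(self):
        a = alignment_from_strings(["AC-", "A-C"])
        region = Region(col_start=0, col_end=3,
                        res_ranges=[(0, 2), (0, 2)])
        cand = align_region_structure(region, a)
        assert np.array_equal(cand, a.rows)


class TestSequenceCandidate:
    def test_identical_subsequences_align_gap_free(self):
        a, region = _block_and_region(region_len=(3, 3))
        cand = align_region_sequence(region, a)
        assert cand.shape == (2, 3)
        assert np.all(cand != GAP)

    def test_absent_chain_comes_out_all_gap(self):
        a, region = _block_and_region(region_len=(2, 0))
        cand = align_region_sequence(region, a)
        assert cand.shape[1] == 2
        assert np.all(cand[1] == GAP)

    def test_missing_external_binary_is_reported(self):
        a, region = _block_and_region(region_len=(2, 2))
        with pytest.raises(RuntimeError, match="clustalw"):
            align_region_sequence(region, a, RefineParams(aligner="clustalw"))

    def test_mafft_adapter_round_trips(self):
        # mafft writes aligned FASTA to stdout through the subprocess contract
        out = _run_external_aligner("mafft", ["TWWHGK", "WWHGK"], [0, 1])
        assert [r.replace("-", "") for r in out] == ["TWWHGK", "WWHGK"]
        assert len(out[0]) == len(out[1])


class TestScoreCandidates:
    def _context(self):
        base = spread_coords(8)
        a = alignment_from_strings(
            ["ACDEFGHI", "ACDEFGHI"], coords={0: base, 1: base.copy()}
        )
        sups = ff.superpose_multiple(a, a.core_columns)
        w = ff.sequence_weights(a)
        return a, w, sups

    def test_lower_cons_candidate_wins(self):
        a, w, sups = self._context()
        good = np.array([[3, 4], [3, 4]])  # aligned identical residues
        bad = np.array([[3, 4, GAP, GAP], [GAP, GAP, 3, 4]])  # zero core
        chosen, info = score_candidates(good, bad, a, w, sups)
        assert info["chosen"] == "sequence"
        assert np.array_equal(chosen, good)
        assert info["cons_structural"] == 9.0

    def test_exact_tie_prefers_structural(self):
        a, w, sups = self._context()
        cand = np.array([[3, 4], [3, 4]])
        _, info = score_candidates(cand, cand.copy(), a, w, sups)
        assert info["chosen"] == "structural"

    def test_zero_core_candidate_scores_worst(self):
        a, w, sups = self._context()
        empty = np.array([[3, GAP], [GAP, 3]])
        assert candidate_cons(empty, a, w, sups) == 9.0

    def test_residue_set_mismatch_rejected(self):
        a, w, sups = self._context()
        c1 = np.array([[3], [3]])
        c2 = np.array([[3, 4], [3, GAP]])
        with pytest.raises(ValueError, match="residue sets"):
            score_candidates(c1, c2, a, w, sups)


class TestSplice:
    def test_idempotent_on_own_columns(self, register_case):
        a = register_case.corrupted
        ann = infer_blocks(a)
        r = ann.regions[0]
        again = splice(a, r.col_start, r.col_end, a.rows[:, r.col_start:r.col_end])
        assert again == a

    def test_residue_conservation_is_enforced(self):
        a = alignment_from_strings(["ACDE", "ACDE"])
        broken = np.array([[1, 1], [1, 2]])  # duplicates residue 1 of row 0
        with pytest.raises(ValueError):
            splice(a, 1, 3, broken)


class TestRefineAlignment:
    def test_single_block_alignment_is_returned_unchanged(self):
        base = spread_coords(12)
        a = alignment_from_strings(
            ["ACDEFGHIKLMN", "ACDEFGHIKLMN"], coords={0: base, 1: base.copy()}
        )
        res = ff.refine_alignment(a)
        assert res.alignment == a
        assert res.decisions == []

    def test_planted_register_error_is_repaired(self, register_case):
        res = ff.refine_alignment(register_case.corrupted)
        truth = register_case.family.true_alignment
        assert ff.percent_correct(res.alignment, truth) == 100.0
        assert any(d["chosen"] == "sequence" for d in res.decisions)

    def test_decision_log_covers_every_region(self, register_case):
        a = register_case.corrupted
        ann = infer_blocks(a)
        res = ff.refine_alignment(a)
        assert len(res.decisions) == len(ann.regions)
        for d in res.decisions:
            assert {"cons_sequence", "cons_structural", "chosen"} <= d.keys()

    def test_anchor_blocks_survive_byte_identical(self, register_case):
        a = register_case.corrupted
        ann = infer_blocks(a)
        res = ff.refine_alignment(a)
        for b_in, b_out in zip(ann.blocks, res.blocks_out):
            assert np.array_equal(
                a.rows[:, b_in.start:b_in.end],
                res.alignment.rows[:, b_out.start:b_out.end],
            )
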