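import math

import pytest
from hypothesis import given, strategies as st

from consmut import (
    Mutation,
    RegionMask,
    SequenceRecord,
    build_construct,
    diff_sequences,
    read_mask,
    select_mutations,
    stabilization_demo,
    sweep_thresholds,
)
from consmut.design import round_percent
from consmut.errors import (
    DuplicateMutationError,
    MaskError,
    NotationError,
    ReferenceMismatchError,
)
from consmut.profile import PositionScore
from bruteforce import brute_force_select

AAS = "ACDEFGHIKLMNPQRSTVWY"


def make_score(pos, wt, cons, ratio):
    f_wt = 0.0 if math.isinf(ratio) else 1.0 / (1.0 + ratio)
    f_cons = 1.0 if math.isinf(ratio) else ratio * f_wt
    return PositionScore(
        residue_number=pos,
        wt_residue=wt,
        consensus_residue=cons,
        f_wt=f_wt,
        f_cons=f_cons,
        ratio=ratio,
    )


def random_scores(rng, n, undefined_p=0.05):
    scores = []
    for pos in range(1, n + 1):
        wt = AAS[int(rng.integers(20))]
        if rng.random() < undefined_p:
            scores.append(
                PositionScore(pos, wt, "", math.nan, math.nan, math.nan)
            )
            continue
        if rng.random() < 0.3:
            scores.append(make_score(pos, wt, wt, 1.0))
            continue
        cons = AAS[(AAS.index(wt) + 1 + int(rng.integers(19))) % 20]
        ratio = math.inf if rng.random() < 0.05 else float(1 + rng.exponential(2.0))
        scores.append(make_score(pos, wt, cons, ratio))
    return scores


def as_dicts(scores):
    return [
        {
            "residue_number": s.residue_number,
            "wt": s.wt_residue,
            "consensus": s.consensus_residue if s.is_defined else None,
            "ratio": s.ratio if s.is_defined else None,
        }
        for s in scores
    ]


class TestSelectMutations:
    def test_strict_inequality_at_published_cutoff(self):
        scores = [
            make_score(1, "A", "A", 1.0),
            make_score(2, "C", "D", 2.0),
            make_score(3, "E", "F", 2.5),
            make_score(4, "G", "H", 3.0),
        ]
        chosen = select_mutations(scores, threshold=2.22)
        assert [m.residue_number for m in chosen] == [3, 4]
        # an exact tie is excluded
        assert [m.residue_number for m in select_mutations(scores, 2.5)] == [4]

    def test_infinite_threshold_selects_nothing(self, rng):
        assert select_mutations(random_scores(rng, 50), math.inf) == []

    def test_infinite_ratio_always_selected(self):
        scores = [make_score(1, "A", "W", math.inf)]
        assert len(select_mutations(scores, 1e12)) == 1

    def test_mask_beyond_reference_is_error(self):
        scores = [make_score(1, "A", "W", 3.0)]
        with pytest.raises(MaskError, match="residue 9"):
            select_mutations(scores, 1.5, RegionMask.from_ranges([(1, 9)]))

    def test_matches_brute_force_with_random_masks(self, rng):
        for _ in range(20):
            scores = random_scores(rng, 200)
            starts = sorted(rng.choice(range(1, 200), size=4, replace=False))
            ranges = [(int(s), min(200, int(s) + int(rng.integers(1, 30)))) for s in starts]
            mask = RegionMask.from_ranges(ranges)
            threshold = float(rng.uniform(0.5, 6.0))
            got = select_mutations(scores, threshold, mask)
            want = brute_force_select(as_dicts(scores), threshold, mask.ranges)
            assert [
                (m.residue_number, m.wt_residue, m.new_residue) for m in got
            ] == want
            for m in got:
                assert m.residue_number in mask


class TestBuildConstruct:
    def test_worked_example_load(self, rng):
        reference = SequenceRecord(
            id="wt", residues="".join(AAS[i % 20] for i in range(501))
        )
        positions = sorted(rng.choice(range(1, 502), size=101, replace=False))
        mutations = [
            Mutation(
                wt_residue=reference.residues[p - 1],
                residue_number=int(p),
                new_residue=AAS[(AAS.index(reference.residues[p - 1]) + 1) % 20],
            )
            for p in positions
        ]
        design = build_construct(reference, mutations, "xCT_20.2", 2.22)
        assert design.mutation_count == 101
        assert design.mutation_percent == 20.2

    def test_empty_mutation_list_is_identity(self):
        ref = SequenceRecord(id="wt", residues="ACDEFG")
        design = build_construct(ref, [], "wt_copy")
        assert design.sequence == "ACDEFG"
        assert design.mutation_percent == 0.0

    def test_diff_roundtrip(self, rng):
        for _ in range(20):
            n = int(rng.integers(5, 80))
            ref = SequenceRecord(
                id="wt", residues="".join(AAS[int(k)] for k in rng.integers(0, 20, n))
            )
            k = int(rng.integers(0, n))
            positions = sorted(rng.choice(range(1, n + 1), size=k, replace=False))
            muts = [
                Mutation(
                    ref.residues[p - 1],
                    int(p),
                    AAS[(AAS.index(ref.residues[p - 1]) + 7) % 20],
                )
                for p in positions
            ]
            design = build_construct(ref, muts, "c")
            assert sorted(
                (m.residue_number, m.wt_residue, m.new_residue)
                for m in diff_sequences(ref, design)
            ) == sorted((m.residue_number, m.wt_residue, m.new_residue) for m in muts)

    def test_wt_mismatch_names_position(self):
        ref = SequenceRecord(id="wt", residues="ACDE")
        with pytest.raises(ReferenceMismatchError, match="position 2"):
            build_construct(ref, [Mutation("W", 2, "Y")], "c")

    def test_duplicate_positions_rejected(self):
        ref = SequenceRecord(id="wt", residues="ACDE")
        with pytest.raises(DuplicateMutationError):
            build_construct(ref, [Mutation("C", 2, "Y"), Mutation("C", 2, "W")], "c")


class TestSweep:
    @given(
        t1=st.floats(min_value=0.1, max_value=10),
        t2=st.floats(min_value=0.1, max_value=10),
        seed=st.integers(min_value=0, max_value=2**31 - 1),
    )
    def test_selection_antitone_in_threshold(self, t1, t2, seed):
        import numpy as np

        lo, hi = sorted([t1, t2])
        scores = random_scores(np.random.default_rng(seed), 60)
        at_lo = {m.residue_number for m in select_mutations(scores, lo)}
        at_hi = {m.residue_number for m in select_mutations(scores, hi)}
        assert at_hi <= at_lo

    def test_threshold_below_min_ratio_selects_every_nonconsensus(self, rng):
        scores = random_scores(rng, 100, undefined_p=0.0)
        finite = [s.ratio for s in scores if s.is_defined and s.ratio > 1]
        threshold = min(finite) * 0.999
        chosen = select_mutations(scores, threshold)
        expected = sum(
            1 for s in scores if s.is_defined and s.consensus_residue != s.wt_residue
        )
        assert len(chosen) == expected

    def test_graded_panel_names(self):
        msa, mask = stabilization_demo()
        from consmut import compute_profiles, map_reference, score_positions

        mapping = map_reference(msa, "REF")
        scores = score_positions(compute_profiles(msa), mapping, msa)
        panel = sweep_thresholds(scores, [3.0, 2.22], mask, msa.get("REF"), "xCT")
        assert [d.name for d in panel] == ["xCT_14.2", "xCT_20.2"]
        assert [d.mutation_count for d in panel] == [71, 101]
        assert panel[0].threshold > panel[1].threshold

    def test_duplicate_thresholds_collapsed(self, rng, caplog):
        scores = random_scores(rng, 30)
        ref = SequenceRecord(id="wt", residues="A" * 30)
        # positions' wt letters don't match ref here, so rebuild consistent scores
        scores = [make_score(i, "A", "W", 1.0 + i / 10) for i in range(1, 31)]
        panel = sweep_thresholds(scores, [2.0, 2.0, 1.5], None, ref, "p")
        assert len(panel) == 2

    def test_name_by_threshold(self):
        ref = SequenceRecord(id="wt", residues="A" * 10)
        scores = [make_score(i, "A", "W", 3.0) for i in range(1, 11)]
        panel = sweep_thresholds(
            scores, [2.5], None, ref, "p", name_by_threshold=True
        )
        assert panel[0].name == "p_t2.5"


class TestMask:
    def test_overlap_merge(self):
        mask = RegionMask.from_ranges([(5, 10), (8, 12)])
        assert mask.ranges == ((5, 12),)

    def test_read_merge_and_comments(self, tmp_path):
        p = tmp_path / "mask.tsv"
        p.write_text("# TM segments\n5\t10\n8\t12\n20\t25  # TM2\n")
        mask = read_mask(p)
        assert mask.ranges == ((5, 12), (20, 25))

    def test_empty_file_is_error(self, tmp_path):
        p = tmp_path / "mask.tsv"
        p.write_text("# nothing here\n")
        with pytest.raises(MaskError):
            read_mask(p)

    def test_bad_range_reports_line(self, tmp_path):
        p = tmp_path / "mask.tsv"
        p.write_text("5\t10\n9\t4\n")
        with pytest.raises(MaskError, match="line 2"):
            read_mask(p)

    def test_twelve_disjoint_segments_total_length(self, tmp_path):
        ranges = [(1 + 40 * k, 25 + 40 * k) for k in range(12)]
        p = tmp_path / "mask.tsv"
        p.write_text("".join(f"{s}\t{e}\n" for s, e in ranges))
        mask = read_mask(p)
        assert len(mask.ranges) == 12
        assert mask.total_length() == sum(e - s + 1 for s, e in ranges)


class TestNotation:
    @given(
        wt=st.sampled_from(AAS),
        pos=st.integers(min_value=1, max_value=99999),
        new=st.sampled_from(AAS),
    )
    def test_roundtrip(self, wt, pos, new):
        if wt == new:
            with pytest.raises(NotationError):
                Mutation(wt, pos, new)
            return
        m = Mutation(wt, pos, new)
        assert Mutation.parse(m.notation) == m

    def test_example(self):
        m = Mutation.parse("V123L")
        assert (m.wt_residue, m.residue_number, m.new_residue) == ("V", 123, "L")

    def test_garbage_rejected(self):
        with pytest.raises(NotationError):
            Mutation.parse("V123")


def test_round_percent_half_up():
    assert round_percent(101, 501) == 20.2
    assert round_percent(71, 501) == 14.2
    assert round_percent(5, 2000) == 0.3  # 0.25 rounds up, not to even
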