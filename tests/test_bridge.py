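"""Relationship tallying, filtering presets and block chaining."""
from itertools import product

import pytest

from methbridge.bridge import (call_relationship, chain_blocks,
                               merged_block_map, tally_relationship)
from methbridge.records import (BlockGap, BlockRelationship, FilterPreset,
                                PhaseBlock, Verdict)


def test_shared_read_with_opposite_labels_votes_switch():
    rel = tally_relationship(1, 2, {"r1": 1}, {"r1": 2})
    assert (rel.same_votes, rel.switch_votes) == (0, 1)


def test_no_shared_reads_gives_zero_votes():
    rel = tally_relationship(1, 2, {"a": 1}, {"b": 2})
    assert (rel.same_votes, rel.switch_votes) == (0, 0)


def test_confidence_formula():
    rel = tally_relationship(1, 2,
                             {f"r{i}": 1 for i in range(6)},
                             {f"r{i}": 1 if i < 5 else 2 for i in range(6)})
    assert (rel.same_votes, rel.switch_votes) == (5, 1)
    assert rel.confidence == pytest.approx(4 / 6)


@pytest.mark.parametrize("votes,min_reads,expected", [
    ((5, 1), 4, Verdict.SAME),       # 6 >= 4 and 0.667 > 0.5
    ((2, 1), 4, Verdict.UNKNOWN),    # below min reads
    ((3, 3), 1, Verdict.UNKNOWN),    # tie
    ((1, 5), 4, Verdict.SWITCH),
    ((4, 2), 4, Verdict.UNKNOWN),    # confidence 1/3 not > 0.5
])
def test_accuracy_mode_verdicts(votes, min_reads, expected):
    rel = BlockRelationship(1, 2, same_votes=votes[0], switch_votes=votes[1])
    preset = FilterPreset(mode="accuracy", min_reads=min_reads)
    assert call_relationship(rel, preset).verdict is expected


def test_min_reads_formula_rounds_up_with_floor():
    assert FilterPreset().resolve(coverage=60, block_count=3179) == (19, 0.5)
    assert FilterPreset().resolve(coverage=0.5, block_count=3000) == (1, 0.5)
    with pytest.raises(ValueError, match="coverage"):
        FilterPreset().resolve(None, None)


def test_success_mode_connects_superset_of_accuracy():
    for same, switch in product(range(6), range(6)):
        rel_a = BlockRelationship(1, 2, same, switch)
        rel_s = BlockRelationship(1, 2, same, switch)
        call_relationship(rel_a, FilterPreset(min_reads=4))
        call_relationship(rel_s, FilterPreset(mode="success"))
        if rel_a.verdict is not Verdict.UNKNOWN:
            assert rel_s.verdict is rel_a.verdict


def _blocks(n):
    return [PhaseBlock(block_id=i + 1, chrom="c", start=1000 * (i + 1),
                       end=1000 * (i + 1) + 500) for i in range(n)]


def _rels(verdicts):
    return [BlockRelationship(i + 1, i + 2, verdict=v)
            for i, v in enumerate(verdicts)]


def test_chain_orientations_same_switch():
    chains, flip_set = chain_blocks(_rels([Verdict.SAME, Verdict.SWITCH]),
                                    _blocks(3))
    assert len(chains) == 1
    assert chains[0].member_ids == [1, 2, 3]
    assert chains[0].flips == [False, False, True]
    assert flip_set == {3}


def test_all_unknown_gives_singletons():
    chains, flip_set = chain_blocks(_rels([Verdict.UNKNOWN] * 2), _blocks(3))
    assert [c.member_ids for c in chains] == [[1], [2], [3]]
    assert flip_set == set()


def test_skipped_gap_breaks_chain():
    gaps = [BlockGap(1, 2, 1500, 2000, skipped=True)]
    chains, _ = chain_blocks(_rels([Verdict.SAME, Verdict.SAME]), _blocks(3),
                             skipped_gaps=gaps)
    assert [c.member_ids for c in chains] == [[1], [2, 3]]


def test_three_blocks_joined_into_one_phase_set():
    """Structural analogue of joining blocks across a difficult region."""
    chains, _ = chain_blocks(_rels([Verdict.SWITCH, Verdict.SAME]), _blocks(3))
    merged = merged_block_map(chains)
    assert merged == {1: 1, 2: 1, 3: 1}


def test_chaining_matches_xor_enumeration_up_to_six_blocks():
    """Exhaustive check of orientation composition for every verdict vector."""
    for n in range(2, 7):
        for verdicts in product([Verdict.SAME, Verdict.SWITCH,
                                 Verdict.UNKNOWN], repeat=n - 1):
            chains, flip_set = chain_blocks(_rels(list(verdicts)), _blocks(n))
            # independent oracle: prefix-XOR within segments split at UNKNOWN
            expected_flips = {}
            orientation = 0
            for i in range(n):
                if i == 0 or verdicts[i - 1] is Verdict.UNKNOWN:
                    orientation = 0
                else:
                    orientation ^= (verdicts[i - 1] is Verdict.SWITCH)
                expected_flips[i + 1] = bool(orientation)
            got = {bid: flip for c in chains
                   for bid, flip in zip(c.member_ids, c.flips)}
            assert got == expected_flips
            assert flip_set == {b for b, f in expected_flips.items() if f}


def test_verdicts_invariant_under_global_haplotype_swap():
    left = {f"r{i}": 1 if i < 7 else 2 for i in range(10)}
    right = {f"r{i}": 1 if i < 6 else 2 for i in range(10)}
    swap = lambda labels: {k: 3 - v for k, v in labels.items()}
    rel = call_relationship(tally_relationship(1, 2, left, right),
                            FilterPreset(min_reads=3))
    rel_sw = call_relationship(tally_relationship(1, 2, swap(left),
                                                  swap(right)),
                               FilterPreset(min_reads=3))
    assert rel_sw.verdict is rel.verdict
    assert (rel_sw.same_votes, rel_sw.switch_votes) \
        == (rel.same_votes, rel.switch_votes)
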