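"""Bridging neighbouring phase blocks by shared methylation-tagged reads.

A read haplotagged in both of the extended blocks flanking a gap votes on
the blocks' relative orientation: identical labels on both sides vote
"same", opposite labels vote "switch".  Relationship calls are filtered by
the accuracy or success preset, then composed left-to-right into chains:
each SWITCH toggles the orientation of every downstream member, and
UNKNOWN verdicts or skipped gaps break the chain.
"""
from __future__ import annotations

from typing import Dict, List, Optional, Sequence, Set, Tuple

from .records import (BlockChain, BlockGap, BlockRelationship, FilterPreset,
                      PhaseBlock, Verdict)


def tally_relationship(
    left_block_id: int,
    right_block_id: int,
    left_labels: Dict[str, int],
    right_labels: Dict[str, int],
) -> BlockRelationship:
    """Count same/switch votes from reads labelled in both extended blocks."""
    rel = BlockRelationship(left_block_id=left_block_id,
                            right_block_id=right_block_id)
    for read_id, left_hap in left_labels.items():
        right_hap = right_labels.get(read_id)
        if right_hap is None:
            continue
        if left_hap == right_hap:
            rel.same_votes += 1
        else:
            rel.switch_votes += 1
    return rel


def call_relationship(
    rel: BlockRelationship,
    preset: FilterPreset,
    coverage: Optional[float] = None,
    block_count: Optional[int] = None,
) -> BlockRelationship:
    """Set the verdict on a vote tally under the given filtering preset.

    The majority side wins when the total vote count reaches the preset's
    minimum and the confidence ``|same - switch| / total`` strictly exceeds
    the preset's threshold; exact ties are always UNKNOWN.
    """
    min_reads, min_confidence = preset.resolve(coverage, block_count)
    if (rel.total_votes >= min_reads
            and rel.confidence > min_confidence
            and rel.same_votes != rel.switch_votes):
        rel.verdict = Verdict.SAME if rel.same_votes > rel.switch_votes \
            else Verdict.SWITCH
    else:
        rel.verdict = Verdict.UNKNOWN
    return rel


def chain_blocks(
    relationships: Sequence[BlockRelationship],
    blocks: Sequence[PhaseBlock],
    skipped_gaps: Sequence[BlockGap] = (),
) -> Tuple[List[BlockChain], Set[int]]:
    """Compose verdicts into block chains and the set of blocks to flip.

    ``relationships`` covers the non-skipped gaps, in any order; chains are
    built left-to-right over the sorted block list.  The first member of
    each chain keeps its orientation and every SWITCH toggles the running
    orientation (XOR composition).  Returns ``(chains, flip_set)``.
    """
    rel_by_pair = {(r.left_block_id, r.right_block_id): r for r in relationships}
    skipped_pairs = {(g.left_block_id, g.right_block_id)
                     for g in skipped_gaps if g.skipped}
    chains: List[BlockChain] = []
    flip_set: Set[int] = set()

    members: List[int] = []
    flips: List[bool] = []

    def close_chain():
        nonlocal members, flips
        if members:
            chains.append(BlockChain(member_ids=members, flips=flips))
            members, flips = [], []

    prev: Optional[PhaseBlock] = None
    for blk in blocks:
        if prev is None:
            members, flips = [blk.block_id], [False]
        else:
            pair = (prev.block_id, blk.block_id)
            rel = rel_by_pair.get(pair)
            verdict = rel.verdict if rel is not None else Verdict.UNKNOWN
            if pair in skipped_pairs or verdict is Verdict.UNKNOWN:
                close_chain()
                members, flips = [blk.block_id], [False]
            else:
                orientation = flips[-1] ^ (verdict is Verdict.SWITCH)
                members.append(blk.block_id)
                flips.append(orientation)
                if orientation:
                    flip_set.add(blk.block_id)
        prev = blk
    close_chain()
    return chains, flip_set


def merged_block_map(chains: Sequence[BlockChain]) -> Dict[int, int]:
    """Map every block id to its chain's phase-set id (the first member's id)."""
    return {bid: chain.chain_id for chain in chains for bid in chain.member_ids}


def relationships_to_table(relationships, truth: Optional[Dict[tuple, str]] = None):
    """Per-chromosome relationship table for CSV export."""
    import pandas as pd

    rows = []
    for r in relationships:
        row = {
            "left_block": r.left_block_id, "right_block": r.right_block_id,
            "same_votes": r.same_votes, "switch_votes": r.switch_votes,
            "confidence": r.confidence, "verdict": r.verdict.value,
        }
        if truth is not None:
            row["truth"] = truth.get((r.left_block_id, r.right_block_id), "NA")
        rows.append(row)
    cols = ["left_block", "right_block", "same_votes", "switch_votes",
            "confidence", "verdict"] + (["truth"] if truth is not None else [])
    return pd.DataFrame(rows, columns=cols)
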