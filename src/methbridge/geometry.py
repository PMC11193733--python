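"""Extended phase blocks and inter-block gaps.

A phase block ``b_i`` spanning ``[s_i, e_i]`` is widened into both adjacent
homozygous gaps: extended block ``be_i`` spans ``[e_{i-1}, s_{i+1}]`` (with
``s_1`` and ``e_n`` substituted at the chromosome ends), so that consecutive
extended blocks overlap exactly on the gap ``(e_i, s_{i+1})`` between their
parents.  Bridging evidence is only collected across non-skipped gaps; by
default the single largest gap per chromosome — in practice the centromere
— is skipped.
"""
from __future__ import annotations

from typing import Iterable, List, Optional, Sequence, Tuple

from .records import BlockGap, ExtendedBlock, PhaseBlock


def compute_extended_blocks(blocks: Sequence[PhaseBlock]) -> List[ExtendedBlock]:
    """Extend each block of one chromosome into its flanking gaps.

    Blocks must be sorted and non-overlapping.  A single block extends to
    itself (there are no gaps to reach into).
    """
    if not blocks:
        return []
    for left, right in zip(blocks, blocks[1:]):
        if right.start <= left.end:
            raise ValueError(
                f"phase blocks must be sorted and non-overlapping: "
                f"{left.block_id} ends at {left.end}, {right.block_id} "
                f"starts at {right.start}")
    n = len(blocks)
    extended = []
    for i, blk in enumerate(blocks):
        ext_start = blocks[i - 1].end if i > 0 else blk.start
        ext_end = blocks[i + 1].start if i < n - 1 else blk.end
        extended.append(ExtendedBlock(
            block_id=blk.block_id, chrom=blk.chrom,
            ext_start=ext_start, ext_end=ext_end, parent=blk))
    return extended


def compute_gaps(blocks: Sequence[PhaseBlock]) -> List[BlockGap]:
    """Inter-block gaps ``(e_i, s_{i+1})`` for a sorted block list."""
    return [
        BlockGap(left_block_id=left.block_id, right_block_id=right.block_id,
                 gap_start=left.end, gap_end=right.start)
        for left, right in zip(blocks, blocks[1:])
    ]


def mark_skipped_gaps(
    gaps: List[BlockGap],
    skip_largest: bool = True,
    exclude_regions: Optional[Iterable[Tuple[int, int]]] = None,
) -> List[BlockGap]:
    """Flag gaps across which no relationship will be attempted.

    With ``skip_largest`` (default) the single largest gap on the
    chromosome is flagged, ties broken to the leftmost.  Gaps overlapping
    any 1-based inclusive interval in ``exclude_regions`` (e.g. a
    centromere annotation) are flagged as well.  Skipped gaps break the
    block chain.
    """
    for gap in gaps:
        gap.skipped = False
    if skip_largest and gaps:
        largest = max(gaps, key=lambda g: g.length)  # max() keeps the leftmost tie
        largest.skipped = True
    if exclude_regions:
        for gap in gaps:
            for start, end in exclude_regions:
                if gap.gap_start <= end and gap.gap_end >= start:
                    gap.skipped = True
                    break
    return gaps
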