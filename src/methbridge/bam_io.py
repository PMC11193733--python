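"""Alignment I/O: decode MM/ML 5mC calls and HP/PS haplotype tags.

Reads are streamed from a coordinate-sorted, indexed BAM.  Modification
calls are projected from read coordinates to reference coordinates via the
alignment; calls falling in deletions or soft clips are dropped.  The
stored 256-bin integer score ``v`` maps to a probability by the bin
midpoint rule ``(v + 0.5) / 256``.

The writer re-emits every input record exactly once, editing only HP and
PS: SNV-tagged reads pass through (HP swapped when their block is
flipped), methylation-assigned reads gain HP and the PS of their merged
block.
"""
from __future__ import annotations

import logging
from array import array
from typing import Dict, Iterator, Optional, Set, Tuple, Union

import pysam

from .records import ModificationDecodeConfig, ReadMethRecord

logger = logging.getLogger(__name__)

BlockKey = Union[int, Tuple[str, int]]


def decode_prob(v: int) -> float:
    """Map a stored 0-255 modification score to its bin-midpoint probability."""
    if not 0 <= v <= 255:
        raise ValueError(f"modification score {v} outside [0, 255]")
    return (v + 0.5) / 256.0


def encode_prob(p: float) -> int:
    """Inverse of :func:`decode_prob`: probability to the containing bin."""
    return min(255, max(0, int(p * 256)))


def _decode_read(
    aln: pysam.AlignedSegment,
    config: ModificationDecodeConfig,
) -> ReadMethRecord:
    record = ReadMethRecord(
        read_id=aln.query_name,
        chrom=aln.reference_name,
        ref_start=aln.reference_start,
        ref_end=aln.reference_end,
        haplotype=aln.get_tag("HP") if aln.has_tag("HP") else None,
        phase_set=aln.get_tag("PS") if aln.has_tag("PS") else None,
        mapq=aln.mapping_quality,
    )
    mods = aln.modified_bases
    if not mods:
        return record
    qpos_to_ref = dict(aln.get_aligned_pairs(matches_only=True))
    calls = []
    for (base, _strand, code), entries in mods.items():
        if base != config.canonical_base or code != config.mod_code:
            continue  # unknown modification stream
        for qpos, score in entries:
            ref_pos = qpos_to_ref.get(qpos)
            if ref_pos is None:
                continue  # deleted from reference or clipped
            if config.merge_strands and aln.is_reverse:
                ref_pos -= 1  # fold the CpG's G onto the forward-strand C
            calls.append((ref_pos, decode_prob(score)))
    calls.sort()
    record.meth_calls = calls
    return record


def read_methylation_records(
    alignment_path: str,
    region: Optional[str] = None,
    config: Optional[ModificationDecodeConfig] = None,
) -> Iterator[ReadMethRecord]:
    """Yield one :class:`ReadMethRecord` per primary alignment in ``region``.

    Secondary alignments are always skipped; supplementary ones unless
    ``config.include_supplementary``.  Reads without MM/ML tags yield a
    record with empty ``meth_calls`` (counted and logged).
    """
    config = config or ModificationDecodeConfig()
    missing_mods = 0
    with pysam.AlignmentFile(alignment_path, "rb") as bam:
        if region is not None and not bam.has_index():
            raise OSError(f"{alignment_path} must be indexed for region queries")
        for aln in bam.fetch(region=region) if region else bam.fetch(until_eof=True):
            if aln.is_unmapped or aln.is_secondary:
                continue
            if aln.is_supplementary and not config.include_supplementary:
                continue
            if aln.mapping_quality < config.min_mapq:
                continue
            record = _decode_read(aln, config)
            if not record.meth_calls and not aln.modified_bases:
                missing_mods += 1
            yield record
    if missing_mods:
        logger.info("%d reads without modification tags in %s",
                    missing_mods, region or alignment_path)


def _lookup(mapping, chrom: str, block_id: int, default=None):
    if mapping is None:
        return default
    if (chrom, block_id) in mapping:
        return mapping[(chrom, block_id)]
    return mapping.get(block_id, default)


def _in_flip_set(flip_set, chrom: str, block_id: int) -> bool:
    return block_id in flip_set or (chrom, block_id) in flip_set


def write_retagged_bam(
    alignment_path: str,
    assignments: Dict[str, Tuple[int, int]],
    flip_set: Set[BlockKey],
    merged_blocks: Optional[Dict[BlockKey, int]],
    out_path: str,
    block_spans: Optional[Dict[BlockKey, Tuple[int, int]]] = None,
) -> Dict[str, int]:
    """Write the re-tagged alignment file; returns summary counts.

    ``assignments`` maps read_id -> (block_id, haplotype) for reads newly
    tagged by methylation (already unique per read); ``flip_set`` holds the
    blocks whose haplotype labels are swapped; ``merged_blocks`` maps each
    block id to its chain's phase-set id.  ``block_spans`` (block id ->
    1-based inclusive extended-block interval) enables the consistency
    check that an assigned read overlaps its block.
    """
    counts = {"snv_tagged": 0, "meth_tagged": 0, "flipped": 0, "total": 0}
    with pysam.AlignmentFile(alignment_path, "rb") as bam:
        header = bam.header.to_dict()
        with pysam.AlignmentFile(out_path, "wb", header=header) as out:
            for aln in bam.fetch(until_eof=True):
                counts["total"] += 1
                chrom = aln.reference_name
                if aln.has_tag("HP"):
                    counts["snv_tagged"] += 1
                    ps = aln.get_tag("PS") if aln.has_tag("PS") else None
                    if ps is not None:
                        if _in_flip_set(flip_set, chrom, ps):
                            aln.set_tag("HP", 3 - aln.get_tag("HP"))
                            counts["flipped"] += 1
                        aln.set_tag("PS", _lookup(merged_blocks, chrom, ps, ps))
                elif not aln.is_unmapped and aln.query_name in assignments:
                    block_id, hap = assignments[aln.query_name]
                    span = _lookup(block_spans, chrom, block_id)
                    if span is not None and not (aln.reference_start < span[1]
                                                 and aln.reference_end > span[0] - 1):
                        raise ValueError(
                            f"read {aln.query_name} assigned to block {block_id} "
                            f"it does not overlap")
                    if _in_flip_set(flip_set, chrom, block_id):
                        hap = 3 - hap
                    aln.set_tag("HP", hap)
                    aln.set_tag("PS", _lookup(merged_blocks, chrom, block_id, block_id))
                    counts["meth_tagged"] += 1
                out.write(aln)
    pysam.index(out_path)
    return counts
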