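"""Phased-VCF I/O: phase blocks in, re-phased variants out.

Phase blocks are derived by grouping phased heterozygous genotypes on
their PS (phase set) value; the block span is the 1-based interval from
its first to its last phased het.  Re-phasing reverses the genotype order
(``a|b -> b|a``) of every variant in a flipped block and rewrites PS so
that all blocks of one chain share the chain's first block id.  Allele
content is never altered.
"""
from __future__ import annotations

import logging
from collections import defaultdict
from typing import Dict, Iterable, List, Optional, Set, Tuple, Union

import pysam

from .records import PhaseBlock, PhasedVariant

logger = logging.getLogger(__name__)

BlockKey = Union[int, Tuple[str, int]]
DEFAULT_BLOCK_ID = 0


def read_phased_vcf(
    vcf_path: str,
    region_filter: Optional[Iterable[str]] = None,
) -> Tuple[Dict[str, List[PhasedVariant]], Dict[str, List[PhaseBlock]]]:
    """Parse a single-sample phased VCF into variants and phase blocks.

    Returns ``(variants_by_chrom, blocks_by_chrom)``; blocks are sorted by
    start.  Unphased and homozygous variants are retained in the variant
    lists but excluded from blocks.  A phased het without PS goes to a
    per-chromosome default block (with a warning).
    """
    wanted = set(region_filter) if region_filter is not None else None
    variants: Dict[str, List[PhasedVariant]] = defaultdict(list)
    missing_ps = 0
    with pysam.VariantFile(vcf_path) as vcf:
        for rec in vcf:
            if wanted is not None and rec.chrom not in wanted:
                continue
            sample = rec.samples[0]
            gt = sample.get("GT")
            if gt is None or len(gt) != 2 or None in gt:
                continue
            phased = bool(sample.phased)
            ps = sample.get("PS")
            het = gt[0] != gt[1]
            if phased and het and ps is None:
                missing_ps += 1
                ps = DEFAULT_BLOCK_ID
            variants[rec.chrom].append(PhasedVariant(
                chrom=rec.chrom, pos=rec.pos, ref=rec.ref,
                alts=tuple(rec.alts or ()), genotype=(gt[0], gt[1]),
                phased=phased, phase_set=ps if (phased and het) else None))
    if missing_ps:
        logger.warning("%d phased het variants without PS assigned to the "
                       "default block", missing_ps)
    return dict(variants), {chrom: blocks_from_variants(vs)
                            for chrom, vs in variants.items()}


def blocks_from_variants(variants: Iterable[PhasedVariant]) -> List[PhaseBlock]:
    """Group one chromosome's phased hets into blocks by phase set."""
    groups: Dict[int, List[PhasedVariant]] = defaultdict(list)
    for v in variants:
        if v.phased and v.is_het and v.phase_set is not None:
            groups[v.phase_set].append(v)
    blocks = [
        PhaseBlock(block_id=ps, chrom=vs[0].chrom,
                   start=min(v.pos for v in vs), end=max(v.pos for v in vs),
                   variant_count=len(vs))
        for ps, vs in groups.items()
    ]
    blocks.sort(key=lambda b: b.start)
    return blocks


def _lookup(mapping, chrom: str, block_id: int, default=None):
    if mapping is None:
        return default
    if (chrom, block_id) in mapping:
        return mapping[(chrom, block_id)]
    return mapping.get(block_id, default)


def _in_flip_set(flip_set, chrom: str, block_id: int) -> bool:
    return block_id in flip_set or (chrom, block_id) in flip_set


def write_rephased_vcf(
    vcf_path: str,
    flip_set: Set[BlockKey],
    merged_blocks: Optional[Dict[BlockKey, int]],
    out_path: str,
) -> Dict[str, int]:
    """Write the re-phased VCF after block chaining; returns summary counts.

    Known block ids are taken from the input's PS values; requesting a flip
    for an unknown block is fatal.
    """
    counts = {"flipped_variants": 0, "total": 0}
    known: Set[Tuple[str, int]] = set()
    with pysam.VariantFile(vcf_path) as vcf:
        header = vcf.header.copy()
        header.add_line("##methbridge=rephased; flipped_blocks="
                        + ",".join(sorted(map(str, flip_set))))
        with pysam.VariantFile(out_path, "w", header=header) as out:
            for rec in vcf:
                counts["total"] += 1
                sample = rec.samples[0]
                gt = sample.get("GT")
                ps = sample.get("PS")
                phased = bool(sample.phased)
                if (phased and gt is not None and len(gt) == 2
                        and None not in gt and gt[0] != gt[1] and ps is not None):
                    known.add((rec.chrom, ps))
                    if _in_flip_set(flip_set, rec.chrom, ps):
                        sample["GT"] = (gt[1], gt[0])
                        counts["flipped_variants"] += 1
                    else:
                        sample["GT"] = gt
                    sample.phased = True
                    sample["PS"] = _lookup(merged_blocks, rec.chrom, ps, ps)
                out.write(rec)
    for key in flip_set:
        chrom_bid = key if isinstance(key, tuple) else None
        if chrom_bid is not None and chrom_bid not in known:
            raise ValueError(f"flip requested for unknown block {key}")
        if chrom_bid is None and not any(b == key for _, b in known):
            raise ValueError(f"flip requested for unknown block {key}")
    return counts


def write_variants_vcf(
    out_path: str,
    variants_by_chrom: Dict[str, List[PhasedVariant]],
    contig_lengths: Dict[str, int],
    sample: str = "SAMPLE",
) -> str:
    """Write PhasedVariant tables as a minimal single-sample VCF."""
    header = pysam.VariantHeader()
    for chrom, length in contig_lengths.items():
        header.add_line(f"##contig=<ID={chrom},length={length}>")
    header.add_line('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    header.add_line('##FORMAT=<ID=PS,Number=1,Type=Integer,Description="Phase set">')
    header.add_sample(sample)
    with pysam.VariantFile(out_path, "w", header=header) as out:
        for chrom in variants_by_chrom:
            for v in sorted(variants_by_chrom[chrom], key=lambda v: v.pos):
                rec = out.new_record(
                    contig=chrom, start=v.pos - 1, stop=v.pos - 1 + len(v.ref),
                    alleles=(v.ref,) + v.alts)
                rec.samples[sample]["GT"] = v.genotype
                rec.samples[sample].phased = v.phased
                if v.phase_set is not None:
                    rec.samples[sample]["PS"] = v.phase_set
                out.write(rec)
    return out_path


def flat_variants(variants_by_chrom: Dict[str, List[PhasedVariant]]):
    for chrom in sorted(variants_by_chrom):
        yield from variants_by_chrom[chrom]
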