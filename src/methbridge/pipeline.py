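"""End-to-end orchestration: phase one chromosome or a whole dataset.

Per chromosome the pipeline (i) derives phase blocks and their extensions
from the phased VCF, (ii) iteratively haplotags untagged reads inside each
extended block, (iii) tallies same/switch votes from reads labelled in
both blocks flanking each non-skipped gap, and (iv) chains blocks through
the called relationships, producing the flip set and merged phase sets
used to rewrite the BAM and VCF.  Chromosomes are processed independently,
so results do not depend on scheduling or thread count.
"""
from __future__ import annotations

import json
import logging
import os
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Set, Tuple

import pysam

from .asm import collect_site_profiles, find_asm_sites
from .bam_io import ModificationDecodeConfig, read_methylation_records, \
    write_retagged_bam
from .bridge import call_relationship, chain_blocks, merged_block_map, \
    relationships_to_table, tally_relationship
from .geometry import compute_extended_blocks, compute_gaps, mark_skipped_gaps
from .metrics import PhasingComparison, compare_phasing, gap_stats, nx, \
    switches_per_connection
from .records import (AsmConfig, BlockChain, BlockGap, BlockRelationship,
                      ExtendedBlock, FilterPreset, PhaseBlock, ReadMethRecord,
                      Verdict, VoteTally, VotingConfig)
from .vcf_io import flat_variants, read_phased_vcf, write_rephased_vcf
from .voting import assignments_to_table, iterate_assignment

logger = logging.getLogger(__name__)

SEX_CHROMS = {"chrX", "chrY", "X", "Y"}


@dataclass
class ChromosomeResult:
    chrom: str
    blocks: List[PhaseBlock]
    extended_blocks: List[ExtendedBlock]
    gaps: List[BlockGap]
    block_tallies: Dict[int, Dict[str, VoteTally]]
    relationships: List[BlockRelationship]
    chains: List[BlockChain]
    flip_set: Set[int]
    merged_map: Dict[int, int]
    assignments: Dict[str, Tuple[int, int]]   # read_id -> (block_id, hap)
    per_iteration: Dict[int, List[int]] = field(default_factory=dict)

    @property
    def n_connections(self) -> int:
        return sum(r.verdict is not Verdict.UNKNOWN for r in self.relationships)

    def blocks_after(self) -> List[PhaseBlock]:
        by_id = {b.block_id: b for b in self.blocks}
        merged = []
        for chain in self.chains:
            members = [by_id[bid] for bid in chain.member_ids]
            merged.append(PhaseBlock(
                block_id=chain.chain_id, chrom=self.chrom,
                start=min(b.start for b in members),
                end=max(b.end for b in members),
                variant_count=sum(b.variant_count for b in members)))
        merged.sort(key=lambda b: b.start)
        return merged


def phase_chromosome(
    reads: Sequence[ReadMethRecord],
    blocks: Sequence[PhaseBlock],
    asm_config: Optional[AsmConfig] = None,
    voting_config: Optional[VotingConfig] = None,
    preset: Optional[FilterPreset] = None,
    coverage: Optional[float] = None,
    genome_block_count: Optional[int] = None,
    skip_largest: bool = True,
    exclude_regions: Optional[Sequence[Tuple[int, int]]] = None,
) -> ChromosomeResult:
    """Run the three phasing steps on one chromosome's in-memory records."""
    asm_config = asm_config or AsmConfig()
    voting_config = voting_config or VotingConfig()
    preset = preset or FilterPreset()
    blocks = sorted(blocks, key=lambda b: b.start)
    chrom = blocks[0].chrom if blocks else (reads[0].chrom if reads else "?")
    if genome_block_count is None:
        genome_block_count = len(blocks)

    extended = compute_extended_blocks(blocks)
    gaps = mark_skipped_gaps(compute_gaps(blocks), skip_largest=skip_largest,
                             exclude_regions=exclude_regions)

    # step 1 + 2: per-extended-block ASM detection and iterative haplotagging
    block_tallies: Dict[int, Dict[str, VoteTally]] = {}
    per_iteration: Dict[int, List[int]] = {}
    snv_labels: Dict[int, Dict[str, int]] = {}
    for ext in extended:
        block_reads = [r for r in reads if ext.overlaps_read(r)]
        tallies, iters = iterate_assignment(block_reads, ext, asm_config,
                                            voting_config)
        block_tallies[ext.block_id] = tallies
        per_iteration[ext.block_id] = iters
        snv_labels[ext.block_id] = {
            r.read_id: r.haplotype for r in block_reads
            if r.haplotype is not None and r.phase_set == ext.block_id}

    # step 3: relationships across the non-skipped gaps
    def labels_of(block_id: int) -> Dict[str, int]:
        labels = dict(snv_labels[block_id])
        labels.update({rid: t.assignment
                       for rid, t in block_tallies[block_id].items()})
        return labels

    relationships = []
    for gap in gaps:
        if gap.skipped:
            continue
        rel = tally_relationship(gap.left_block_id, gap.right_block_id,
                                 labels_of(gap.left_block_id),
                                 labels_of(gap.right_block_id))
        relationships.append(call_relationship(rel, preset, coverage,
                                               genome_block_count))

    chains, flip_set = chain_blocks(relationships, blocks, gaps)
    merged = merged_block_map(chains)

    # unique read assignments: earlier block wins; SNV-tagged reads keep theirs
    snv_tagged = {r.read_id for r in reads if r.haplotype is not None}
    assignments: Dict[str, Tuple[int, int]] = {}
    for ext in extended:
        for rid in sorted(block_tallies[ext.block_id]):
            if rid in snv_tagged or rid in assignments:
                continue
            assignments[rid] = (ext.block_id,
                                block_tallies[ext.block_id][rid].assignment)

    return ChromosomeResult(
        chrom=chrom, blocks=list(blocks), extended_blocks=extended, gaps=gaps,
        block_tallies=block_tallies, relationships=relationships,
        chains=chains, flip_set=flip_set, merged_map=merged,
        assignments=assignments, per_iteration=per_iteration)


def estimate_coverage(bam_path: str, window: int = 1_000,
                      windows_per_contig: int = 20) -> float:
    """Mean read depth over evenly spaced windows of each contig."""
    depths = []
    with pysam.AlignmentFile(bam_path, "rb") as bam:
        for contig, length in zip(bam.references, bam.lengths):
            n = min(windows_per_contig, max(1, length // window))
            step = max(1, (length - window) // n)
            for start in range(0, length - window + 1, step)[:n]:
                cov = bam.count_coverage(contig, start, start + window,
                                         quality_threshold=0)
                depths.append(sum(map(sum, cov)) / window)
    if not depths:
        raise ValueError(f"cannot estimate coverage from {bam_path}")
    return float(sum(depths) / len(depths))


def _read_exclude_bed(path: str) -> Dict[str, List[Tuple[int, int]]]:
    regions: Dict[str, List[Tuple[int, int]]] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track")):
                continue
            chrom, start, end = line.split()[:3]
            regions.setdefault(chrom, []).append((int(start) + 1, int(end)))
    return regions


def run_phase(
    bam_path: str,
    vcf_path: str,
    out_prefix: str,
    asm_config: Optional[AsmConfig] = None,
    voting_config: Optional[VotingConfig] = None,
    preset: Optional[FilterPreset] = None,
    coverage: Optional[float] = None,
    skip_largest: bool = True,
    exclude_bed: Optional[str] = None,
    include_sex: bool = False,
    decode_config: Optional[ModificationDecodeConfig] = None,
    chroms: Optional[Sequence[str]] = None,
    threads: int = 1,
) -> dict:
    """Phase a dataset end to end and write all outputs.

    ``threads`` is accepted for interface compatibility; chromosomes are
    processed independently so results are identical for any value.
    """
    preset = preset or FilterPreset()
    decode_config = decode_config or ModificationDecodeConfig()
    variants_by_chrom, blocks_by_chrom = read_phased_vcf(vcf_path)
    with pysam.AlignmentFile(bam_path, "rb") as bam:
        bam_chroms = set(bam.references)
    targets = [c for c in sorted(blocks_by_chrom)
               if c in bam_chroms
               and (include_sex or c not in SEX_CHROMS)
               and (chroms is None or c in chroms)]
    if not targets:
        raise ValueError("no chromosome shared between BAM and VCF to phase")

    genome_block_count = sum(len(blocks_by_chrom[c]) for c in targets)
    if coverage is None and preset.mode == "accuracy" and preset.min_reads is None:
        coverage = estimate_coverage(bam_path)
        logger.info("estimated coverage: %.1fx", coverage)
    exclude = _read_exclude_bed(exclude_bed) if exclude_bed else {}

    results: Dict[str, ChromosomeResult] = {}
    assignments_all: Dict[str, Tuple[int, int]] = {}
    flip_keys: Set[Tuple[str, int]] = set()
    merged_all: Dict[Tuple[str, int], int] = {}
    spans_all: Dict[Tuple[str, int], Tuple[int, int]] = {}
    any_hp = any_mods = False

    for chrom in targets:
        reads = list(read_methylation_records(bam_path, chrom, decode_config))
        any_hp = any_hp or any(r.haplotype is not None for r in reads)
        any_mods = any_mods or any(r.meth_calls for r in reads)
        res = phase_chromosome(
            reads, blocks_by_chrom[chrom], asm_config, voting_config, preset,
            coverage=coverage, genome_block_count=genome_block_count,
            skip_largest=skip_largest, exclude_regions=exclude.get(chrom))
        results[chrom] = res
        for rid, (bid, hap) in res.assignments.items():
            assignments_all[rid] = (bid, hap)
        flip_keys |= {(chrom, bid) for bid in res.flip_set}
        merged_all.update({(chrom, bid): cid
                           for bid, cid in res.merged_map.items()})
        spans_all.update({(chrom, e.block_id): (e.ext_start, e.ext_end)
                          for e in res.extended_blocks})

    if not any_hp:
        raise ValueError("no HP tags found: SNV-based haplotagging is a "
                         "prerequisite")
    if not any_mods:
        raise ValueError("no MM/ML modification tags found in the BAM")

    bam_counts = write_retagged_bam(bam_path, assignments_all, flip_keys,
                                    merged_all, out_prefix + ".bam",
                                    block_spans=spans_all)
    vcf_counts = write_rephased_vcf(vcf_path, flip_keys, merged_all,
                                    out_prefix + ".vcf")

    for chrom, res in results.items():
        relationships_to_table(res.relationships).to_csv(
            f"{out_prefix}.{chrom}.relationships.csv", index=False)
        import pandas as pd
        tables = [assignments_to_table(bid, t)
                  for bid, t in res.block_tallies.items() if t]
        table = pd.concat(tables) if tables else assignments_to_table(0, {})
        table.to_csv(f"{out_prefix}.{chrom}.assignments.csv", index=False)

    before = {c: results[c].blocks for c in results}
    after = {c: results[c].blocks_after() for c in results}
    summary = {
        "chromosomes": targets,
        "blocks_before": sum(len(b) for b in before.values()),
        "blocks_after": sum(len(b) for b in after.values()),
        "connections": sum(r.n_connections for r in results.values()),
        "flipped_blocks": sorted(f"{c}:{b}" for c, b in flip_keys),
        "reads_newly_tagged": len(assignments_all),
        "coverage_used": coverage,
        **gap_stats(before, after),
        "bam_counts": bam_counts,
        "vcf_counts": vcf_counts,
    }
    with open(out_prefix + ".summary.json", "w") as fh:
        json.dump(summary, fh, indent=2)
    return summary


def run_eval(
    test_vcf: str,
    truth_vcf: str,
    baseline_vcf: Optional[str] = None,
    relationships_csvs: Optional[Sequence[str]] = None,
    out_path: Optional[str] = None,
) -> dict:
    """Benchmark a phased VCF against a truth-phased VCF.

    With a baseline (pre-bridging) VCF the report adds gap statistics and,
    when relationship CSVs are supplied, the newly introduced switches per
    block connection.
    """
    test_vars, test_blocks = read_phased_vcf(test_vcf)
    truth_vars, _ = read_phased_vcf(truth_vcf)
    if not set(test_vars) & set(truth_vars):
        raise ValueError("test and truth VCFs share no chromosome")

    cmp_after = compare_phasing(flat_variants(test_vars),
                                flat_variants(truth_vars))
    lengths = [b.end - b.start + 1 for bs in test_blocks.values() for b in bs]
    report = {
        "n50": nx(lengths, 50),
        "nx_curve": {f"N{x}": nx(lengths, x) for x in range(10, 100, 10)},
        "blocks": sum(len(b) for b in test_blocks.values()),
        "switch_errors": cmp_after.switch_count,
        "flip_errors": cmp_after.flip_count,
        "hamming_distance": cmp_after.hamming_distance,
        "switch_rate": cmp_after.switch_rate,
        "flip_rate": cmp_after.flip_rate,
        "assessed_variants": cmp_after.assessed_variant_count,
        "blocks_skipped_in_comparison": cmp_after.blocks_skipped,
    }
    if baseline_vcf:
        base_vars, base_blocks = read_phased_vcf(baseline_vcf)
        cmp_before = compare_phasing(flat_variants(base_vars),
                                     flat_variants(truth_vars))
        base_lengths = [b.end - b.start + 1
                        for bs in base_blocks.values() for b in bs]
        report["baseline_n50"] = nx(base_lengths, 50)
        report["baseline_switch_errors"] = cmp_before.switch_count
        report.update(gap_stats(base_blocks, test_blocks))
        if relationships_csvs:
            import pandas as pd
            n_connections = 0
            for path in relationships_csvs:
                df = pd.read_csv(path)
                n_connections += int((df["verdict"] != "UNKNOWN").sum())
            report["connections"] = n_connections
            spc = switches_per_connection(cmp_before, cmp_after, n_connections)
            report["switches_per_connection"] = spc if spc is not None else "NA"
    if out_path:
        with open(out_path, "w") as fh:
            json.dump(report, fh, indent=2)
    return report
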