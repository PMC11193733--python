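"""Synthetic diploid datasets with known haplotypes, ASM sites and block structure.

The generator emulates the signal structure the phasing method relies on:
a diploid chromosome carved into SNV phase blocks separated by homozygous
gaps; long reads drawn from one haplotype each; per-read CpG modification
probabilities drawn from haplotype-specific Beta distributions at planted
ASM sites and from a shared distribution elsewhere; a subset of reads
pre-tagged by "SNV phasing" with each block's planted orientation; and an
optional fraction of methylation-scrambled reads modelling tissue
heterogeneity.  Every random draw comes from one NumPy generator seeded
from the configuration, so outputs are reproducible byte for byte.
"""
from __future__ import annotations

import math
import os
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pysam

from .bam_io import encode_prob
from .records import (ExtendedBlock, PhaseBlock, PhasedVariant, ReadMethRecord,
                      Verdict)
from .vcf_io import write_variants_vcf

BASES = np.frombuffer(b"ACGT", dtype="S1")


@dataclass
class SimulationConfig:
    """Study conditions for one simulated chromosome.

    Defaults model a desk-scale analogue of a long-read methylation run:
    ~10 kb reads at 25x coverage, heterozygous SNVs every ~1 kb inside
    blocks, CpGs every 150 bp, half of them allele-specific with strongly
    separated Beta(8,2) / Beta(2,8) score distributions.  Gaps default to
    roughly half a read length so that every gap is crossed by enough
    informative reads to be bridged at the default filtering level.
    """

    seed: int = 0
    chrom: str = "chr1"
    n_blocks: int = 10
    block_length: int = 12_000
    gap_length_mean: float = 4_500
    gap_length_sd: float = 700
    het_spacing: int = 1_000
    cpg_spacing: int = 150
    asm_fraction: float = 0.5
    asm_high: Tuple[float, float] = (8.0, 2.0)
    asm_low: Tuple[float, float] = (2.0, 8.0)
    shared_beta: Tuple[float, float] = (5.0, 5.0)
    read_length_mean: float = 10_000
    read_length_sigma: float = 0.3
    coverage: float = 25.0
    snv_tag_fraction: float = 0.8
    scramble_fraction: float = 0.0
    relationships: Optional[Sequence[str]] = None   # "SAME"/"SWITCH" per gap

    def __post_init__(self):
        for name in ("asm_fraction", "snv_tag_fraction", "scramble_fraction"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.relationships is not None \
                and len(self.relationships) != self.n_blocks - 1:
            raise ValueError("need one relationship per gap "
                             f"({self.n_blocks - 1}), got "
                             f"{len(self.relationships)}")


@dataclass
class TruthSet:
    """Ground truth emitted alongside a simulated dataset."""

    chrom: str
    chrom_length: int
    read_haplotypes: Dict[str, int] = field(default_factory=dict)
    scrambled_reads: set = field(default_factory=set)
    cpg_sites: List[dict] = field(default_factory=list)      # pos0, is_asm, high_hap
    block_orientations: Dict[int, int] = field(default_factory=dict)
    gap_relationships: Dict[Tuple[int, int], Verdict] = field(default_factory=dict)
    truth_variants: List[PhasedVariant] = field(default_factory=list)

    @property
    def asm_positions(self) -> List[int]:
        return [s["pos"] for s in self.cpg_sites if s["is_asm"]]


@dataclass
class SimulatedChromosome:
    config: SimulationConfig
    reads: List[ReadMethRecord]
    blocks: List[PhaseBlock]
    test_variants: List[PhasedVariant]
    truth: TruthSet
    reference: bytes                      # for BAM emission
    read_seqs: Dict[str, str] = field(default_factory=dict)


def _draw_beta(rng: np.random.Generator, ab: Tuple[float, float]) -> float:
    return float(rng.beta(*ab))


def simulate_chromosome(config: SimulationConfig) -> SimulatedChromosome:
    """Generate one chromosome's reads, blocks, variants and truth in memory."""
    rng = np.random.default_rng(config.seed)
    chrom = config.chrom

    # --- block / gap geometry (0-based region bounds) -----------------------
    gap_lengths = [
        max(1_000, int(rng.normal(config.gap_length_mean, config.gap_length_sd)))
        for _ in range(config.n_blocks - 1)
    ]
    region_starts = [0]
    for g in gap_lengths:
        region_starts.append(region_starts[-1] + config.block_length + g)
    chrom_length = region_starts[-1] + config.block_length + 500

    # --- heterozygous SNVs inside blocks ------------------------------------
    het_pos0: List[List[int]] = []
    for rs in region_starts:
        positions = list(range(rs + 500, rs + config.block_length - 400,
                               config.het_spacing))
        het_pos0.append(positions)
    het_all = {p for ps in het_pos0 for p in ps}

    # --- CpG sites -----------------------------------------------------------
    cpg_pos0 = [p for p in range(100, chrom_length - 2, config.cpg_spacing)
                if not any(abs(p - h) <= 2 for h in het_all)]
    is_asm = rng.random(len(cpg_pos0)) < config.asm_fraction
    high_hap = rng.integers(1, 3, size=len(cpg_pos0))
    site_index = {p: i for i, p in enumerate(cpg_pos0)}

    # --- planted orientations / gap relationships ---------------------------
    if config.relationships is None:
        rels = [Verdict.SAME if rng.random() < 0.5 else Verdict.SWITCH
                for _ in range(config.n_blocks - 1)]
    else:
        rels = [Verdict(r) for r in config.relationships]
    orientations = [0]
    for r in rels:
        orientations.append(orientations[-1] ^ (r is Verdict.SWITCH))

    # --- variant tables ------------------------------------------------------
    blocks: List[PhaseBlock] = []
    test_variants: List[PhasedVariant] = []
    truth_variants: List[PhasedVariant] = []
    truth_pairs: Dict[int, Tuple[int, int]] = {}   # het pos0 -> truth genotype
    block_of_het: Dict[int, int] = {}
    block_ids: List[int] = []
    for i, positions in enumerate(het_pos0):
        block_id = positions[0] + 1            # PS = 1-based first-het position
        block_ids.append(block_id)
        blocks.append(PhaseBlock(block_id=block_id, chrom=chrom,
                                 start=positions[0] + 1, end=positions[-1] + 1,
                                 variant_count=len(positions)))
        for p in positions:
            a = int(rng.integers(0, 2))
            truth = (a, 1 - a)
            truth_pairs[p] = truth
            block_of_het[p] = block_id
            test_gt = truth if orientations[i] == 0 else truth[::-1]
            truth_variants.append(PhasedVariant(
                chrom=chrom, pos=p + 1, ref="A", alts=("G",),
                genotype=truth, phased=True, phase_set=1))
            test_variants.append(PhasedVariant(
                chrom=chrom, pos=p + 1, ref="A", alts=("G",),
                genotype=test_gt, phased=True, phase_set=block_id))
        # two unphased homozygous variants per block, for parser realism
        for p in (positions[0] + 250, positions[-1] + 151):
            if p not in het_all and p not in site_index:
                test_variants.append(PhasedVariant(
                    chrom=chrom, pos=p + 1, ref="T", alts=("C",),
                    genotype=(1, 1), phased=False, phase_set=None))

    # --- reference sequence --------------------------------------------------
    ref = rng.integers(0, 4, size=chrom_length)
    ref_bytes = BASES[ref].copy()
    for p in cpg_pos0:
        ref_bytes[p] = b"C"
        ref_bytes[p + 1] = b"G"
    for p in het_all:
        ref_bytes[p] = b"A"
    reference = ref_bytes.tobytes()

    # --- reads ---------------------------------------------------------------
    n_reads = int(math.ceil(config.coverage * chrom_length
                            / config.read_length_mean))
    mu = math.log(config.read_length_mean) - config.read_length_sigma ** 2 / 2
    reads: List[ReadMethRecord] = []
    read_seqs: Dict[str, str] = {}
    truth = TruthSet(chrom=chrom, chrom_length=chrom_length)
    truth.block_orientations = dict(zip(block_ids, orientations))
    truth.gap_relationships = {
        (block_ids[i], block_ids[i + 1]): rels[i]
        for i in range(config.n_blocks - 1)
    }
    truth.truth_variants = truth_variants
    truth.cpg_sites = [
        {"pos": p, "is_asm": bool(is_asm[i]), "high_hap": int(high_hap[i])}
        for p, i in site_index.items()
    ]

    half = int(config.read_length_mean)
    for k in range(n_reads):
        length = max(500, int(rng.lognormal(mu, config.read_length_sigma)))
        start = int(rng.integers(-half + 500, chrom_length - 500))
        end = min(chrom_length, start + length)
        start = max(0, start)
        if end - start < 500:
            continue
        read_id = f"read_{k:05d}"
        hap = int(rng.integers(1, 3))
        scrambled = rng.random() < config.scramble_fraction
        meth_hap = int(rng.integers(1, 3)) if scrambled else hap

        calls = []
        lo = 100 + ((start - 100) // config.cpg_spacing + 1) * config.cpg_spacing \
            if start > 100 else 100
        for p in range(lo, end - 1, config.cpg_spacing):
            i = site_index.get(p)
            if i is None:
                continue
            if is_asm[i]:
                ab = config.asm_high if meth_hap == high_hap[i] else config.asm_low
            else:
                ab = config.shared_beta
            calls.append((p, _draw_beta(rng, ab)))

        # SNV tagging: majority block among overlapped hets, >=2 hets needed
        overlaps: Dict[int, int] = {}
        for p, bid in block_of_het.items():
            if start <= p < end:
                overlaps[bid] = overlaps.get(bid, 0) + 1
        hp = ps = None
        if overlaps:
            best = max(sorted(overlaps), key=lambda b: overlaps[b])
            if overlaps[best] >= 2 and rng.random() < config.snv_tag_fraction:
                o = truth.block_orientations[best]
                hp = hap if o == 0 else 3 - hap
                ps = best

        reads.append(ReadMethRecord(
            read_id=read_id, chrom=chrom, ref_start=start, ref_end=end,
            haplotype=hp, phase_set=ps, meth_calls=calls))
        truth.read_haplotypes[read_id] = hap
        if scrambled:
            truth.scrambled_reads.add(read_id)

        seq = bytearray(reference[start:end])
        for p, bid in block_of_het.items():
            if start <= p < end and truth_pairs[p][hap - 1] == 1:
                seq[p - start] = ord("G")
        read_seqs[read_id] = seq.decode()

    reads.sort(key=lambda r: (r.ref_start, r.read_id))
    return SimulatedChromosome(config=config, reads=reads, blocks=blocks,
                               test_variants=test_variants, truth=truth,
                               reference=reference, read_seqs=read_seqs)


# ---------------------------------------------------------------------------
# file emission
# ---------------------------------------------------------------------------

def _mm_ml_tags(seq: str, calls: List[Tuple[int, float]], start: int):
    """Build MM/ML tag values for forward-strand 5mC calls on one read."""
    c_positions = [i for i, ch in enumerate(seq) if ch == "C"]
    c_rank = {p: r for r, p in enumerate(c_positions)}
    skips, ml = [], []
    prev_rank = -1
    for ref_pos, prob in calls:
        qpos = ref_pos - start
        rank = c_rank[qpos]            # planted CpG C is always in the read
        skips.append(rank - prev_rank - 1)
        prev_rank = rank
        ml.append(encode_prob(prob))
    mm = "C+m?," + ",".join(map(str, skips)) + ";" if skips else "C+m?;"
    return mm, ml


def write_dataset_bam(sim: SimulatedChromosome, bam_path: str) -> str:
    """Emit the simulated reads as a coordinate-sorted, indexed BAM."""
    header = {"HD": {"VN": "1.6", "SO": "coordinate"},
              "SQ": [{"SN": sim.truth.chrom, "LN": sim.truth.chrom_length}],
              "PG": [{"ID": "methbridge-simulate", "PN": "methbridge",
                      "CL": f"seed={sim.config.seed}"}]}
    with pysam.AlignmentFile(bam_path, "wb", header=header) as out:
        for read in sim.reads:
            seq = sim.read_seqs[read.read_id]
            aln = pysam.AlignedSegment(out.header)
            aln.query_name = read.read_id
            aln.query_sequence = seq
            aln.flag = 0
            aln.reference_id = 0
            aln.reference_start = read.ref_start
            aln.mapping_quality = 60
            aln.cigartuples = [(0, len(seq))]
            mm, ml = _mm_ml_tags(seq, read.meth_calls, read.ref_start)
            aln.set_tag("MM", mm)
            from array import array
            aln.set_tag("ML", array("B", ml))
            if read.haplotype is not None:
                aln.set_tag("HP", read.haplotype)
                aln.set_tag("PS", read.phase_set)
            out.write(aln)
    pysam.index(bam_path)
    return bam_path


def write_truth_tables(sim: SimulatedChromosome, prefix: str) -> Dict[str, str]:
    """Emit the truth set as plain TSV files (and the truth-phased VCF)."""
    import pandas as pd

    paths = {}
    t = sim.truth
    reads_df = pd.DataFrame({
        "read_id": list(t.read_haplotypes),
        "haplotype": [t.read_haplotypes[r] for r in t.read_haplotypes],
        "scrambled": [r in t.scrambled_reads for r in t.read_haplotypes],
    })
    paths["truth_reads"] = f"{prefix}.truth_reads.tsv"
    reads_df.to_csv(paths["truth_reads"], sep="\t", index=False)

    sites_df = pd.DataFrame(t.cpg_sites)
    sites_df["pos_1based"] = sites_df["pos"] + 1
    paths["truth_sites"] = f"{prefix}.truth_sites.tsv"
    sites_df.to_csv(paths["truth_sites"], sep="\t", index=False)

    rel_df = pd.DataFrame([
        {"left_block": l, "right_block": r, "relationship": v.value}
        for (l, r), v in t.gap_relationships.items()
    ])
    paths["truth_relationships"] = f"{prefix}.truth_relationships.tsv"
    rel_df.to_csv(paths["truth_relationships"], sep="\t", index=False)

    paths["truth_vcf"] = f"{prefix}.truth.vcf"
    write_variants_vcf(paths["truth_vcf"], {t.chrom: t.truth_variants},
                       {t.chrom: t.chrom_length})
    return paths


def simulate_dataset(config: SimulationConfig, out_dir: str,
                     prefix: str = "sim") -> Tuple[Dict[str, str], SimulatedChromosome]:
    """Generate and write a full dataset; returns (paths, simulated data)."""
    os.makedirs(out_dir, exist_ok=True)
    sim = simulate_chromosome(config)
    base = os.path.join(out_dir, prefix)
    paths = {"bam": write_dataset_bam(sim, base + ".bam"),
             "vcf": write_variants_vcf(
                 base + ".vcf", {sim.truth.chrom: sim.test_variants},
                 {sim.truth.chrom: sim.truth.chrom_length})}
    paths.update(write_truth_tables(sim, base))
    return paths, sim


def make_fixture_suite(out_dir: str) -> Dict[str, Dict[str, str]]:
    """Emit the small named fixtures used by the unit tests."""
    suite = {
        "two_block": SimulationConfig(seed=11, n_blocks=2, block_length=8_000),
        "three_block": SimulationConfig(seed=12, n_blocks=3,
                                        block_length=8_000),
        "tie_gap": SimulationConfig(seed=13, n_blocks=3, block_length=8_000,
                                    gap_length_sd=0),
        "zero_asm": SimulationConfig(seed=14, n_blocks=3, block_length=8_000,
                                     asm_fraction=0.0),
        "scrambled_30": SimulationConfig(seed=15, n_blocks=3, block_length=8_000,
                                         scramble_fraction=0.3),
    }
    out = {}
    for name, cfg in suite.items():
        paths, _ = simulate_dataset(cfg, out_dir, prefix=name)
        out[name] = paths
    return out


# ---------------------------------------------------------------------------
# in-memory helpers for focused tests
# ---------------------------------------------------------------------------

def simulate_block(
    seed: int,
    n_asm_sites: int = 30,
    asm_spacing: int = 1_500,
    coverage: float = 20.0,
    read_length_mean: float = 8_000,
    read_length_sigma: float = 0.25,
    snv_tag_fraction: float = 0.8,
    asm_high: Tuple[float, float] = (8.0, 2.0),
    asm_low: Tuple[float, float] = (2.0, 8.0),
    shared_beta: Tuple[float, float] = (5.0, 5.0),
    scramble_fraction: float = 0.0,
):
    """One extended block with planted ASM sites, for read-voting tests.

    Returns ``(reads, extended_block, truth_haps, asm_positions)``: a
    fraction of reads is pre-tagged with its true haplotype (standing in
    for SNV haplotagging), the rest is untagged.
    """
    rng = np.random.default_rng(seed)
    length = asm_spacing * (n_asm_sites + 1)
    asm_positions = [asm_spacing * (i + 1) for i in range(n_asm_sites)]
    shared_positions = [p + asm_spacing // 2 for p in [0] + asm_positions]
    sites = sorted([(p, True) for p in asm_positions]
                   + [(p, False) for p in shared_positions])
    high_hap = {p: int(rng.integers(1, 3)) for p in asm_positions}

    block = PhaseBlock(block_id=1, chrom="sim", start=1, end=length)
    ext = ExtendedBlock(block_id=1, chrom="sim", ext_start=1, ext_end=length,
                        parent=block)

    n_reads = int(math.ceil(coverage * length / read_length_mean))
    mu = math.log(read_length_mean) - read_length_sigma ** 2 / 2
    reads, truth_haps = [], {}
    for k in range(n_reads):
        rl = max(500, int(rng.lognormal(mu, read_length_sigma)))
        start = int(rng.integers(-int(read_length_mean) + 500, length - 500))
        end = min(length, start + rl)
        start = max(0, start)
        if end - start < 500:
            continue
        hap = int(rng.integers(1, 3))
        meth_hap = int(rng.integers(1, 3)) \
            if rng.random() < scramble_fraction else hap
        calls = []
        for p, asm in sites:
            if start <= p < end:
                if asm:
                    ab = asm_high if meth_hap == high_hap[p] else asm_low
                else:
                    ab = shared_beta
                calls.append((p, _draw_beta(rng, ab)))
        tagged = rng.random() < snv_tag_fraction
        read_id = f"blk_read_{k:05d}"
        reads.append(ReadMethRecord(
            read_id=read_id, chrom="sim", ref_start=start, ref_end=end,
            haplotype=hap if tagged else None,
            phase_set=1 if tagged else None, meth_calls=calls))
        truth_haps[read_id] = hap
    return reads, ext, truth_haps, asm_positions


def build_iteration_fixture():
    """A hand-built block where one read is only assignable in iteration 2.

    Sites S1-S3 are covered by the SNV-tagged reads (four per haplotype)
    and by eight untagged reads, which therefore get three votes each and
    are assigned in iteration 1.  Sites S4-S6 are covered only by those
    untagged reads plus one further read, so they only become testable —
    and that read assignable — once iteration 1 has committed its
    assignments.
    """
    s = [1_000, 2_000, 3_000, 11_000, 12_000, 13_000]
    block = PhaseBlock(block_id=1, chrom="fix", start=1, end=14_000)
    ext = ExtendedBlock(block_id=1, chrom="fix", ext_start=1, ext_end=14_000,
                        parent=block)

    def probs(hap, offset):
        base = 0.90 if hap == 1 else 0.10
        return base - offset * 0.007

    reads = []
    for j in range(4):                      # SNV-tagged seeds, sites S1-S3 only
        for hap in (1, 2):
            reads.append(ReadMethRecord(
                read_id=f"tag_h{hap}_{j}", chrom="fix",
                ref_start=500, ref_end=3_500, haplotype=hap, phase_set=1,
                meth_calls=[(p, probs(hap, j) + i * 1e-4)
                            for i, p in enumerate(s[:3])]))
    for j in range(4):                      # untagged, spanning S1-S6
        for hap in (1, 2):
            reads.append(ReadMethRecord(
                read_id=f"unt_h{hap}_{j}", chrom="fix",
                ref_start=500, ref_end=13_500, haplotype=None, phase_set=None,
                meth_calls=[(p, probs(hap, j) + 0.004 + i * 1e-4)
                            for i, p in enumerate(s)]))
    late = ReadMethRecord(                  # assignable only in iteration 2
        read_id="late_read", chrom="fix", ref_start=10_500, ref_end=13_500,
        haplotype=None, phase_set=None,
        meth_calls=[(p, probs(1, 1) + 0.002 + i * 1e-4)
                    for i, p in enumerate(s[3:])])
    reads.append(late)
    truth = {"late_read": 1}
    return reads, ext, truth
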