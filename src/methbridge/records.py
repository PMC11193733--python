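"""Core domain records shared across the pipeline.

Coordinate conventions
----------------------
Reads and CpG positions live in BAM space: 0-based, half-open intervals,
with each CpG identified by the 0-based position of its forward-strand
cytosine.  Variants and phase blocks live in VCF space: 1-based, inclusive.
Conversion happens only at I/O boundaries and at the few places where read
intervals are intersected with block intervals.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Optional

H1 = 1
H2 = 2

#: Maps haplotype 1 <-> 2.
def other_hap(hap: int) -> int:
    return 3 - hap


@dataclass(slots=True)
class ReadMethRecord:
    """One aligned read with its per-CpG 5mC modification probabilities.

    ``meth_calls`` is a list of ``(ref_pos, prob)`` pairs sorted by the
    0-based reference position of the CpG cytosine; ``prob`` is the
    modification probability in [0, 1].  ``haplotype`` is ``None`` when the
    read carries no HP tag.
    """

    read_id: str
    chrom: str
    ref_start: int
    ref_end: int
    haplotype: Optional[int] = None
    phase_set: Optional[int] = None
    meth_calls: list = field(default_factory=list)
    mapq: int = 60

    def call_map(self) -> dict:
        return dict(self.meth_calls)


@dataclass(slots=True)
class ModificationDecodeConfig:
    """How modification tags are decoded into probabilities."""

    mod_code: str = "m"          # 5mC
    canonical_base: str = "C"
    min_mapq: int = 10
    include_supplementary: bool = False
    merge_strands: bool = True   # fold reverse-strand CpG calls onto the forward C


@dataclass(slots=True)
class PhasedVariant:
    """A VCF record reduced to its phasing content (1-based position)."""

    chrom: str
    pos: int
    ref: str
    alts: tuple
    genotype: tuple              # (hap1_allele, hap2_allele)
    phased: bool
    phase_set: Optional[int] = None

    @property
    def is_het(self) -> bool:
        return self.genotype[0] != self.genotype[1]


@dataclass(slots=True)
class PhaseBlock:
    """An SNV phase block: the span of its phased heterozygous variants."""

    block_id: int
    chrom: str
    start: int                   # 1-based position of first phased het
    end: int                     # 1-based position of last phased het
    variant_count: int = 0


@dataclass(slots=True)
class ExtendedBlock:
    """A phase block widened into both adjacent homozygous gaps.

    Neighbouring extended blocks overlap exactly on the inter-block gap, so
    a read assigned in both can vote on the blocks' relative orientation.
    """

    block_id: int
    chrom: str
    ext_start: int               # 1-based inclusive
    ext_end: int
    parent: PhaseBlock = None

    def overlaps_read(self, read: ReadMethRecord) -> bool:
        # block as 0-based half-open: [ext_start-1, ext_end)
        return read.ref_start < self.ext_end and read.ref_end > self.ext_start - 1

    def contains_pos0(self, pos: int) -> bool:
        return self.ext_start - 1 <= pos < self.ext_end


@dataclass(slots=True)
class BlockGap:
    left_block_id: int
    right_block_id: int
    gap_start: int               # = end of left block (1-based)
    gap_end: int                 # = start of right block
    skipped: bool = False

    @property
    def length(self) -> int:
        return self.gap_end - self.gap_start


@dataclass(slots=True)
class CpGSiteProfile:
    """Haplotype-partitioned methylation scores at one CpG site.

    ``pos`` is the 0-based forward-strand cytosine position; exports convert
    to 1-based.  ``is_asm`` is set only when the site passed the rank-sum
    test at the configured level with enough scores on both haplotypes.
    """

    chrom: str
    pos: int
    h1_scores: list = field(default_factory=list)
    h2_scores: list = field(default_factory=list)
    h1_median: Optional[float] = None
    h2_median: Optional[float] = None
    p_value: Optional[float] = None
    is_asm: bool = False

    @property
    def n1(self) -> int:
        return len(self.h1_scores)

    @property
    def n2(self) -> int:
        return len(self.h2_scores)


@dataclass(slots=True)
class AsmConfig:
    """Thresholds for calling a CpG site haplotype-specific."""

    alpha: float = 0.05
    min_scores_per_hap: int = 2   # floor for the rank-sum test
    merge_strands: bool = True

    def __post_init__(self):
        if self.min_scores_per_hap < 2:
            raise ValueError("min_scores_per_hap must be >= 2")


@dataclass(slots=True)
class VotingConfig:
    """Thresholds for methylation-based read haplotagging."""

    min_votes: int = 3
    min_cov_per_hap: int = 3
    max_iterations: int = 10

    def __post_init__(self):
        if min(self.min_votes, self.min_cov_per_hap, self.max_iterations) < 1:
            raise ValueError("voting thresholds must all be >= 1")


@dataclass(slots=True)
class VoteTally:
    read_id: str
    votes_h1: int = 0
    votes_h2: int = 0
    abstentions: int = 0
    assignment: Optional[int] = None     # H1, H2 or None
    iteration_assigned: Optional[int] = None


class Verdict(str, Enum):
    SAME = "SAME"
    SWITCH = "SWITCH"
    UNKNOWN = "UNKNOWN"


@dataclass(slots=True)
class BlockRelationship:
    left_block_id: int
    right_block_id: int
    same_votes: int = 0
    switch_votes: int = 0
    verdict: Verdict = Verdict.UNKNOWN

    @property
    def total_votes(self) -> int:
        return self.same_votes + self.switch_votes

    @property
    def confidence(self) -> float:
        if self.total_votes == 0:
            return 0.0
        return abs(self.same_votes - self.switch_votes) / self.total_votes


@dataclass(slots=True)
class FilterPreset:
    """Relationship-call filtering: ``accuracy`` (default) or ``success``.

    In accuracy mode the minimum supporting-read count defaults to
    ``coverage / (genome-wide block count / 1000)`` and the vote confidence
    must exceed 0.5; success mode imposes no limits.
    """

    mode: str = "accuracy"
    min_reads: Optional[int] = None      # explicit override of the formula
    min_confidence: Optional[float] = None

    def resolve(self, coverage: Optional[float] = None,
                block_count: Optional[int] = None) -> tuple:
        """Return effective (min_reads, min_confidence)."""
        import math
        if self.mode == "success":
            return (self.min_reads or 1,
                    0.0 if self.min_confidence is None else self.min_confidence)
        if self.mode != "accuracy":
            raise ValueError(f"unknown filter mode {self.mode!r}")
        conf = 0.5 if self.min_confidence is None else self.min_confidence
        if self.min_reads is not None:
            return max(1, int(self.min_reads)), conf
        if coverage is None or block_count is None or coverage <= 0 or block_count <= 0:
            raise ValueError(
                "accuracy mode needs positive coverage and block_count "
                "to resolve min_reads (or an explicit min_reads)")
        return max(1, math.ceil(coverage / (block_count / 1000))), conf


@dataclass(slots=True)
class BlockChain:
    """Blocks merged into one super-block, with per-member orientation."""

    member_ids: list                      # ordered block ids
    flips: list                           # parallel bools; True = flip member

    @property
    def chain_id(self) -> int:
        return self.member_ids[0]
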