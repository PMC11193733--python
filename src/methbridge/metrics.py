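"""Phasing-evaluation metrics: Nx, switch/flip errors, hamming distance.

The comparison follows the read-backed-phasing conventions: within each
test phase block the shared phased heterozygous variants are compared with
the truth under the orientation that minimises mismatches.  In the
resulting mismatch vector an isolated wrong variant (flanked by matches)
counts as one flip, every remaining orientation change counts as one
switch, and the per-block hamming contribution is
``min(mismatches, n - mismatches)``.  Rates are normalised by the number
of assessable adjacent phased pairs.
"""
from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

from .records import PhaseBlock, PhasedVariant, Verdict


def nx(block_lengths: Sequence[float], x: float = 50) -> float:
    """Nx statistic of a set of phase-block lengths.

    The minimum block length such that blocks at least that long cover
    >= x% of the total phased length.
    """
    if not 0 < x < 100:
        raise ValueError("x must be in (0, 100)")
    lengths = sorted(block_lengths, reverse=True)
    if not lengths:
        raise ValueError("nx of an empty length list is undefined")
    threshold = sum(lengths) * x / 100.0
    acc = 0.0
    for length in lengths:
        acc += length
        if acc >= threshold:
            return length
    return lengths[-1]  # unreachable with exact arithmetic


def _index_truth(truth_variants: Iterable[PhasedVariant]) -> Dict[tuple, PhasedVariant]:
    return {(v.chrom, v.pos): v for v in truth_variants
            if v.phased and v.is_het}


def _orientation(test: PhasedVariant, truth: PhasedVariant) -> Optional[int]:
    """0 = same order as truth, 1 = inverted, None = alleles disagree."""
    if test.genotype == truth.genotype:
        return 0
    if test.genotype == truth.genotype[::-1]:
        return 1
    return None


def block_orientation_vs_truth(
    block_variants: Sequence[PhasedVariant],
    truth_index: Dict[tuple, PhasedVariant],
) -> Optional[int]:
    """Majority orientation of a block against the truth set.

    Returns 0 (same), 1 (inverted) or None when there are no shared phased
    hets or the orientations split exactly 50/50.
    """
    same = inverted = 0
    for v in block_variants:
        t = truth_index.get((v.chrom, v.pos))
        if t is None or not (v.phased and v.is_het):
            continue
        o = _orientation(v, t)
        if o == 0:
            same += 1
        elif o == 1:
            inverted += 1
    if same == inverted:
        return None
    return 0 if same > inverted else 1


def truth_relationship(
    left_variants: Sequence[PhasedVariant],
    right_variants: Sequence[PhasedVariant],
    truth_variants: Iterable[PhasedVariant],
) -> Verdict:
    """True relationship of two neighbouring blocks via a truth-phased set.

    Each block's haplotype order is compared with the truth; if both blocks
    relate to the truth the same way the relationship is SAME, otherwise
    SWITCH.  UNKNOWN when either block's orientation is undetermined.
    """
    truth_index = _index_truth(truth_variants)
    left = block_orientation_vs_truth(left_variants, truth_index)
    right = block_orientation_vs_truth(right_variants, truth_index)
    if left is None or right is None:
        return Verdict.UNKNOWN
    return Verdict.SAME if left == right else Verdict.SWITCH


def switch_flip_decomposition(mismatch_vector: Sequence[int]) -> Tuple[int, int]:
    """Decompose a 0/1 mismatch vector into (switches, flips).

    Orientation changes are the boundaries between a match run and a
    mismatch run; two changes at adjacent boundaries (an isolated single
    mismatch) collapse into one flip, every remaining change is a switch,
    so ``2*flips + switches`` equals the orientation-change count exactly.
    """
    changes = [i for i in range(len(mismatch_vector) - 1)
               if mismatch_vector[i] != mismatch_vector[i + 1]]
    switches = flips = 0
    i = 0
    while i < len(changes):
        if i + 1 < len(changes) and changes[i + 1] == changes[i] + 1:
            flips += 1
            i += 2
        else:
            switches += 1
            i += 1
    return switches, flips


@dataclass
class PhasingComparison:
    """Switch/flip/hamming comparison of a test phasing against a truth."""

    switch_count: int = 0
    flip_count: int = 0
    hamming_distance: int = 0
    assessed_variant_count: int = 0
    assessable_pairs: int = 0
    blocks_compared: int = 0
    blocks_skipped: int = 0
    per_block_vectors: dict = field(default_factory=dict)
    undefined: bool = False

    @property
    def switch_rate(self) -> Optional[float]:
        return None if self.assessable_pairs == 0 \
            else self.switch_count / self.assessable_pairs

    @property
    def flip_rate(self) -> Optional[float]:
        return None if self.assessable_pairs == 0 \
            else self.flip_count / self.assessable_pairs


def compare_phasing(
    test_variants: Iterable[PhasedVariant],
    truth_variants: Iterable[PhasedVariant],
) -> PhasingComparison:
    """Compare two phased variant sets block by block.

    Blocks are the test set's phase sets; comparison is restricted to
    phased heterozygous variants shared (same chrom/pos, compatible
    alleles) with the truth.  Per block the truth orientation minimising
    mismatches is chosen; mismatches below half stay, above half the
    vector is inverted, exact ties keep the uninverted vector.
    """
    truth_index = _index_truth(truth_variants)
    by_block: Dict[tuple, List[PhasedVariant]] = defaultdict(list)
    for v in test_variants:
        if v.phased and v.is_het and v.phase_set is not None:
            by_block[(v.chrom, v.phase_set)].append(v)

    cmp = PhasingComparison()
    for key in sorted(by_block):
        variants = sorted(by_block[key], key=lambda v: v.pos)
        vector = []
        for v in variants:
            t = truth_index.get((v.chrom, v.pos))
            if t is None:
                continue
            o = _orientation(v, t)
            if o is not None:
                vector.append(o)
        if not vector:
            cmp.blocks_skipped += 1
            continue
        n = len(vector)
        mismatches = sum(vector)
        if mismatches > n - mismatches:
            vector = [1 - b for b in vector]
            mismatches = n - mismatches
        switches, flips = switch_flip_decomposition(vector)
        cmp.switch_count += switches
        cmp.flip_count += flips
        cmp.hamming_distance += mismatches
        cmp.assessed_variant_count += n
        cmp.assessable_pairs += n - 1
        cmp.blocks_compared += 1
        cmp.per_block_vectors[key] = vector
    cmp.undefined = cmp.assessed_variant_count == 0
    return cmp


def switches_per_connection(
    comparison_before: PhasingComparison,
    comparison_after: PhasingComparison,
    n_connections: int,
) -> Optional[float]:
    """Newly introduced switch errors per phase-block connection made.

    Undefined (None) when no connections were made.
    """
    if n_connections == 0:
        return None
    return (comparison_after.switch_count - comparison_before.switch_count) \
        / n_connections


def gap_stats(
    blocks_before: Dict[str, Sequence[PhaseBlock]],
    blocks_after: Dict[str, Sequence[PhaseBlock]],
) -> dict:
    """Gap counts before/after chaining and the percentage remaining."""
    def count(blocks_by_chrom):
        return sum(max(0, len(b) - 1) for b in blocks_by_chrom.values())

    before = count(blocks_before)
    after = count(blocks_after)
    return {
        "gaps_before": before,
        "gaps_after": after,
        "percent_remaining": None if before == 0 else 100.0 * after / before,
    }
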