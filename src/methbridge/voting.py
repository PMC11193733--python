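"""Methylation-based haplotagging of untagged reads by per-site votes.

Each ASM site a read covers casts one vote: for the haplotype whose median
methylation score is closer to the read's own score at that site.  Sites
where either haplotype has fewer than ``min_cov_per_hap`` contributing
scores abstain, as do exact ties.  A read is assigned to the haplotype
with strictly more votes, provided the winner collected at least
``min_votes``.

Assignment is iterative and synchronous: within an iteration all votes are
cast against the profiles committed at the end of the previous iteration,
so results do not depend on read order.  Newly assigned reads enter the
profiles of the next iteration, which can unlock sites that previously
lacked coverage.  Assignments are never revoked.
"""
from __future__ import annotations

from typing import Dict, Iterable, List, Optional, Sequence

from .asm import collect_site_profiles, find_asm_sites
from .records import (AsmConfig, CpGSiteProfile, ExtendedBlock, ReadMethRecord,
                      VoteTally, VotingConfig)


def cast_votes(
    read: ReadMethRecord,
    asm_profiles: Dict[int, CpGSiteProfile],
    config: VotingConfig,
) -> VoteTally:
    """Vote the read's scores at every ASM site it covers."""
    tally = VoteTally(read_id=read.read_id)
    for pos, score in read.meth_calls:
        prof = asm_profiles.get(pos)
        if prof is None:
            continue
        if prof.n1 < config.min_cov_per_hap or prof.n2 < config.min_cov_per_hap:
            tally.abstentions += 1
            continue
        d1 = abs(score - prof.h1_median)
        d2 = abs(score - prof.h2_median)
        if d1 < d2:
            tally.votes_h1 += 1
        elif d2 < d1:
            tally.votes_h2 += 1
        else:
            tally.abstentions += 1
    return tally


def assign_read(tally: VoteTally, config: VotingConfig) -> Optional[int]:
    """Resolve a tally: the strict-majority haplotype, if it has enough votes."""
    if tally.votes_h1 == tally.votes_h2:
        return None
    winner, votes = (1, tally.votes_h1) if tally.votes_h1 > tally.votes_h2 \
        else (2, tally.votes_h2)
    return winner if votes >= config.min_votes else None


def iterate_assignment(
    block_reads: Sequence[ReadMethRecord],
    extended_block: ExtendedBlock,
    asm_config: AsmConfig,
    voting_config: VotingConfig,
) -> tuple:
    """Iteratively haplotag the block's untagged reads.

    Reads carrying the block's own phase set seed the profiles; every other
    overlapping read (untagged, or tagged with a different phase set) is a
    candidate.  Returns ``(tallies, per_iteration_counts)`` where
    ``tallies`` maps read_id -> VoteTally for every read assigned by
    methylation, and ``per_iteration_counts`` lists the number of reads
    newly assigned in each iteration.
    """
    seed_labels = {
        r.read_id: r.haplotype for r in block_reads
        if r.haplotype is not None and r.phase_set == extended_block.block_id
    }
    assigned: Dict[str, VoteTally] = {}
    per_iteration: List[int] = []
    for iteration in range(1, voting_config.max_iterations + 1):
        labels = dict(seed_labels)
        labels.update({rid: t.assignment for rid, t in assigned.items()})
        profiles = collect_site_profiles(block_reads, extended_block, labels)
        asm_profiles = find_asm_sites(profiles, asm_config)
        newly: Dict[str, VoteTally] = {}
        for read in block_reads:
            if read.read_id in labels:
                continue
            tally = cast_votes(read, asm_profiles, voting_config)
            hap = assign_read(tally, voting_config)
            if hap is not None:
                tally.assignment = hap
                tally.iteration_assigned = iteration
                newly[read.read_id] = tally
        per_iteration.append(len(newly))
        if not newly:
            break
        assigned.update(newly)
    return assigned, per_iteration


def assignments_to_table(block_id: int, tallies: Dict[str, VoteTally]):
    """Per-block read-assignment table for CSV export."""
    import pandas as pd

    rows = [{
        "read_id": t.read_id, "block_id": block_id,
        "votes_h1": t.votes_h1, "votes_h2": t.votes_h2,
        "abstentions": t.abstentions,
        "assignment": f"H{t.assignment}" if t.assignment else "unassigned",
        "iteration": t.iteration_assigned,
    } for t in tallies.values()]
    return pd.DataFrame(rows, columns=["read_id", "block_id", "votes_h1",
                                       "votes_h2", "abstentions", "assignment",
                                       "iteration"])
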