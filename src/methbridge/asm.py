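"""Per-CpG haplotype methylation profiles and allele-specific methylation calls.

Inside each extended phase block the modification probabilities of the
currently haplotagged reads are pooled per CpG site and per haplotype.  A
site whose two score samples differ under a two-sided Wilcoxon rank-sum
(Mann-Whitney) test at the configured level is flagged as allele-specific
methylation (ASM) and becomes eligible to cast haplotype votes for
untagged reads.
"""
from __future__ import annotations

from typing import Dict, Iterable, List, Optional

import numpy as np
from scipy.stats import mannwhitneyu

from .records import AsmConfig, CpGSiteProfile, ExtendedBlock, ReadMethRecord

EXACT_MAX_N = 25


def rank_sum_test(h1_scores, h2_scores) -> float:
    """Two-sided Wilcoxon rank-sum p-value for two score samples.

    Uses the exact null distribution when both samples have at most
    25 observations and no ties across the pooled sample; otherwise the
    normal approximation with midranks, tie correction and continuity
    correction.  Requires at least two scores per haplotype.
    """
    x = np.asarray(h1_scores, dtype=float)
    y = np.asarray(h2_scores, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("rank-sum test needs >= 2 scores per haplotype")
    pooled = np.concatenate([x, y])
    tie_free = np.unique(pooled).size == pooled.size
    method = "exact" if (tie_free and x.size <= EXACT_MAX_N and y.size <= EXACT_MAX_N) \
        else "asymptotic"
    return float(mannwhitneyu(x, y, alternative="two-sided", method=method).pvalue)


def collect_site_profiles(
    reads: Iterable[ReadMethRecord],
    extended_block: ExtendedBlock,
    labels: Optional[Dict[str, int]] = None,
) -> Dict[int, CpGSiteProfile]:
    """Pool modification scores per CpG site, partitioned by haplotype.

    ``labels`` maps read_id -> haplotype (1/2) and defines which reads
    currently count as tagged; when omitted, each read's own HP tag is used
    (restricted to the block's phase set).  Only calls inside the extended
    block contribute.  Sites covered solely by unlabeled reads get no
    profile.
    """
    profiles: Dict[int, CpGSiteProfile] = {}
    chrom = extended_block.chrom
    for read in reads:
        if labels is not None:
            hap = labels.get(read.read_id)
        elif read.phase_set == extended_block.block_id:
            hap = read.haplotype
        else:
            hap = None
        if hap is None:
            continue
        for pos, prob in read.meth_calls:
            if not extended_block.contains_pos0(pos):
                continue
            prof = profiles.get(pos)
            if prof is None:
                prof = profiles[pos] = CpGSiteProfile(chrom=chrom, pos=pos)
            (prof.h1_scores if hap == 1 else prof.h2_scores).append(prob)
    return profiles


def find_asm_sites(
    profiles: Dict[int, CpGSiteProfile],
    config: AsmConfig,
) -> Dict[int, CpGSiteProfile]:
    """Test every eligible profile and return the ASM sites, ordered by position.

    A site is eligible when both haplotypes have at least
    ``config.min_scores_per_hap`` scores; it is ASM when the rank-sum
    p-value is below ``config.alpha``.  Medians are filled in for every
    profile with at least one score on the respective haplotype.
    """
    asm: Dict[int, CpGSiteProfile] = {}
    for pos in sorted(profiles):
        prof = profiles[pos]
        if prof.h1_scores:
            prof.h1_median = float(np.median(prof.h1_scores))
        if prof.h2_scores:
            prof.h2_median = float(np.median(prof.h2_scores))
        if prof.n1 >= config.min_scores_per_hap and prof.n2 >= config.min_scores_per_hap:
            prof.p_value = rank_sum_test(prof.h1_scores, prof.h2_scores)
            prof.is_asm = prof.p_value < config.alpha
        else:
            prof.p_value = None
            prof.is_asm = False
        if prof.is_asm:
            asm[pos] = prof
    return asm


def profiles_to_table(profiles: Dict[int, CpGSiteProfile]):
    """Per-site profile table (1-based positions) for TSV export."""
    import pandas as pd

    rows = []
    for pos in sorted(profiles):
        p = profiles[pos]
        rows.append({
            "chrom": p.chrom, "pos": p.pos + 1, "n1": p.n1, "n2": p.n2,
            "median1": p.h1_median, "median2": p.h2_median,
            "p_value": p.p_value, "is_asm": p.is_asm,
        })
    return pd.DataFrame(rows, columns=["chrom", "pos", "n1", "n2", "median1",
                                       "median2", "p_value", "is_asm"])
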