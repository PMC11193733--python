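"""Modification-tag decoding, CIGAR projection and re-tagged BAM output."""
import pysam
import pytest

from methbridge.bam_io import (ModificationDecodeConfig, decode_prob,
                               encode_prob, read_methylation_records,
                               write_retagged_bam)

from conftest import write_toy_bam


def test_decode_prob_midpoint_rule():
    assert decode_prob(255) == pytest.approx(0.998046875)
    assert decode_prob(0) == pytest.approx(0.5 / 256)


def test_decode_prob_monotone_and_bounded():
    probs = [decode_prob(v) for v in range(256)]
    assert all(0 < p < 1 for p in probs)
    assert probs == sorted(probs)
    assert all(encode_prob(p) == v for v, p in enumerate(probs))


@pytest.fixture(scope="module")
def toy_bam(tmp_path_factory):
    """Three reads exercising projection, strand merging and tag handling."""
    records = [
        # plain forward read, two modified CpG cytosines
        {"name": "fwd", "start": 100, "seq": "TACGTTCGAA",
         "mm": "C+m?,0,0;", "ml": [255, 128], "tags": {"HP": 1, "PS": 5}},
        # 2 bp insertion (one modified C inside it) then a 2 bp deletion:
        # qpos 3 has no reference anchor, qpos 9 projects to ref 209
        {"name": "indel", "start": 200, "seq": "ACGCCACGTCG",
         "cigar": [(0, 3), (1, 2), (0, 3), (2, 2), (0, 3)],
         "mm": "C+m?,1,2;", "ml": [200, 100]},
        # reverse-strand read: the modified C sits on the CpG's G in
        # genomic-forward coordinates (ref 303), merged onto the C at 302
        {"name": "rev", "start": 300, "seq": "AACGTT", "flag": 16,
         "mm": "C+m?,0;", "ml": [255]},
        {"name": "no_mods", "start": 400, "seq": "ACGTACGT"},
        {"name": "low_mapq", "start": 500, "seq": "ACGTACGT", "mapq": 3},
    ]
    path = tmp_path_factory.mktemp("toy") / "toy.bam"
    return write_toy_bam(path, records)


def test_forward_read_projection_and_tags(toy_bam):
    recs = {r.read_id: r for r in read_methylation_records(toy_bam)}
    fwd = recs["fwd"]
    assert fwd.haplotype == 1 and fwd.phase_set == 5
    assert fwd.meth_calls == [(102, pytest.approx(255.5 / 256)),
                              (106, pytest.approx(128.5 / 256))]


def test_insertion_call_dropped_deletion_shifts(toy_bam):
    recs = {r.read_id: r for r in read_methylation_records(toy_bam)}
    # the inserted C's call has no reference anchor; the remaining call
    # lands after the deletion at ref 209 (= 200 + 3 + 3 + 2 + 1)
    assert recs["indel"].meth_calls == [(209, pytest.approx(100.5 / 256))]


def test_reverse_strand_merged_onto_forward_c(toy_bam):
    recs = {r.read_id: r for r in read_methylation_records(toy_bam)}
    assert recs["rev"].meth_calls == [(302, pytest.approx(255.5 / 256))]
    unmerged = {r.read_id: r for r in read_methylation_records(
        toy_bam, config=ModificationDecodeConfig(merge_strands=False))}
    assert unmerged["rev"].meth_calls[0][0] == 303


def test_untagged_and_missing_mod_reads(toy_bam):
    recs = {r.read_id: r for r in read_methylation_records(toy_bam)}
    assert recs["no_mods"].haplotype is None
    assert recs["no_mods"].meth_calls == []
    assert "low_mapq" not in recs  # below min_mapq default 10


def _records(path):
    with pysam.AlignmentFile(path) as bam:
        return [r.to_string() for r in bam.fetch(until_eof=True)]


def test_passthrough_is_identity(small_dataset, tmp_path):
    """Empty assignments + empty flip set reproduce the input record-for-record."""
    paths, _ = small_dataset
    out = str(tmp_path / "pass.bam")
    counts = write_retagged_bam(paths["bam"], {}, set(), None, out)
    assert _records(out) == _records(paths["bam"])
    assert counts["total"] == len(_records(paths["bam"]))


def test_flip_swaps_snv_tags_and_assignment_adds_hp(small_dataset, tmp_path):
    paths, sim = small_dataset
    chrom = sim.truth.chrom
    flip_block = sim.blocks[0].block_id
    with pysam.AlignmentFile(paths["bam"]) as bam:
        alns = list(bam.fetch(until_eof=True))
    tagged = next(a for a in alns if a.has_tag("HP")
                  and a.get_tag("PS") == flip_block)
    untagged = next(a for a in alns if not a.has_tag("HP")
                    and a.reference_start < sim.blocks[0].end)
    out = str(tmp_path / "flip.bam")
    write_retagged_bam(
        paths["bam"], {untagged.query_name: (flip_block, 1)},
        {(chrom, flip_block)}, None, out)
    with pysam.AlignmentFile(out) as bam:
        by_name = {a.query_name: a for a in bam.fetch(until_eof=True)}
    assert by_name[tagged.query_name].get_tag("HP") == 3 - tagged.get_tag("HP")
    newly = by_name[untagged.query_name]
    assert newly.get_tag("HP") == 2              # flipped from 1
    assert newly.get_tag("PS") == flip_block


def test_assignment_to_nonoverlapping_block_is_fatal(small_dataset, tmp_path):
    paths, sim = small_dataset
    chrom = sim.truth.chrom
    with pysam.AlignmentFile(paths["bam"]) as bam:
        aln = next(a for a in bam.fetch(until_eof=True) if not a.has_tag("HP"))
    spans = {(chrom, 999): (aln.reference_end + 10_000,
                            aln.reference_end + 20_000)}
    with pytest.raises(ValueError, match="does not overlap"):
        write_retagged_bam(paths["bam"], {aln.query_name: (999, 1)}, set(),
                           None, str(tmp_path / "bad.bam"), block_spans=spans)
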