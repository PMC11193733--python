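"""Shared fixtures: small simulated datasets and a hand-built toy BAM."""
from array import array

import pysam
import pytest

from methbridge.simulate import SimulationConfig, simulate_dataset


@pytest.fixture(scope="session")
def small_dataset(tmp_path_factory):
    """A 3-block chromosome with files on disk: (paths, simulated data)."""
    out = tmp_path_factory.mktemp("smallds")
    cfg = SimulationConfig(seed=7, n_blocks=3, block_length=8_000)
    return simulate_dataset(cfg, str(out), prefix="small")


@pytest.fixture(scope="session")
def two_block_dataset(tmp_path_factory):
    out = tmp_path_factory.mktemp("twoblock")
    cfg = SimulationConfig(seed=11, n_blocks=2, block_length=8_000)
    return simulate_dataset(cfg, str(out), prefix="two")


def write_toy_bam(path, records, ref_name="t", ref_len=10_000):
    """Write hand-specified alignments (dicts) as a sorted, indexed BAM.

    Record keys: name, start, seq, cigar (tuples), flag, mm, ml, tags.
    """
    header = {"HD": {"VN": "1.6", "SO": "coordinate"},
              "SQ": [{"SN": ref_name, "LN": ref_len}]}
    records = sorted(records, key=lambda r: r["start"])
    with pysam.AlignmentFile(str(path), "wb", header=header) as out:
        for spec in records:
            a = pysam.AlignedSegment(out.header)
            a.query_name = spec["name"]
            a.query_sequence = spec["seq"]
            a.flag = spec.get("flag", 0)
            a.reference_id = 0
            a.reference_start = spec["start"]
            a.mapping_quality = spec.get("mapq", 60)
            a.cigartuples = spec.get("cigar", [(0, len(spec["seq"]))])
            if "mm" in spec:
                a.set_tag("MM", spec["mm"])
                a.set_tag("ML", array("B", spec["ml"]))
            for tag, value in spec.get("tags", {}).items():
                a.set_tag(tag, value)
            out.write(a)
    pysam.index(str(path))
    return str(path)
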