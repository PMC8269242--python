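"""Shared fixtures: tiny SAM builders and fragment factories."""

from __future__ import annotations

import pysam
import pytest

from primerscope.extract import PrimerRegionFragment
from primerscope.primers import DegeneratePrimer


def write_sam(path, ref_name, ref_len, reads):
    """Write a headered SAM; reads are dicts with name/start0/seq/qual/....

    ``start0`` is the 0-based leftmost reference position; ``cigar`` defaults
    to full-length match; ``flag`` defaults to mapped forward.
    """
    header = {
        "HD": {"VN": "1.6"},
        "SQ": [{"SN": ref_name, "LN": ref_len}],
    }
    with pysam.AlignmentFile(str(path), "w", header=header) as sam:
        for r in reads:
            a = pysam.AlignedSegment(sam.header)
            a.query_name = r["name"]
            a.query_sequence = r["seq"]
            a.flag = r.get("flag", 0)
            if not (a.flag & 0x4):
                a.reference_id = 0
                a.reference_start = r["start0"]
                a.cigarstring = r.get("cigar", f"{len(r['seq'])}M")
                a.mapping_quality = 60
            if "qual" in r:
                a.query_qualities = pysam.qualitystring_to_array(r["qual"])
            sam.write(a)
    return path


@pytest.fixture
def sam_factory(tmp_path):
    def make(ref_name, ref_len, reads, fname="reads.sam"):
        return write_sam(tmp_path / fname, ref_name, ref_len, reads)

    return make


def make_fragment(bases, sample="S01", group="Bacteria", primer="P",
                  read_id="r0", mean_quality=40.0, n_mismatches=None):
    return PrimerRegionFragment(
        read_id=read_id, sample_id=sample, group=group, primer_name=primer,
        bases=bases, mean_quality=mean_quality, n_mismatches=n_mismatches,
    )


@pytest.fixture
def toy_forward_primer():
    """A short concrete-window primer on a 60 bp toy reference."""
    return DegeneratePrimer(
        "toyF", "ACGTACGTAC", "forward", reference="toy_ref",
        ref_start=21, ref_end=30,
    )
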