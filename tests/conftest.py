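import numpy as np
import pandas as pd
import pysam
import pytest

from splicekin.design import default_design, design_arrays


@pytest.fixture(scope="session")
def sam_header():
    return pysam.AlignmentHeader.from_dict(
        {"HD": {"VN": "1.6", "SO": "coordinate"}, "SQ": [{"SN": "chr1", "LN": 100000}]}
    )


@pytest.fixture
def make_read(sam_header):
    """Factory for synthetic aligned segments.

    Reads are unpaired and forward by default; with strandedness 'fr' they
    are sense to the + strand.
    """

    def _make(name, start, cigar, mapq=255, flag=0):
        a = pysam.AlignedSegment(sam_header)
        a.query_name = name
        a.reference_id = 0
        a.reference_start = start
        a.cigarstring = cigar
        a.mapping_quality = mapq
        a.flag = flag
        return a

    return _make


@pytest.fixture
def write_sam(sam_header, tmp_path):
    def _write(reads, name="reads.sam"):
        path = tmp_path / name
        with pysam.AlignmentFile(path, "w", header=sam_header) as fh:
            for read in sorted(reads, key=lambda r: r.reference_start):
                fh.write(read)
        return str(path)

    return _write


@pytest.fixture(scope="session")
def flat_design():
    """28-sample study design with unit depth, 10% contamination."""
    design = default_design()
    factors = pd.DataFrame(
        {
            "sample_id": design["sample_id"],
            "F": 1.0,
            "chi": np.where(design["protocol"] == "ttseq", 0.1, 1.0),
        }
    )
    return design, factors, design_arrays(design, factors)
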