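import os

import pysam
import pytest

from meicall import simulate as sim
from meicall.config import load_config
from meicall.mobilome import db_from_sequences


@pytest.fixture(scope="session")
def cfg():
    return load_config(preset="wgs-pe")


@pytest.fixture(scope="session")
def mobilome_records():
    return sim.make_mobilome(3)


@pytest.fixture(scope="session")
def db(mobilome_records):
    return db_from_sequences(mobilome_records)


@pytest.fixture(scope="session")
def small_sim(tmp_path_factory):
    """A small error-free homozygous simulation shared across tests."""
    out = tmp_path_factory.mktemp("smallsim")
    simcfg = sim.SimConfig(
        seed=11,
        genome_length=300_000,
        n_insertions=10,
        coverage=20,
        base_error_rate=0.0,
        n_decoys=4,
    )
    mobilome = sim.make_mobilome(11)
    reference = sim.make_reference(simcfg, mobilome)
    truths = sim.plant_insertions(reference, mobilome, simcfg)
    bam = sim.emit_alignments(
        reference, truths, mobilome, simcfg, str(out / "reads.bam"),
        fastq_path=str(out / "reads.fastq"),
    )
    return {
        "dir": out,
        "simcfg": simcfg,
        "mobilome": mobilome,
        "reference": reference,
        "truths": truths,
        "bam": bam,
    }


def write_sam(path, records, ref_length=100000):
    """Write records (dicts of AlignedSegment attributes) to a sorted+indexed BAM."""
    header = {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": "chr1", "LN": ref_length}, {"SN": "chr5", "LN": ref_length}],
    }
    tmp = str(path) + ".unsorted.bam"
    with pysam.AlignmentFile(tmp, "wb", header=header) as out:
        for rec in records:
            out.write(rec)
    pysam.sort("-o", str(path), tmp)
    os.unlink(tmp)
    pysam.index(str(path))
    return str(path)
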