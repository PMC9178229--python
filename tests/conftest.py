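import numpy as np
import pytest

from archscan.synthetic_data import generate_genome, plant_mgees
from archscan.types import DUP, LSG, REARR, FeatureRecord, PipelineParams


@pytest.fixture(scope="session")
def params():
    return PipelineParams()


@pytest.fixture(scope="session")
def small_genome():
    """Four chromosomes of 12 Mb, 250 genes each."""
    return generate_genome(4, 250, 12_000_000, seed=11)


@pytest.fixture(scope="session")
def planted(small_genome):
    """Unambiguously planted dataset: low rates, no noise, no decoys."""
    maps, truth = plant_mgees(
        small_genome,
        rates={LSG: 0.03, REARR: 0.03, DUP: 0.03},
        seed=12,
    )
    return maps, truth


@pytest.fixture()
def gff3_file(tmp_path):
    """Three genes on two chromosomes; the first has two CDS with midpoints
    at 100 and 200 (0-based), so its representative midpoint is 150."""
    text = "\n".join(
        [
            "##gff-version 3",
            "chr1\tsrc\tgene\t41\t260\t.\t+\t.\tID=gA",
            "chr1\tsrc\texon\t41\t260\t.\t+\t.\tID=gA.e1;Parent=gA",
            "chr1\tsrc\tCDS\t51\t150\t.\t+\t0\tID=gA.c1;Parent=gA",
            "chr1\tsrc\tCDS\t151\t250\t.\t+\t0\tID=gA.c2;Parent=gA",
            "chr1\tsrc\tgene\t1001\t2000\t.\t-\t.\tID=gB",
            "chr1\tsrc\texon\t1001\t2000\t.\t-\t.\tID=gB.e1;Parent=gB",
            "chr2\tsrc\tgene\t501\t700\t.\t+\t.\tID=gC",
            "",
        ]
    )
    path = tmp_path / "genes.gff3"
    path.write_text(text)
    return path
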