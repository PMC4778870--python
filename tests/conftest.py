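import io

import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


TOY_GTF = """\
chr2L\tFlyBase\texon\t100\t200\t.\t+\t.\tgene_id "FBgn0001"; transcript_id "FBtr0001";
chr2L\tFlyBase\texon\t300\t400\t.\t+\t.\tgene_id "FBgn0001"; transcript_id "FBtr0001";
"""

TWO_TX_GTF = TOY_GTF + """\
chr2L\tFlyBase\texon\t100\t200\t.\t+\t.\tgene_id "FBgn0001"; transcript_id "FBtr0002";
chr2L\tFlyBase\texon\t500\t600\t.\t+\t.\tgene_id "FBgn0001"; transcript_id "FBtr0002";
"""

TOY_MAF = """\
##maf version=1
a score=0.0
s dm3.chr2L 10 9 + 1000 ACGT-TCCTT
s droSim1.chr2L 5 8 + 800 ACGT--CCTT
s anoGam1.chr3 7 10 - 900 ACGTATCCTT

"""


@pytest.fixture
def toy_gtf():
    return io.StringIO(TOY_GTF)


@pytest.fixture
def two_transcript_gtf():
    return io.StringIO(TWO_TX_GTF)


@pytest.fixture
def toy_maf():
    return io.StringIO(TOY_MAF)
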