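import pytest

import redoxquant as rq
from redoxquant.datasets import adh1_fasta_path, adh1_quant_path


@pytest.fixture
def design4() -> rq.ChannelDesign:
    """Single replicate group: 114/116/118/121."""
    return rq.read_channel_design("itraq4")


@pytest.fixture
def design8() -> rq.ChannelDesign:
    """Two replicate groups: 114/116/118/121 and 113/115/117/119."""
    return rq.read_channel_design("itraq8-duplex")


@pytest.fixture
def adh_fasta():
    return adh1_fasta_path()


@pytest.fixture
def adh_table_5mm():
    return adh1_quant_path("5mm")


@pytest.fixture
def adh_records_5mm(design4, adh_table_5mm):
    return rq.read_peptide_quant(adh_table_5mm, design4)
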