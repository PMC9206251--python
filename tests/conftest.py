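import pytest

from privgst.data_io import HaplotypeDataset
from privgst.gst_core import build_trie
from privgst.query_engine import build_server_bundle
from privgst.rmt_hash import Salt
from privgst.secure_index import EncryptionContext

#: The 5x6 demonstration haplotype matrix used in the worked examples.
TABLE_ROWS = ("100010", "111010", "110001", "010110", "010101")


@pytest.fixture
def table1() -> HaplotypeDataset:
    return HaplotypeDataset(records=TABLE_ROWS)


@pytest.fixture
def salt() -> Salt:
    # fixed key material: tests need determinism, not secrecy
    return Salt(bytes(range(16)))


@pytest.fixture
def ctx() -> EncryptionContext:
    return EncryptionContext(key=bytes(range(16)), iv=bytes(range(16, 32)))


@pytest.fixture
def table1_bundle(table1, salt, ctx):
    return build_server_bundle(build_trie(table1), salt, ctx)
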