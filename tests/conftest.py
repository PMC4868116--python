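import pytest

from treekit.taxonomy import build_taxdb, canonical_taxdump


@pytest.fixture(scope="session")
def taxdump_dir(tmp_path_factory):
    out = tmp_path_factory.mktemp("taxdump")
    canonical_taxdump(out)
    return out


@pytest.fixture(scope="session")
def taxdb(taxdump_dir):
    return build_taxdb(taxdump_dir / "nodes.dmp", taxdump_dir / "names.dmp",
                       taxdump_dir / "merged.dmp")
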