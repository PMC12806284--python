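import pytest

from plastkit.synthetic import PlastomeSpec, generate_synthetic_plastome


@pytest.fixture(scope="session")
def plastome():
    """The default synthetic plastome (33 kb, IR 2.5 kb) and its ledger."""
    return generate_synthetic_plastome(PlastomeSpec(seed=42))


@pytest.fixture(scope="session")
def record(plastome):
    return plastome[0]


@pytest.fixture(scope="session")
def ledger(plastome):
    return plastome[1]


MINIMAL_GENBANK = """\
LOCUS       mini                     120 bp    DNA     circular PLN 01-JAN-2000
DEFINITION  minimal fixture.
ACCESSION   mini
VERSION     mini
KEYWORDS    .
SOURCE      .
  ORGANISM  .
            .
FEATURES             Location/Qualifiers
     source          1..120
     CDS             11..100
                     /gene="demo"
ORIGIN
        1 acgtacgtac gtacgtacgt acgtacgtac gtacgtacgt acgtacgtac gtacgtacgt
       61 acgtacgtac gtacgtacgt acgtacgtac gtacgtacgt acgtacgtac gtacgtacgt
//
"""


@pytest.fixture()
def minimal_gb_path(tmp_path):
    p = tmp_path / "mini.gb"
    p.write_text(MINIMAL_GENBANK)
    return p
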