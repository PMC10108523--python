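import json
import pytest

from genoscene.genome import Assembly, Region


@pytest.fixture(scope="session")
def sv_demo(tmp_path_factory):
    """The desk-scale SV story bundle (2 x 100 kb genome, reciprocal
    translocation + inversion + deletion, simulated long reads)."""
    from genoscene.fixtures import make_preset

    outdir = tmp_path_factory.mktemp("sv_demo")
    manifest = make_preset("sv-demo", seed=7, outdir=str(outdir))
    return manifest


@pytest.fixture(scope="session")
def sv_demo_assembly(sv_demo):
    return Assembly.from_fasta(sv_demo["paths"]["reference"], name="ref")


@pytest.fixture
def toy_assembly():
    return Assembly(
        "toy",
        [("chr1", 5000), ("chr2", 800)],
        aliases={"1": "chr1", "2": "chr2"},
    )
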