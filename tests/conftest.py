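import pytest

from m6aforest.features import FeatureWindow
from m6aforest.motifs import MotifSite
from m6aforest.synthetic import SyntheticConfig, generate_fixture


def make_window(
    ref="tx1",
    a_pos=50,
    motif="GGACT",
    strand="+",
    values=None,
    flank=10,
    coverage=10,
    label="unknown",
):
    """Hand-build a FeatureWindow without touching track files."""
    if values is None:
        values = (0.5,) * (2 * flank + 1)
    return FeatureWindow(
        MotifSite(ref, a_pos, motif, strand), tuple(values), coverage, label
    )


@pytest.fixture(scope="session")
def small_fixture(tmp_path_factory):
    """A compact synthetic data set shared by read-only tests."""
    out = tmp_path_factory.mktemp("fixture")
    config = SyntheticConfig(
        n_sequences=4,
        seq_length=1200,
        n_methylated_sites=60,
        n_unmethylated_drach_decoys=60,
        seed=7,
    )
    manifest = generate_fixture(config, out)
    return out, config, manifest
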