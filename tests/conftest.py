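import pytest

from plastid_atlas.core_io import ThresholdConfig
from plastid_atlas.pipeline import run_atlas, simulate_bundle


@pytest.fixture
def cfg():
    return ThresholdConfig()


@pytest.fixture(scope="session")
def atlas_run(tmp_path_factory):
    """One full synthetic bundle + atlas run shared across tests."""
    bundle_dir = tmp_path_factory.mktemp("bundle")
    simulate_bundle(bundle_dir, seed=7)
    outdir = bundle_dir / "out"
    report = run_atlas(bundle_dir / "config.yaml", outdir)
    return bundle_dir, outdir, report
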