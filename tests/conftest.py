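"""Shared fixtures: one default synthetic study, reused across modules."""

import pytest

from sagelnc.simulate import SyntheticDesign, simulate_study


@pytest.fixture(scope="session")
def default_study():
    """A full synthetic study under the default design (seed fixed)."""
    return simulate_study(SyntheticDesign(), seed=11)


@pytest.fixture(scope="session")
def collision_study():
    """A study with 10% of genes in shared-tag pairs (multi-map cases)."""
    return simulate_study(SyntheticDesign(tag_collision_rate=0.10), seed=13)


@pytest.fixture(scope="session")
def fixture_dir(tmp_path_factory, collision_study):
    """File-based fixture set written from the collision study."""
    from sagelnc.simulate import write_fixtures

    outdir = tmp_path_factory.mktemp("fixtures")
    paths = write_fixtures(collision_study, outdir, seed=13)
    return paths
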