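import pytest

from chromosaic import painting, simgen, tags


@pytest.fixture(scope="session")
def three_group_spec() -> simgen.GroupPhylogenySpec:
    """Three ancestral groups at the study's divergence depths (years),
    evolved at the Musaceae synonymous rate."""
    return simgen.GroupPhylogenySpec(
        "((A:4400000,B:4400000):3400000,C:7800000);", length=200_000, seed=11
    )


@pytest.fixture(scope="session")
def panels(three_group_spec):
    result, _ = simgen.simulate_ancestral_groups(three_group_spec)
    return result


@pytest.fixture(scope="session")
def diagnostic_tags(panels):
    return tags.discover_tags(panels, tags.TagConfig())


@pytest.fixture(scope="session")
def default_mosaic(panels):
    """Two-donor mosaic with the default A/B/A recipe and its truth."""
    spec = simgen.MosaicSpec("chrM", [(80_000, "A", 0), (60_000, "B", 0), (60_000, "A", 0)])
    return simgen.build_mosaic_genome(panels, spec)


@pytest.fixture(scope="session")
def default_painting(default_mosaic, diagnostic_tags):
    mosaic, _ = default_mosaic
    return painting.paint_assembly(mosaic, diagnostic_tags)
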