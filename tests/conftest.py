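import pytest

from restcobind.pipeline import RunConfig, run_pipeline
from restcobind.simulate import SyntheticConfig, SiteSpec, generate_fixture


def small_synth_config(seed: int = 11) -> SyntheticConfig:
    """A scaled-down study: 1 Mb genome, 12 sites (one per class x
    occupancy), 60 genes, 100k tags per sample.  Same background tag
    density (0.1/base) and enrichment (20x) as the standard fixture."""
    spec = []
    for cls in ("R+/S+/L+", "R+/S+/L-", "R+/S-/L+", "R+/S-/L-"):
        for occ in ("ES-only", "EpiS-only", "both"):
            induced = cls != "R+/S-/L-" and occ != "EpiS-only"
            spec.append(SiteSpec(cls, occ, 20.0, induced, 4.0))
    return SyntheticConfig(
        seed=seed,
        genome=[("chr1", 1_000_000)],
        n_coding_genes=60,
        n_noncoding_genes=0,
        n_intergenic_promoters=4,
        site_spec=spec,
        chip_depth=100_000,
        input_depth=100_000,
        tss_depth=100_000,
        mrna_depth=100_000,
    )


@pytest.fixture(scope="session")
def small_config():
    return small_synth_config()


@pytest.fixture(scope="session")
def small_fixture_dir(tmp_path_factory, small_config):
    out = tmp_path_factory.mktemp("smallfix") / "fixture"
    generate_fixture(small_config, out)
    return out


@pytest.fixture(scope="session")
def small_result(small_fixture_dir, tmp_path_factory):
    out = tmp_path_factory.mktemp("smallrun")
    cfg = RunConfig(data_dir=str(small_fixture_dir), out_dir=str(out), seed=5)
    return run_pipeline(cfg)


@pytest.fixture(scope="session")
def standard_fixture_dir(tmp_path_factory):
    """The standard synthetic study: 5 Mb genome, 60 planted sites over
    every class x occupancy category at 20x enrichment, 500k tags per
    sample, seed 42."""
    out = tmp_path_factory.mktemp("stdfix") / "fixture"
    generate_fixture(SyntheticConfig(seed=42), out)
    return out


@pytest.fixture(scope="session")
def standard_result(standard_fixture_dir, tmp_path_factory):
    out = tmp_path_factory.mktemp("stdrun")
    cfg = RunConfig(
        data_dir=str(standard_fixture_dir), out_dir=str(out), seed=1
    )
    return run_pipeline(cfg)
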