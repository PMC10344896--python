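import pytest

from omniindel import fixtures as fx


@pytest.fixture(scope="session")
def default_spec():
    return fx.default_fixture_spec(seed=17)


@pytest.fixture(scope="session")
def fixture_dir(tmp_path_factory, default_spec):
    """Default fixture written to disk once per session."""
    out = tmp_path_factory.mktemp("fixture")
    paths = fx.generate(default_spec, out)
    return paths


@pytest.fixture(scope="session")
def fixture_data(default_spec):
    """In-memory default fixture: genome, records, calls, truth tables."""
    genome, ssr_truth = fx.make_genome(default_spec)
    records, calls, truth = fx.make_vcf(default_spec, genome)
    return {
        "spec": default_spec,
        "genome": genome,
        "ssr_truth": ssr_truth,
        "records": records,
        "calls": calls,
        "truth": truth,
    }
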