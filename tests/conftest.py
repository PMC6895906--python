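import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite", derandomize=True, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture
def small_catalog():
    """Three diseases over a 12-gene universe with known overlaps."""
    from neurosim import DiseaseGeneCatalog

    universe = frozenset(f"g{i}" for i in range(12))
    return DiseaseGeneCatalog(
        diseases=["ataxia", "dystonia", "epilepsy"],
        gene_sets={
            "ataxia": frozenset({"g0", "g1", "g2", "g3"}),
            "dystonia": frozenset({"g2", "g3", "g4", "g5", "g6", "g7"}),
            "epilepsy": frozenset({"g8", "g9"}),
        },
        universe=universe,
    )


@pytest.fixture
def mutation_tsv(tmp_path):
    """Write a mutation TSV from rows and return its path."""

    def _write(rows, name="muts.tsv",
               header="disease\tgene\tbuild\tchrom\tpos\tref\talt\tpathogenicity"):
        p = tmp_path / name
        p.write_text("\n".join([header] + rows) + "\n")
        return p

    return _write


@pytest.fixture
def rng():
    return np.random.default_rng(20190)
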