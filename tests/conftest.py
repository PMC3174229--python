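import numpy as np
import pytest

from pathrise.core_data import FloraTable, SpeciesRecord
from pathrise.synthetic_flora import SyntheticConfig, generate


def make_record(i, pathways, status="casual", year=None, **kw):
    defaults = dict(
        species_id=f"sp{i:04d}",
        genus=f"genus{i % 7}",
        family=f"family{i % 3}",
        order=f"order{i % 2}",
        pathways=frozenset(pathways),
        status=status,
        first_record_year=year,
        life_form=frozenset({"herb"}),
        life_span=frozenset({"annual"}),
    )
    defaults.update(kw)
    return SpeciesRecord(**defaults)


@pytest.fixture
def tiny_flora():
    """Three hand-made species covering multi-label pathways."""
    recs = [
        make_record(1, {"release"}, status="invasive", year=1850,
                    grid_cells=10, habitats_total=5, habitats_seminatural=2),
        make_record(2, {"escape", "contaminant"}, status="naturalized", year=1900),
        make_record(3, {"stowaway"}, status="casual", year=1950, height_m=0.4),
    ]
    t = FloraTable(records=recs)
    t.validate()
    return t


@pytest.fixture(scope="session")
def small_synthetic():
    """A 400-species synthetic flora with complete records (no masking)."""
    return generate(SyntheticConfig(n_species=400, seed=42, missingness={}))


@pytest.fixture(scope="session")
def published_margin_flora():
    """1,007 species whose multi-label pathway sets realize the published
    per-pathway totals (93, 599, 443, 254; grand total 1,389)."""
    combos = (
        [("release", "escape")] * 93
        + [("escape",)] * 471
        + [("escape", "contaminant")] * 35
        + [("contaminant",)] * 154
        + [("contaminant", "stowaway")] * 254
    )
    t = FloraTable(records=[make_record(i, set(c)) for i, c in enumerate(combos)])
    t.validate()
    return t


@pytest.fixture(scope="session")
def medium_synthetic():
    """A 1007-species synthetic flora under the default study conditions."""
    return generate(SyntheticConfig(n_species=1007, seed=7))
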