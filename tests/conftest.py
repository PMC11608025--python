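import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=50,
    # fixtures drawn inside @given are read-only frames, safe to reuse
    suppress_health_check=[HealthCheck.too_slow, HealthCheck.function_scoped_fixture],
)
settings.load_profile("ci")


@pytest.fixture
def toy_catalog_df():
    """Raw (unvalidated) three-species catalog frame."""
    return pd.DataFrame(
        {
            "species_id": ["Thunnus obesus", "Scomber australasicus", "Niphon spinosus"],
            "scientific_name": ["Thunnus obesus", "Scomber australasicus", "Niphon spinosus"],
            "family": ["Scombridae", "Scombridae", "Niphonidae"],
            "common_name": ["Bigeye tuna", "Blue mackerel", "Ara"],
            "trophic_level": [4.49, 4.23, 4.5],
            "migratory_class": ["tuna", "seasonal_migratory", "indigenous"],
            "excluded_taxon": [False, False, False],
        }
    )


@pytest.fixture
def toy_catalog(toy_catalog_df):
    from trophodyn.io import catalog_from_dataframe

    return catalog_from_dataframe(toy_catalog_df)


@pytest.fixture
def toy_catch():
    """Validated toy catch table (tonnes), two sectors, three species."""
    from trophodyn.io import catch_from_dataframe

    rows = []
    for year in (2000, 2001):
        rows += [
            (year, "coastal", "Thunnus obesus", 10.0),
            (year, "coastal", "Scomber australasicus", 60.0),
            (year, "coastal", "Niphon spinosus", 30.0),
            (year, "offshore", "Thunnus obesus", 100.0),
            (year, "offshore", "Scomber australasicus", 500.0),
            (year, "offshore", "Niphon spinosus", 150.0),
        ]
    df = pd.DataFrame(rows, columns=["year", "sector", "species_id", "catch"])
    return catch_from_dataframe(df, unit="tonnes")


def make_catalog(species):
    """Build a validated catalog from (name, tl, migratory_class[, excluded]) tuples."""
    from trophodyn.io import catalog_from_dataframe

    rows = []
    for entry in species:
        name, tl, cls = entry[:3]
        excluded = entry[3] if len(entry) > 3 else False
        rows.append(
            {
                "species_id": name,
                "scientific_name": name,
                "family": "Testidae",
                "common_name": name,
                "trophic_level": tl,
                "migratory_class": cls,
                "excluded_taxon": excluded,
            }
        )
    return catalog_from_dataframe(pd.DataFrame(rows))


def make_catch(records):
    """Build a validated catch table (tonnes) from (year, sector, species, catch)."""
    from trophodyn.io import catch_from_dataframe

    df = pd.DataFrame(records, columns=["year", "sector", "species_id", "catch"])
    return catch_from_dataframe(df, unit="tonnes")
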