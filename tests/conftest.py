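import numpy as np
import pandas as pd
import pytest

from aliendrivers.records import SpeciesRecord
from aliendrivers.simulate import SynthConfig, generate_dataset


def make_record(
    species="abies alba",
    phylum="Tracheophyta",
    taxon_class="Pinopsida",
    country="Austria",
    year=1990,
    degree="ESTABLISHED",
    status="PRESENT",
) -> SpeciesRecord:
    return SpeciesRecord(
        species_name=species,
        phylum=phylum,
        taxon_class=taxon_class,
        country=country,
        first_record_year=year,
        degree_of_establishment=degree,
        occurrence_status=status,
    )


@pytest.fixture
def record_factory():
    return make_record


@pytest.fixture(scope="session")
def small_config() -> SynthConfig:
    """Scaled-down study: 24 countries, 30 years, modest pools."""
    return SynthConfig(
        seed=42,
        n_countries=24,
        n_years=30,
        intercept=3.5,
        regional_pool_size=400,
        global_pool_size=1200,
    )


@pytest.fixture(scope="session")
def small_dataset(small_config):
    return generate_dataset(small_config)


@pytest.fixture
def records_csv(tmp_path):
    """Write a small raw records CSV and return its path."""

    def write(rows, header=None):
        header = header or (
            "scientificName,phylum,class,country,firstRecordYear,"
            "degreeOfEstablishment,occurrenceStatus"
        )
        path = tmp_path / "records.csv"
        path.write_text("\n".join([header] + rows) + "\n")
        return path

    return write


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
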