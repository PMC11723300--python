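import numpy as np
import pandas as pd
import pytest

from barcodekit.seqio import BarcodeRecord, MarkerDataset
from barcodekit.synthetic_data import MarkerProfile, SimConfig


def make_dataset(seqs: dict[str, str], taxonomy: dict[str, tuple[str, str, str]],
                 marker: str = "ITS", aligned: bool = True) -> MarkerDataset:
    """Dataset from {sample_id: sequence} and {sample_id: (species, genus, family)}."""
    records = [
        BarcodeRecord(
            sample_id=sid,
            species=taxonomy[sid][0],
            genus=taxonomy[sid][1],
            family=taxonomy[sid][2],
            marker=marker,
            sequence=seq,
        )
        for sid, seq in seqs.items()
    ]
    return MarkerDataset(marker=marker, records=records, aligned=aligned)


def taxonomy_frame(taxonomy: dict[str, tuple[str, str, str]]) -> pd.DataFrame:
    return pd.DataFrame(
        [(sid, sp, ge, fa) for sid, (sp, ge, fa) in taxonomy.items()],
        columns=["sample_id", "species", "genus", "family"],
    )


TWO_SPECIES_TAX = {
    "a1": ("sp_a", "GenA", "FamA"),
    "a2": ("sp_a", "GenA", "FamA"),
    "b1": ("sp_b", "GenB", "FamB"),
    "b2": ("sp_b", "GenB", "FamB"),
}


@pytest.fixture
def two_species_dataset():
    """2 species x 2 samples, clear within/between separation."""
    base = "ACGT" * 25
    far = "TGCA" * 10 + "ACGT" * 15
    seqs = {
        "a1": base,
        "a2": base[:-1] + "A",
        "b1": far,
        "b2": far[:-1] + "C",
    }
    return make_dataset(seqs, TWO_SPECIES_TAX), taxonomy_frame(TWO_SPECIES_TAX)


@pytest.fixture
def gap_config():
    """Single-marker survey with an enforced barcoding gap (5 species)."""
    return SimConfig(
        seed=0,
        n_families=1,
        genera_per_family=1,
        species_per_genus=5,
        samples_per_species=(2, 3),
        markers=(
            MarkerProfile(
                name="ITS", length=800, gc=0.50,
                intra_divergence=0.02, inter_divergence=0.12,
            ),
        ),
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
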