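import numpy as np
import pytest

from hisol import (
    FamilySpec,
    conservation_rates,
    generate_family,
    map_target_positions,
    z_transform_scale,
)
from hisol.synthetic import random_target


@pytest.fixture(scope="session")
def kd_scale():
    return z_transform_scale()


@pytest.fixture()
def toy_family_files(tmp_path):
    """A 3-sequence toy alignment written as FASTA and Clustal."""
    rows = {"T1": "A-CDE", "H1": "AGCDE", "H2": "AGC-E"}
    fasta = tmp_path / "toy.fasta"
    fasta.write_text("".join(f">{k}\n{v}\n" for k, v in rows.items()))
    clustal = tmp_path / "toy.aln"
    body = "\n".join(f"{k:<10s}{v}" for k, v in rows.items())
    clustal.write_text(f"CLUSTAL W (1.81) multiple sequence alignment\n\n{body}\n")
    return {"fasta": fasta, "clustal": clustal}


@pytest.fixture(scope="session")
def small_family():
    """A seeded 30-sequence synthetic family with moderate conservation."""
    spec = FamilySpec(
        target_sequence=random_target(40, seed=11),
        n_sequences=30,
        conservation=0.6,
        gap_rate=0.05,
        seed=101,
    )
    return generate_family(spec)


@pytest.fixture(scope="session")
def small_family_tables(small_family):
    positions = map_target_positions(small_family)
    cons = conservation_rates(small_family, positions)
    return positions, cons
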