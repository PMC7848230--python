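"""Shared fixtures: a tiny hand-written reference collection and helpers."""

import numpy as np
import pandas as pd
import pytest

from phenomark.reference import (
    BinaryPhenotypeMatrix,
    ReferenceCollection,
    ReferenceGenome,
)


def make_lineage(genus="Gen01", species="sp1", family="Fam01"):
    return ("Bacteria", "Phy01", "", "", family, genus, species)


@pytest.fixture
def tiny_collection():
    """Three genomes; g1 has two 16S copies."""
    genomes = {
        "g1": ReferenceGenome(
            "g1",
            make_lineage("Bacteroides", "ovatus"),
            {"g1__r1": "ACGTACGTAC", "g1__r2": "ACGTACGTAT"},
        ),
        "g2": ReferenceGenome(
            "g2", make_lineage("Bacteroides", "vulgatus"), {"g2__r1": "ACGTACGGGC"}
        ),
        "g3": ReferenceGenome(
            "g3", make_lineage("Faecalibacterium", "prausnitzii", "Fam02"),
            {"g3__r1": "TTTTACGTAC"},
        ),
    }
    return ReferenceCollection(genomes)


@pytest.fixture
def tiny_bpm():
    values = pd.DataFrame(
        {"butyrate": [1, 0, 1], "GH13": [0, 1, 1]},
        index=["g1", "g2", "g3"],
    )
    cats = pd.Series(
        {"butyrate": "SCFA production", "GH13": "GH family"}
    )
    return BinaryPhenotypeMatrix(values=values, categories=cats)


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


def random_sequences(rng, n, length=60):
    bases = np.array(list("ACGT"))
    return {
        f"t{i}": "".join(bases[rng.integers(0, 4, length)]) for i in range(n)
    }
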