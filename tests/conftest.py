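"""Shared fixtures: small seeded synthetic collections and helpers."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from panprev import (
    PanMatrix,
    SimConfig,
    build_matrix,
    classify_families,
    generate_collection,
    greedy_cluster,
    remove_paralogs,
)
from panprev.io import collection_proteins

AA = "ACDEFGHIKLMNPQRSTVWY"


def random_protein(rng: np.random.Generator, length: int) -> str:
    return "".join(AA[i] for i in rng.integers(0, 20, length))


def truth_matrix(records, truth) -> PanMatrix:
    """Pan-matrix built directly from the planted truth presence patterns."""
    genomes = [r.genome_id for r in records]
    fams = sorted(truth.family_class)
    arr = np.zeros((len(fams), len(genomes)), dtype=np.int8)
    col = {g: j for j, g in enumerate(genomes)}
    for i, fid in enumerate(fams):
        for g in truth.presence(fid):
            arr[i, col[g]] = 1
    df = pd.DataFrame(arr, index=fams, columns=genomes)
    return PanMatrix(df, {r.genome_id: r.niche for r in records})


TWO_NICHE_CONFIG = dict(
    n_genomes=6,
    niche_assignment={
        "G1": "GIT",
        "G2": "GIT",
        "G3": "GIT",
        "O1": "ORAL",
        "O2": "ORAL",
        "O3": "ORAL",
    },
    n_core=15,
    n_shared_accessory=10,
    n_exclusive_present={"GIT": 4, "ORAL": 5},
    n_exclusive_absent={"ORAL": 3},
    n_singletons=3,
    within_family_identity=0.8,
    protein_length_mean=120,
    protein_length_sd=30,
    seed=42,
)


@pytest.fixture(scope="session")
def two_niche_collection():
    cfg = SimConfig(**TWO_NICHE_CONFIG)
    return generate_collection(cfg)


@pytest.fixture(scope="session")
def clustered_two_niche(two_niche_collection):
    records, truth = two_niche_collection
    families = remove_paralogs(
        greedy_cluster(collection_proteins(records), prescreen_min_kmers=1)
    )
    matrix = build_matrix(families, {r.genome_id: r.niche for r in records})
    return records, truth, families, matrix, classify_families(matrix)
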