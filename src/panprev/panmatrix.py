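"""Binary family × genome presence/absence matrix and occupancy classes.

The pan-matrix has one row per gene family and one column per genome, with
1 marking presence of a retained member.  Families are classified purely
from row sums: present in all genomes → core; present in exactly one →
singleton; anything in between → accessory.  A single-genome collection is
the degenerate overlap of the two rules and is classified core (the
"all members" condition takes precedence), flagged in the summary.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cluster import GeneFamily


def round_half_away(x: float) -> int:
    """Round half away from zero (2.5 → 3, −2.5 → −3)."""
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


@dataclass
class PanMatrix:
    """Presence/absence matrix plus per-genome niche labels."""

    data: pd.DataFrame  # index: family ids, columns: genome ids, values 0/1
    niches: dict[str, str]  # genome id -> niche label

    def __post_init__(self) -> None:
        if self.data.index.has_duplicates or self.data.columns.has_duplicates:
            raise ValueError("family and genome ids must be unique")
        vals = self.data.to_numpy()
        if not np.isin(vals, (0, 1)).all():
            raise ValueError("pan-matrix cells must be 0 or 1")
        if (vals.sum(axis=1) == 0).any():
            raise ValueError("pan-matrix rows must each have at least one presence")

    @property
    def families(self) -> list[str]:
        return list(self.data.index)

    @property
    def genomes(self) -> list[str]:
        return list(self.data.columns)

    @property
    def n_genomes(self) -> int:
        return self.data.shape[1]

    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=bool)

    def presence(self, family_id: str) -> set[str]:
        row = self.data.loc[family_id]
        return set(row.index[row == 1])

    def genomes_of_niche(self, niche: str) -> list[str]:
        target = niche.strip().lower()
        return [g for g in self.genomes if self.niches[g].strip().lower() == target]

    def to_tsv(self, path) -> None:
        self.data.to_csv(path, sep="\t", index_label="family_id")

    def to_triples(self) -> pd.DataFrame:
        """Sparse (family_id, genome_id, 1) long-format export."""
        stacked = self.data.stack()
        present = stacked[stacked == 1]
        out = present.reset_index()
        out.columns = ["family_id", "genome_id", "present"]
        return out


@dataclass
class OccupancyClasses:
    core: set[str]
    accessory: set[str]
    singleton: set[str]

    def label_of(self) -> dict[str, str]:
        out = {f: "core" for f in self.core}
        out.update({f: "accessory" for f in self.accessory})
        out.update({f: "singleton" for f in self.singleton})
        return out


@dataclass
class PanSummary:
    """Per-genome and collection-level pan-genome statistics."""

    per_genome: pd.DataFrame  # genes, core/accessory/unique counts and %
    total_genes: int
    total_families: int
    class_counts: dict[str, int]
    class_percent: dict[str, float]
    mean_genes_per_genome: float
    single_genome_collection: bool = False


def build_matrix(
    families: list[GeneFamily], metadata: dict[str, str] | pd.DataFrame
) -> PanMatrix:
    """Build the pan-matrix from paralog-free families.

    ``metadata`` maps genome id to niche label (or is a DataFrame with
    ``genome_id`` and ``niche`` columns).  Every genome contributing a
    member must appear in the metadata.
    """
    if isinstance(metadata, pd.DataFrame):
        niches = dict(zip(metadata["genome_id"], metadata["niche"]))
    else:
        niches = dict(metadata)
    genomes = list(niches)
    for fam in families:
        for genome_id in fam.genomes:
            if genome_id not in niches:
                raise ValueError(
                    f"genome {genome_id!r} (family {fam.family_id}) "
                    "is missing from the metadata table"
                )
    fam_ids = [f.family_id for f in families]
    arr = np.zeros((len(families), len(genomes)), dtype=np.int8)
    col = {g: j for j, g in enumerate(genomes)}
    for i, fam in enumerate(families):
        for genome_id in fam.genomes:
            arr[i, col[genome_id]] = 1
    df = pd.DataFrame(arr, index=fam_ids, columns=genomes)
    return PanMatrix(df, niches)


def classify_families(matrix: PanMatrix) -> OccupancyClasses:
    """Partition families into core / accessory / singleton by row sum."""
    sums = matrix.data.sum(axis=1)
    n = matrix.n_genomes
    core = set(sums.index[sums == n])
    singleton = set(sums.index[sums == 1]) - core  # n == 1: core wins
    accessory = set(sums.index) - core - singleton
    return OccupancyClasses(core, accessory, singleton)


def labeled_share(a: int, b: int) -> float:
    """Percentage 100·a/(a+b) of a two-way labeled count split."""
    if a + b == 0:
        raise ValueError("labeled_share requires a positive total")
    return 100.0 * a / (a + b)


def summarize(matrix: PanMatrix, classes: OccupancyClasses) -> PanSummary:
    """Per-genome class percentages and collection totals.

    Per-genome percentages use that genome's retained gene count as the
    denominator; reported percentages are rounded half away from zero, full
    precision is kept in the frame's ``pct_*_exact`` columns.
    """
    label = classes.label_of()
    rows = []
    for genome in matrix.genomes:
        col = matrix.data[genome]
        present = set(col.index[col == 1])
        n_genes = len(present)
        counts = {"core": 0, "accessory": 0, "singleton": 0}
        for fam in present:
            counts[label[fam]] += 1
        row = {"genome_id": genome, "niche": matrix.niches[genome], "genes": n_genes}
        for cls in ("core", "accessory", "singleton"):
            pct = 100.0 * counts[cls] / n_genes if n_genes else 0.0
            row[f"n_{cls}"] = counts[cls]
            row[f"pct_{cls}_exact"] = pct
            row[f"pct_{cls}"] = round_half_away(pct)
        rows.append(row)
    per_genome = pd.DataFrame(rows).set_index("genome_id")

    total_families = len(matrix.families)
    total_genes = int(matrix.data.to_numpy().sum())
    class_counts = {
        "core": len(classes.core),
        "accessory": len(classes.accessory),
        "singleton": len(classes.singleton),
    }
    class_percent = {
        cls: 100.0 * cnt / total_families for cls, cnt in class_counts.items()
    }
    return PanSummary(
        per_genome=per_genome,
        total_genes=total_genes,
        total_families=total_families,
        class_counts=class_counts,
        class_percent=class_percent,
        mean_genes_per_genome=total_genes / matrix.n_genomes,
        single_genome_collection=matrix.n_genomes == 1,
    )
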