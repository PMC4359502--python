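"""Core domain records shared across the pipeline.

A genome collection is a list of :class:`GenomeRecord` objects plus a
metadata table mapping genome id to species and body-site niche.  Gene ids
are unique within a genome; the pipeline-wide key for a gene is the pair
``(genome_id, gene_id)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

from Bio.Data.CodonTable import standard_dna_table

#: amino acid -> tuple of codons, standard bacterial (table 1) code
CODONS_FOR_AA: dict[str, tuple[str, ...]] = {}
for _codon, _aa in standard_dna_table.forward_table.items():
    CODONS_FOR_AA.setdefault(_aa, tuple())
    CODONS_FOR_AA[_aa] = CODONS_FOR_AA[_aa] + (_codon,)

STOP_CODONS: frozenset[str] = frozenset(standard_dna_table.stop_codons)

#: the 61 sense codons, sorted
SENSE_CODONS: tuple[str, ...] = tuple(sorted(standard_dna_table.forward_table))

CODON_TO_AA: dict[str, str] = dict(standard_dna_table.forward_table)

AMINO_ACIDS: tuple[str, ...] = tuple(sorted(CODONS_FOR_AA))


def translate_cds(cds: str) -> str:
    """Translate a frame-1 CDS (length divisible by 3); stops raise ValueError."""
    if len(cds) % 3 != 0:
        raise ValueError(f"CDS length {len(cds)} not divisible by 3")
    residues = []
    for i in range(0, len(cds), 3):
        codon = cds[i : i + 3].upper()
        if codon in STOP_CODONS:
            raise ValueError(f"stop codon {codon} at nucleotide position {i}")
        try:
            residues.append(CODON_TO_AA[codon])
        except KeyError:
            raise ValueError(f"unrecognized codon {codon!r} at position {i}") from None
    return "".join(residues)


@dataclass
class GenomeRecord:
    """One genome: id, species, niche label, proteins and optional CDSs.

    ``proteins`` is a list of ``(gene_id, amino_acid_sequence)`` pairs;
    ``cds`` (when present) pairs each gene id with a nucleotide sequence
    whose frame-1 translation equals the protein.
    """

    genome_id: str
    species: str
    niche: str
    proteins: list[tuple[str, str]] = field(default_factory=list)
    cds: Optional[list[tuple[str, str]]] = None

    def __post_init__(self) -> None:
        ids = [g for g, _ in self.proteins]
        if len(ids) != len(set(ids)):
            raise ValueError(f"duplicate gene ids in genome {self.genome_id}")

    @property
    def gene_ids(self) -> list[str]:
        return [g for g, _ in self.proteins]

    def protein_dict(self) -> dict[str, str]:
        return dict(self.proteins)

    def cds_dict(self) -> dict[str, str]:
        return dict(self.cds or [])
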