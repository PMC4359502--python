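"""Synthetic genome-collection generator with planted pan-genome structure.

Generates a collection of bacterial genomes whose gene families fall into
planted classes — core (all genomes), shared accessory (a random subset of
2..n-1 genomes), niche-exclusive-present (only genomes of one body-site
niche), niche-exclusive-absent (absent from one niche, present in every
genome outside it) and per-genome singletons — together with a ground-truth
table, so every downstream stage of the pipeline can be tested without
external data.

Sequence model: one ancestral protein per family, i.i.d. residues from the
20-letter alphabet (maximally dissimilar between families, so the clustering
truth is unambiguous); each carrier genome receives a substitution-only
mutated copy at the configured within-family identity.  CDSs are
back-translations whose codon choices are biased toward each genome's GC
target.  Everything is deterministic given the seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np

from .records import AMINO_ACIDS, CODONS_FOR_AA, GenomeRecord


class ConfigError(ValueError):
    """Raised when a simulation configuration is infeasible."""


@dataclass
class SimConfig:
    """Parameters of a planted genome collection.

    ``n_exclusive_present`` / ``n_exclusive_absent`` map niche label to the
    number of families planted for that niche.  ``gc_targets`` maps genome id
    to its GC fraction; genomes absent from the map use ``gc_default``.
    """

    n_genomes: int = 6
    niche_assignment: Optional[dict[str, str]] = None
    n_core: int = 50
    n_shared_accessory: int = 30
    p_acc: float = 0.5
    n_exclusive_present: dict[str, int] = field(default_factory=dict)
    n_exclusive_absent: dict[str, int] = field(default_factory=dict)
    n_singletons: int = 10
    protein_length_mean: int = 250
    protein_length_sd: int = 60
    protein_length_min: int = 50
    protein_length_max: int = 600
    within_family_identity: float = 0.8
    paralog_rate: float = 0.0
    gc_targets: dict[str, float] = field(default_factory=dict)
    gc_default: float = 0.45
    seed: int = 0

    def __post_init__(self) -> None:
        if self.niche_assignment is None:
            self.niche_assignment = {
                f"G{i + 1:02d}": "GIT" for i in range(self.n_genomes)
            }
        if len(self.niche_assignment) != self.n_genomes:
            raise ConfigError(
                f"niche_assignment has {len(self.niche_assignment)} genomes, "
                f"n_genomes={self.n_genomes}"
            )
        self.validate()

    @property
    def genome_ids(self) -> list[str]:
        return list(self.niche_assignment)

    @property
    def niches(self) -> list[str]:
        return sorted(set(self.niche_assignment.values()))

    def validate(self) -> None:
        if self.n_genomes < 1:
            raise ConfigError("n_genomes must be >= 1")
        for name in ("n_core", "n_shared_accessory", "n_singletons"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be non-negative")
        if self.n_shared_accessory > 0:
            if not (0.0 < self.p_acc < 1.0):
                raise ConfigError("p_acc must lie in (0, 1)")
            if self.n_genomes < 3:
                raise ConfigError(
                    "n_shared_accessory requires >= 3 genomes "
                    "(accessory means present in >1 but <all)"
                )
        n_niches = len(self.niches)
        for niche, count in self.n_exclusive_present.items():
            if count < 0:
                raise ConfigError(f"n_exclusive_present[{niche}] must be non-negative")
            if count > 0 and niche not in self.niches:
                raise ConfigError(f"n_exclusive_present names unknown niche {niche!r}")
        for niche, count in self.n_exclusive_absent.items():
            if count < 0:
                raise ConfigError(f"n_exclusive_absent[{niche}] must be non-negative")
            if count > 0 and niche not in self.niches:
                raise ConfigError(f"n_exclusive_absent names unknown niche {niche!r}")
            if count > 0 and n_niches < 2:
                raise ConfigError(
                    "n_exclusive_absent requires >= 2 niches in the collection"
                )
        if not (0.0 < self.within_family_identity <= 1.0):
            raise ConfigError("within_family_identity must lie in (0, 1]")
        if self.paralog_rate < 0:
            raise ConfigError("paralog_rate must be non-negative")
        for gid, gc in self.gc_targets.items():
            if not (0.0 < gc < 1.0):
                raise ConfigError(f"gc_targets[{gid}] must lie in (0, 1)")
        if not (0.0 < self.gc_default < 1.0):
            raise ConfigError("gc_default must lie in (0, 1)")


@dataclass
class SyntheticTruth:
    """Planted ground truth of a generated collection."""

    family_class: dict[str, str]  # family id -> class label
    family_members: dict[str, set[tuple[str, str]]]  # family -> {(genome, gene)}
    gene_family: dict[tuple[str, str], str]  # (genome, gene) -> family

    def presence(self, family_id: str) -> set[str]:
        """Genomes carrying at least one member of the family."""
        return {g for g, _ in self.family_members[family_id]}

    def families_of_class(self, label: str) -> set[str]:
        return {f for f, c in self.family_class.items() if c == label}


def mutate_protein(seq: str, target_identity: float, seed: int) -> str:
    """Substitution-only mutant of ``seq`` at the given identity.

    Exactly ``round((1 - target_identity) * len(seq))`` positions are
    substituted with a different residue, so the realized identity equals the
    target up to the rounding of that count (within 0.5/len of it).
    """
    if not seq:
        raise ValueError("cannot mutate an empty sequence")
    if not (0.0 < target_identity <= 1.0):
        raise ValueError("target_identity must lie in (0, 1]")
    n_sub = round((1.0 - target_identity) * len(seq))
    if n_sub == 0:
        return seq
    rng = np.random.default_rng(seed)
    positions = rng.choice(len(seq), size=n_sub, replace=False)
    out = list(seq)
    for pos in positions:
        alternatives = [a for a in AMINO_ACIDS if a != out[pos]]
        out[pos] = alternatives[rng.integers(len(alternatives))]
    return "".join(out)


def gc_codon_weights(
    gc_target: float, sharpness: float = 3.0
) -> dict[str, np.ndarray]:
    """Per-amino-acid codon probabilities biased toward a genomic GC target.

    Each codon's base weight is the product over its three bases of
    ``gc_target/2`` (G or C) or ``(1-gc_target)/2`` (A or T), raised to
    ``sharpness`` and renormalized within the amino acid's synonymous codon
    set.  Most codon positions are pinned by the amino acid, so without
    sharpening the realized genomic GC barely moves; the default of 3
    makes a 0.3/0.6 target pair separate clearly while keeping all
    synonymous codons in use.
    """
    weights: dict[str, np.ndarray] = {}
    for aa, codons in CODONS_FOR_AA.items():
        raw = np.array(
            [
                math.prod(
                    (gc_target / 2.0) if b in "GC" else ((1.0 - gc_target) / 2.0)
                    for b in codon
                )
                ** sharpness
                for codon in codons
            ]
        )
        weights[aa] = raw / raw.sum()
    return weights


def back_translate(
    protein: str, codon_weights: dict[str, np.ndarray], seed: int
) -> str:
    """Sample a CDS for ``protein`` from per-residue codon probabilities."""
    rng = np.random.default_rng(seed)
    codons = []
    for i, aa in enumerate(protein):
        if aa not in codon_weights or aa not in CODONS_FOR_AA:
            raise ValueError(f"no codon weights for residue {aa!r} at position {i}")
        probs = np.asarray(codon_weights[aa], dtype=float)
        choices = CODONS_FOR_AA[aa]
        if len(probs) != len(choices):
            raise ValueError(f"codon weight vector for {aa!r} has wrong length")
        codons.append(choices[rng.choice(len(choices), p=probs)])
    return "".join(codons)


def _sample_length(rng: np.random.Generator, cfg: SimConfig) -> int:
    raw = int(round(rng.normal(cfg.protein_length_mean, cfg.protein_length_sd)))
    return int(min(max(raw, cfg.protein_length_min), cfg.protein_length_max))


def _random_protein(rng: np.random.Generator, length: int) -> str:
    idx = rng.integers(0, len(AMINO_ACIDS), size=length)
    return "".join(AMINO_ACIDS[i] for i in idx)


def generate_collection(
    config: SimConfig,
) -> tuple[list[GenomeRecord], SyntheticTruth]:
    """Generate the planted collection described by ``config``.

    Families are laid down in a fixed order (core, shared accessory,
    exclusive-present per sorted niche, exclusive-absent per sorted niche,
    singletons per genome) so that identical config + seed always yields
    identical output.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    genome_ids = config.genome_ids
    niche_of = dict(config.niche_assignment or {})

    # (class label, carrier genome list) per planted family
    plan: list[tuple[str, list[str]]] = []
    plan.extend(("core", list(genome_ids)) for _ in range(config.n_core))
    for _ in range(config.n_shared_accessory):
        while True:
            mask = rng.random(len(genome_ids)) < config.p_acc
            if 1 < mask.sum() < len(genome_ids):
                break
        plan.append(("accessory", [g for g, m in zip(genome_ids, mask) if m]))
    for niche in sorted(config.n_exclusive_present):
        members = [g for g in genome_ids if niche_of[g] == niche]
        for _ in range(config.n_exclusive_present[niche]):
            while True:
                mask = rng.random(len(members)) < 0.7
                if mask.sum() >= 1:
                    break
            plan.append(
                (
                    f"exclusive_present:{niche}",
                    [g for g, m in zip(members, mask) if m],
                )
            )
    for niche in sorted(config.n_exclusive_absent):
        outside = [g for g in genome_ids if niche_of[g] != niche]
        for _ in range(config.n_exclusive_absent[niche]):
            plan.append((f"exclusive_absent:{niche}", list(outside)))
    for gid in genome_ids:
        plan.extend(("singleton", [gid]) for _ in range(config.n_singletons))

    genome_weights = {
        gid: gc_codon_weights(config.gc_targets.get(gid, config.gc_default))
        for gid in genome_ids
    }

    proteins: dict[str, list[tuple[str, str]]] = {g: [] for g in genome_ids}
    cds: dict[str, list[tuple[str, str]]] = {g: [] for g in genome_ids}
    gene_counter = {g: 0 for g in genome_ids}

    family_class: dict[str, str] = {}
    family_members: dict[str, set[tuple[str, str]]] = {}
    gene_family: dict[tuple[str, str], str] = {}

    def add_gene(fid: str, gid: str, protein: str) -> None:
        gene_counter[gid] += 1
        gene_id = f"g{gene_counter[gid]:05d}"
        proteins[gid].append((gene_id, protein))
        nt = back_translate(
            protein, genome_weights[gid], seed=int(rng.integers(2**31))
        )
        cds[gid].append((gene_id, nt))
        family_members[fid].add((gid, gene_id))
        gene_family[(gid, gene_id)] = fid

    for idx, (label, carriers) in enumerate(plan):
        fid = f"F{idx + 1:05d}"
        family_class[fid] = label
        family_members[fid] = set()
        ancestor = _random_protein(rng, _sample_length(rng, config))
        for gid in carriers:
            mutant = mutate_protein(
                ancestor, config.within_family_identity, seed=int(rng.integers(2**31))
            )
            add_gene(fid, gid, mutant)
            if config.paralog_rate > 0 and rng.random() < config.paralog_rate:
                paralog = mutate_protein(
                    ancestor,
                    config.within_family_identity,
                    seed=int(rng.integers(2**31)),
                )
                add_gene(fid, gid, paralog)

    records = [
        GenomeRecord(
            genome_id=gid,
            species=f"Synthetica sp. {gid}",
            niche=niche_of[gid],
            proteins=proteins[gid],
            cds=cds[gid],
        )
        for gid in genome_ids
    ]
    truth = SyntheticTruth(family_class, family_members, gene_family)
    return records, truth


def write_collection(
    records: list[GenomeRecord],
    truth: Optional[SyntheticTruth],
    outdir: str | Path,
) -> None:
    """Write per-genome FASTA files, the metadata table and truth tables."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    with open(outdir / "metadata.tsv", "w") as meta:
        meta.write("genome_id\tspecies\tniche\n")
        for rec in records:
            meta.write(f"{rec.genome_id}\t{rec.species}\t{rec.niche}\n")
            with open(outdir / f"{rec.genome_id}.faa", "w") as fh:
                for gene_id, seq in rec.proteins:
                    fh.write(f">{rec.genome_id}|{gene_id}\n{seq}\n")
            if rec.cds is not None:
                with open(outdir / f"{rec.genome_id}.fna", "w") as fh:
                    for gene_id, seq in rec.cds:
                        fh.write(f">{rec.genome_id}|{gene_id}\n{seq}\n")
    if truth is not None:
        with open(outdir / "truth_families.tsv", "w") as fh:
            fh.write("family_id\tclass\n")
            for fid in sorted(truth.family_class):
                fh.write(f"{fid}\t{truth.family_class[fid]}\n")
        with open(outdir / "truth_genes.tsv", "w") as fh:
            fh.write("genome_id\tgene_id\tfamily_id\n")
            for (gid, gene), fid in sorted(truth.gene_family.items()):
                fh.write(f"{gid}\t{gene}\t{fid}\n")
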