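"""Greedy incremental protein clustering into orthologous gene families.

Implements the CD-HIT-style scheme: proteins are sorted by decreasing
length, each sequence is compared against the representatives of existing
families in creation order and joins the first family whose representative
it matches at ≥ 50% identity with the aligned region covering ≥ 50% of the
shorter sequence; otherwise it founds a new family.  Within-genome
duplicates (paralogs) are removed afterwards, keeping the longest member
per genome.

Identity is defined as matches / aligned columns of the best local
alignment (gap columns included in the denominator); coverage of a sequence
is the fraction of its residues spanned by the locally aligned region.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional

from Bio import Align


@dataclass(frozen=True)
class Scoring:
    """Local-alignment scoring scheme (simple match/mismatch by default)."""

    match: float = 1.0
    mismatch: float = -1.0
    gap_open: float = -2.0
    gap_extend: float = -1.0


DEFAULT_SCORING = Scoring()


@dataclass
class PairAlignment:
    """Summary of the best local alignment of a sequence pair."""

    aligned_length: int
    matches: int
    identity: float
    coverage_a: float
    coverage_b: float


@dataclass
class GeneFamily:
    """An ortholog cluster: representative plus per-genome members.

    ``members`` and ``removed_paralogs`` map ``(genome_id, gene_id)`` to the
    member's sequence.
    """

    family_id: str
    representative: tuple[str, str]
    members: dict[tuple[str, str], str] = field(default_factory=dict)
    removed_paralogs: dict[tuple[str, str], str] = field(default_factory=dict)

    @property
    def genomes(self) -> set[str]:
        return {g for g, _ in self.members}

    @property
    def size(self) -> int:
        return len(self.members)


_ALIGNER_CACHE: dict[Scoring, Align.PairwiseAligner] = {}


def _make_aligner(scoring: Scoring) -> Align.PairwiseAligner:
    aligner = _ALIGNER_CACHE.get(scoring)
    if aligner is None:
        aligner = Align.PairwiseAligner()
        aligner.mode = "local"
        aligner.match_score = scoring.match
        aligner.mismatch_score = scoring.mismatch
        aligner.open_gap_score = scoring.gap_open
        aligner.extend_gap_score = scoring.gap_extend
        _ALIGNER_CACHE[scoring] = aligner
    return aligner


def align_pair(
    a: str, b: str, scoring: Scoring = DEFAULT_SCORING
) -> PairAlignment:
    """Best local alignment of two protein sequences.

    When no positive-scoring local alignment exists (e.g. disjoint
    alphabets) identity and both coverages are 0.
    """
    if not a or not b:
        raise ValueError("align_pair requires two non-empty sequences")
    aligner = _make_aligner(scoring)
    alignments = aligner.align(a, b)
    if alignments.score <= 0:
        return PairAlignment(0, 0, 0.0, 0.0, 0.0)
    aln = alignments[0]
    counts = aln.counts()
    matches = counts.identities
    aligned_length = aln.length
    blocks_a, blocks_b = aln.aligned
    span_a = blocks_a[-1][1] - blocks_a[0][0]
    span_b = blocks_b[-1][1] - blocks_b[0][0]
    return PairAlignment(
        aligned_length=aligned_length,
        matches=matches,
        identity=matches / aligned_length if aligned_length else 0.0,
        coverage_a=span_a / len(a),
        coverage_b=span_b / len(b),
    )


def _kmer_set(seq: str, k: int = 4) -> frozenset[str]:
    return frozenset(seq[i : i + k] for i in range(len(seq) - k + 1))


def matches_family(
    rep_seq: str,
    seq: str,
    identity_thr: float,
    coverage_thr: float,
    scoring: Scoring = DEFAULT_SCORING,
    coverage_mode: str = "shorter",
) -> bool:
    """Membership rule: identity ≥ threshold and coverage ≥ threshold.

    ``coverage_mode='shorter'`` (default) requires the aligned region to
    cover the configured fraction of the shorter sequence; ``'both'``
    requires it of both sequences.
    """
    aln = align_pair(rep_seq, seq, scoring)
    if aln.identity < identity_thr:
        return False
    if coverage_mode == "shorter":
        cov = aln.coverage_a if len(rep_seq) <= len(seq) else aln.coverage_b
        return cov >= coverage_thr
    if coverage_mode == "both":
        return min(aln.coverage_a, aln.coverage_b) >= coverage_thr
    raise ValueError(f"unknown coverage_mode {coverage_mode!r}")


def greedy_cluster(
    proteins: Iterable[tuple[str, str, str]],
    identity_thr: float = 0.5,
    coverage_thr: float = 0.5,
    scoring: Scoring = DEFAULT_SCORING,
    coverage_mode: str = "shorter",
    prescreen_min_kmers: Optional[int] = None,
) -> list[GeneFamily]:
    """Cluster ``(genome_id, gene_id, sequence)`` triples into families.

    Sequences are processed in order of decreasing length (ties broken by
    lexicographically smaller gene id, then genome id); each joins the first
    existing family whose representative it matches, else founds a new
    family.  ``prescreen_min_kmers``, when set, skips the alignment against
    representatives sharing fewer than that many 4-mers with the query — a
    speed filter only; it is applied only when both sequences have ≥ 100
    residues (related proteins of that length share exact 4-mers with
    overwhelming probability, while unrelated ones rarely do), so short
    sequences are always aligned and results match the unfiltered rule.
    """
    if not (0.0 < identity_thr <= 1.0) or not (0.0 < coverage_thr <= 1.0):
        raise ValueError("identity and coverage thresholds must lie in (0, 1]")
    entries = list(proteins)
    seen: set[tuple[str, str]] = set()
    for genome_id, gene_id, seq in entries:
        if not seq:
            raise ValueError(f"empty sequence for {genome_id}|{gene_id}")
        key = (genome_id, gene_id)
        if key in seen:
            raise ValueError(f"duplicate gene id {gene_id!r} in genome {genome_id!r}")
        seen.add(key)
    entries.sort(key=lambda e: (-len(e[2]), e[1], e[0]))

    families: list[GeneFamily] = []
    rep_seqs: list[str] = []
    rep_kmers: list[frozenset[str]] = []
    for genome_id, gene_id, seq in entries:
        query_kmers = _kmer_set(seq) if prescreen_min_kmers else None
        placed = False
        for idx, fam in enumerate(families):
            if (
                query_kmers is not None
                and len(seq) >= 100
                and len(rep_seqs[idx]) >= 100
                and len(query_kmers & rep_kmers[idx]) < prescreen_min_kmers
            ):
                continue
            if matches_family(
                rep_seqs[idx], seq, identity_thr, coverage_thr, scoring, coverage_mode
            ):
                fam.members[(genome_id, gene_id)] = seq
                placed = True
                break
        if not placed:
            fam = GeneFamily(
                family_id=f"FAM{len(families) + 1:05d}",
                representative=(genome_id, gene_id),
                members={(genome_id, gene_id): seq},
            )
            families.append(fam)
            rep_seqs.append(seq)
            rep_kmers.append(_kmer_set(seq) if prescreen_min_kmers else frozenset())
    return families


def remove_paralogs(families: list[GeneFamily]) -> list[GeneFamily]:
    """Keep one member per genome per family (longest; ties by gene id).

    Returns new GeneFamily objects; removed members are recorded in
    ``removed_paralogs``.  The family count never changes.
    """
    out: list[GeneFamily] = []
    for fam in families:
        by_genome: dict[str, list[tuple[str, str]]] = {}
        for (genome_id, gene_id), seq in fam.members.items():
            by_genome.setdefault(genome_id, []).append((gene_id, seq))
        members: dict[tuple[str, str], str] = {}
        removed: dict[tuple[str, str], str] = dict(fam.removed_paralogs)
        for genome_id, genes in by_genome.items():
            genes.sort(key=lambda e: (-len(e[1]), e[0]))
            keep_id, keep_seq = genes[0]
            members[(genome_id, keep_id)] = keep_seq
            for gene_id, seq in genes[1:]:
                removed[(genome_id, gene_id)] = seq
        rep = fam.representative
        if rep not in members:
            # representative was a paralog; promote the retained member
            genome = rep[0]
            rep = next(k for k in members if k[0] == genome)
        out.append(
            GeneFamily(
                family_id=fam.family_id,
                representative=rep,
                members=members,
                removed_paralogs=removed,
            )
        )
    return out
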