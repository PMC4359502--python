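"""Pairwise dN/dS screening by Nei–Gojobori counting.

For each orthologous CDS pair the translated proteins are globally aligned,
the alignment is mapped back to codon triplets and gapped or ambiguous
columns are dropped.  Unweighted Nei–Gojobori (1986) counting is then
applied:

* synonymous site count of a codon = Σ over its 3 positions of the
  fraction of the 3 possible single-base changes that are synonymous;
  changes producing a stop codon are excluded and the remaining changes at
  that position renormalized.  Site totals are averaged between the two
  sequences, so N + S = 3 × retained codons exactly.
* differences per codon pair are resolved by averaging, with equal weight,
  over all minimal substitution pathways between the codons; pathway steps
  passing through a stop codon are excluded (if every pathway hits a stop,
  all pathways are used with stop steps counted as nonsynonymous).
* proportions pN = Nd/N and pS = Sd/S receive the Jukes–Cantor correction
  d = −(3/4)·ln(1 − 4p/3), undefined for p ≥ 3/4.

dN/dS > 1 flags positive selection (strict inequality); the ratio is
undefined when dS = 0 or either distance is undefined, and such pairs are
reported separately, never flagged.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from functools import lru_cache
from typing import Iterable, Literal, Optional

from Bio import Align

from .records import CODON_TO_AA, STOP_CODONS

_BASES = "ACGT"


@dataclass
class CodonAlignment:
    """Gap-free aligned codon pairs plus the count of excluded columns."""

    pairs: list[tuple[str, str]]
    n_excluded: int


@dataclass
class DnDsEstimate:
    n_codons: int
    N: float
    S: float
    Nd: float
    Sd: float
    pN: float
    pS: float
    dN: Optional[float]
    dS: Optional[float]
    ratio: Optional[float]
    flag: Literal["positive", "not_positive", "undefined"]


_CODON_ALIGNER: Optional[Align.PairwiseAligner] = None


def _aligner() -> Align.PairwiseAligner:
    global _CODON_ALIGNER
    if _CODON_ALIGNER is None:
        a = Align.PairwiseAligner()
        a.mode = "global"
        a.substitution_matrix = Align.substitution_matrices.load("BLOSUM62")
        a.open_gap_score = -11
        a.extend_gap_score = -1
        _CODON_ALIGNER = a
    return _CODON_ALIGNER


def _validated_protein(cds: str, which: str) -> str:
    if len(cds) % 3 != 0:
        raise ValueError(f"CDS {which} has length {len(cds)}, not divisible by 3")
    for i in range(0, len(cds) - 3, 3):
        if cds[i : i + 3].upper() in STOP_CODONS:
            raise ValueError(
                f"internal stop codon in CDS {which} at nucleotide position {i}"
            )
    seq = cds.upper()
    if seq[-3:] in STOP_CODONS:  # trailing stop is tolerated and trimmed
        seq = seq[:-3]
    # ambiguous codons translate as 'X' placeholders and are excluded later
    residues = []
    for i in range(0, len(seq), 3):
        residues.append(CODON_TO_AA.get(seq[i : i + 3], "X"))
    return "".join(residues)


def codon_align(cds_a: str, cds_b: str) -> CodonAlignment:
    """Codon-level alignment of two CDSs via their translated proteins."""
    a = cds_a.upper()
    b = cds_b.upper()
    prot_a = _validated_protein(a, "a")
    prot_b = _validated_protein(b, "b")
    a = a[: 3 * len(prot_a)]
    b = b[: 3 * len(prot_b)]
    aln = _aligner().align(prot_a.replace("X", "A"), prot_b.replace("X", "A"))[0]
    ia = ib = 0
    pairs: list[tuple[str, str]] = []
    excluded = 0
    for col_a, col_b in zip(str(aln[0]), str(aln[1])):
        if col_a == "-" or col_b == "-":
            excluded += 1
            if col_a != "-":
                ia += 1
            if col_b != "-":
                ib += 1
            continue
        codon_a = a[3 * ia : 3 * ia + 3]
        codon_b = b[3 * ib : 3 * ib + 3]
        ia += 1
        ib += 1
        if set(codon_a) <= set(_BASES) and set(codon_b) <= set(_BASES):
            pairs.append((codon_a, codon_b))
        else:
            excluded += 1
    return CodonAlignment(pairs=pairs, n_excluded=excluded)


@lru_cache(maxsize=None)
def synonymous_sites(codon: str) -> float:
    """Synonymous site count of a sense codon (0..3).

    Per position, the fraction of single-base changes that preserve the
    amino acid, with changes to stop codons removed and the fraction
    renormalized over the remaining changes.
    """
    aa = CODON_TO_AA[codon]
    total = 0.0
    for pos in range(3):
        syn = considered = 0
        for base in _BASES:
            if base == codon[pos]:
                continue
            mutant = codon[:pos] + base + codon[pos + 1 :]
            if mutant in STOP_CODONS:
                continue
            considered += 1
            if CODON_TO_AA[mutant] == aa:
                syn += 1
        if considered:
            total += syn / considered
    return total


@lru_cache(maxsize=None)
def pathway_differences(codon_a: str, codon_b: str) -> tuple[float, float]:
    """(synonymous, nonsynonymous) difference counts for one codon pair.

    Averages with equal weight over all minimal substitution pathways;
    pathways passing through a stop codon are discarded (with a fallback to
    all pathways, stop steps counted nonsynonymous, if none survive).
    """
    diff_pos = [i for i in range(3) if codon_a[i] != codon_b[i]]
    if not diff_pos:
        return 0.0, 0.0

    def walk(order: tuple[int, ...], allow_stops: bool) -> Optional[tuple[int, int]]:
        syn = non = 0
        current = codon_a
        for pos in order:
            nxt = current[:pos] + codon_b[pos] + current[pos + 1 :]
            if nxt in STOP_CODONS and not allow_stops:
                return None
            aa_from = CODON_TO_AA.get(current)
            aa_to = CODON_TO_AA.get(nxt)
            if aa_from is not None and aa_to is not None and aa_from == aa_to:
                syn += 1
            else:
                non += 1
            current = nxt
        return syn, non

    results = [
        r
        for order in itertools.permutations(diff_pos)
        if (r := walk(order, allow_stops=False)) is not None
    ]
    if not results:
        results = [walk(order, allow_stops=True) for order in itertools.permutations(diff_pos)]
    syn = sum(r[0] for r in results) / len(results)
    non = sum(r[1] for r in results) / len(results)
    return syn, non


def jukes_cantor(p: float) -> Optional[float]:
    """JC-corrected distance; None when p ≥ 3/4 (correction undefined)."""
    if p >= 0.75:
        return None
    return -0.75 * math.log(1.0 - 4.0 * p / 3.0)


def nei_gojobori(aln: CodonAlignment) -> DnDsEstimate:
    """Unweighted Nei–Gojobori estimate over a codon alignment."""
    if not aln.pairs:
        raise ValueError("empty codon alignment")
    S = N = Sd = Nd = 0.0
    for codon_a, codon_b in aln.pairs:
        s_a = synonymous_sites(codon_a)
        s_b = synonymous_sites(codon_b)
        s_avg = (s_a + s_b) / 2.0
        S += s_avg
        N += 3.0 - s_avg
        sd, nd = pathway_differences(codon_a, codon_b)
        Sd += sd
        Nd += nd
    pS = Sd / S if S > 0 else 0.0
    pN = Nd / N if N > 0 else 0.0
    dS = jukes_cantor(pS) if S > 0 else None
    dN = jukes_cantor(pN) if N > 0 else None
    if dN is None or dS is None:
        ratio = None
        flag = "undefined"
    elif dS == 0.0:
        ratio = None
        flag = "undefined" if dN > 0 else "not_positive"
    else:
        ratio = dN / dS
        flag = "positive" if ratio > 1.0 else "not_positive"
    return DnDsEstimate(
        n_codons=len(aln.pairs),
        N=N,
        S=S,
        Nd=Nd,
        Sd=Sd,
        pN=pN,
        pS=pS,
        dN=dN,
        dS=dS,
        ratio=ratio,
        flag=flag,
    )


@dataclass
class SelectionReport:
    """Positive-selection screen over many ortholog pairs."""

    flagged: list[str]  # defined ratio > 1 and enough codons
    undefined: list[str]  # ratio undefined (dS = 0 or saturated)
    too_short: list[str]  # defined ratio > 1 but below the codon gate


def flag_positive_selection(
    estimates: Iterable[tuple[str, DnDsEstimate]], min_codons: int = 100
) -> SelectionReport:
    """Pairs under positive selection (dN/dS strictly > 1).

    ``min_codons`` gates flagging to alignments with enough retained codons
    to make the ratio meaningful; shorter would-be hits are reported in
    ``too_short``.  Undefined-ratio pairs are listed separately and never
    flagged.
    """
    flagged: list[str] = []
    undefined: list[str] = []
    too_short: list[str] = []
    for pair_id, est in estimates:
        if est.ratio is None:
            if est.flag == "undefined":
                undefined.append(pair_id)
            continue
        if est.ratio > 1.0:
            if est.n_codons >= min_codons:
                flagged.append(pair_id)
            else:
                too_short.append(pair_id)
    return SelectionReport(flagged=flagged, undefined=undefined, too_short=too_short)
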