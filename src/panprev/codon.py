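"""Codon usage profiles, squared-difference codon distances and GC content.

A genome's codon profile is the vector of relative frequencies of the 61
sense codons over its core gene set (codons read in frame 1 across the
concatenated CDSs; stop codons and codons with non-ACGT characters are
excluded from both numerator and denominator).  The distance between two
genomes is the sum of squared frequency differences over all codons:

    d(i, j) = Σ_t (f_t,i − f_t,j)²

which tracks genomic G+C bias: GC-divergent genomes prefer different
synonymous codons, inflating the squared differences.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .records import SENSE_CODONS, STOP_CODONS
from .trees import DistanceMatrix

ALL_CODONS: tuple[str, ...] = tuple(sorted(SENSE_CODONS) + sorted(STOP_CODONS))


@dataclass
class CodonProfile:
    genome_id: str
    codons: tuple[str, ...]  # the codon vocabulary, fixed order
    freqs: np.ndarray  # relative frequencies, sums to 1
    total: int  # codons counted

    def as_series(self) -> pd.Series:
        return pd.Series(self.freqs, index=list(self.codons), name=self.genome_id)


def codon_profile(
    cds_set: Iterable[str], genome_id: str = "", include_stops: bool = False
) -> CodonProfile:
    """Relative codon frequencies over a set of frame-1 CDSs.

    With ``include_stops=False`` (default) the vocabulary is the 61 sense
    codons; stop codons are skipped entirely.  ``include_stops=True``
    switches to the full 64-codon vocabulary.
    """
    vocab = ALL_CODONS if include_stops else SENSE_CODONS
    index = {c: i for i, c in enumerate(vocab)}
    counts = np.zeros(len(vocab), dtype=np.int64)
    for seq in cds_set:
        seq = seq.upper()
        if len(seq) % 3 != 0:
            raise ValueError(
                f"CDS of length {len(seq)} is not divisible by 3 "
                f"(starts {seq[:12]!r})"
            )
        for i in range(0, len(seq), 3):
            codon = seq[i : i + 3]
            pos = index.get(codon)
            if pos is not None:
                counts[pos] += 1
    total = int(counts.sum())
    if total == 0:
        raise ValueError("no countable codons in the CDS set")
    return CodonProfile(genome_id, vocab, counts / total, total)


def codon_distance(p: CodonProfile, q: CodonProfile) -> float:
    """Squared-difference codon usage distance Σ_t (f_t,p − f_t,q)²."""
    if p.codons != q.codons:
        raise ValueError("profiles are over different codon sets")
    return float(np.sum((p.freqs - q.freqs) ** 2))


def codon_distance_matrix(profiles: Sequence[CodonProfile]) -> DistanceMatrix:
    """Symmetric genome × genome matrix of codon usage distances."""
    if len(profiles) < 2:
        raise ValueError("need at least 2 profiles")
    ids = [p.genome_id for p in profiles]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate genome ids among profiles")
    n = len(profiles)
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            out[i, j] = out[j, i] = codon_distance(profiles[i], profiles[j])
    return DistanceMatrix(ids, out)


def profiles_table(profiles: Sequence[CodonProfile]) -> pd.DataFrame:
    """Per-genome frequency table (one column per codon)."""
    return pd.DataFrame([p.as_series() for p in profiles])


def gc_content(seqs: Iterable[str]) -> float:
    """(G+C) / (A+C+G+T) over all sequences; ambiguous characters ignored."""
    gc = at = 0
    for seq in seqs:
        seq = seq.upper()
        gc += seq.count("G") + seq.count("C")
        at += seq.count("A") + seq.count("T")
    if gc + at == 0:
        raise ValueError("no countable A/C/G/T bases in input")
    return gc / (gc + at)
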