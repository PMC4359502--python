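"""Nei–Gojobori counting against a brute-force codon-pair enumerator."""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from panprev import (
    codon_align,
    flag_positive_selection,
    nei_gojobori,
)
from panprev.dnds import DnDsEstimate, CodonAlignment, pathway_differences, synonymous_sites
from panprev.records import CODON_TO_AA, SENSE_CODONS, STOP_CODONS

BASES = "ACGT"


# ---------------------------------------------------------------- oracle --
def oracle_syn_sites(codon: str) -> float:
    """Independent per-codon synonymous site count (loop-free re-derivation)."""
    total = 0.0
    for pos in range(3):
        changes = [
            codon[:pos] + b + codon[pos + 1:]
            for b in BASES
            if b != codon[pos]
        ]
        non_stop = [m for m in changes if m not in STOP_CODONS]
        if non_stop:
            syn = sum(CODON_TO_AA[m] == CODON_TO_AA[codon] for m in non_stop)
            total += syn / len(non_stop)
    return total


def oracle_pathways(a: str, b: str) -> tuple[float, float]:
    """Recursive pathway enumeration of (syn, nonsyn) differences."""
    diff = [i for i in range(3) if a[i] != b[i]]
    if not diff:
        return 0.0, 0.0

    def paths(cur: str, remaining: tuple[int, ...]):
        if not remaining:
            yield []
            return
        for k, pos in enumerate(remaining):
            nxt = cur[:pos] + b[pos] + cur[pos + 1:]
            for rest in paths(nxt, remaining[:k] + remaining[k + 1:]):
                yield [(cur, nxt)] + rest

    def score(path, allow_stop):
        syn = non = 0
        for frm, to in path:
            if to in STOP_CODONS and not allow_stop:
                return None
            if CODON_TO_AA.get(frm) == CODON_TO_AA.get(to) and frm not in STOP_CODONS \
                    and to not in STOP_CODONS:
                syn += 1
            else:
                non += 1
        return syn, non

    all_paths = list(paths(a, tuple(diff)))
    scored = [s for p in all_paths if (s := score(p, False)) is not None]
    if not scored:
        scored = [score(p, True) for p in all_paths]
    return (
        sum(s for s, _ in scored) / len(scored),
        sum(n for _, n in scored) / len(scored),
    )


# ----------------------------------------------------------------- tests --
class TestCodonAlign:
    def test_identical_sequences_fully_retained(self):
        cds = "ATGAAACCCGGG" * 25
        aln = codon_align(cds, cds)
        assert len(aln.pairs) == 100
        assert aln.n_excluded == 0

    def test_codon_deletion_excluded(self):
        a = "ATGAAACCCGGGTTT"
        b = "ATGAAAGGGTTT"  # CCC deleted
        aln = codon_align(a, b)
        assert len(aln.pairs) == 4
        assert aln.n_excluded == 1

    def test_ambiguous_codon_excluded(self):
        a = "ATGNNNCCC"
        b = "ATGAAACCC"
        aln = codon_align(a, b)
        assert len(aln.pairs) == 2
        assert aln.n_excluded == 1

    def test_internal_stop_rejected_with_position(self):
        with pytest.raises(ValueError, match="position 3"):
            codon_align("ATGTAAAAA", "ATGAAAAAA")

    def test_trailing_stop_tolerated(self):
        aln = codon_align("ATGAAATAA", "ATGAAATGA")
        assert len(aln.pairs) == 2


class TestSitesOracle:
    def test_all_61_codons_match_enumeration(self):
        for codon in SENSE_CODONS:
            assert synonymous_sites(codon) == pytest.approx(
                oracle_syn_sites(codon), abs=1e-12
            ), codon

    def test_ttt_worked_example(self):
        # only TTT→TTC (pos 3) is synonymous: S = 1/3, N = 8/3
        assert synonymous_sites("TTT") == pytest.approx(1 / 3)

    def test_site_conservation(self):
        rng = np.random.default_rng(2)
        codons = rng.choice(list(SENSE_CODONS), size=200)
        aln = CodonAlignment([(c, c) for c in codons], 0)
        est = nei_gojobori(aln)
        assert est.N + est.S == pytest.approx(3 * 200, abs=1e-9)


class TestPathwayOracle:
    def test_all_pairs_match_enumeration(self):
        """Per-pair (Sd, Nd) equal the brute-force enumerator, 61×61."""
        for a, b in itertools.product(SENSE_CODONS, repeat=2):
            got = pathway_differences(a, b)
            exp = oracle_pathways(a, b)
            assert got == pytest.approx(exp, abs=1e-12), (a, b)

    def test_single_synonymous_change(self):
        sd, nd = pathway_differences("TTT", "TTC")
        assert (sd, nd) == (1.0, 0.0)


class TestEstimates:
    def test_identical_sequences_not_positive(self):
        aln = codon_align("ATGAAACCC" * 40, "ATGAAACCC" * 40)
        est = nei_gojobori(aln)
        assert est.Nd == est.Sd == 0
        assert est.dN == est.dS == 0.0
        assert est.ratio is None
        assert est.flag == "not_positive"

    def test_single_ttt_ttc_pair_saturates(self):
        est = nei_gojobori(CodonAlignment([("TTT", "TTC")], 0))
        assert est.Sd == 1 and est.Nd == 0
        assert est.S == pytest.approx(1 / 3)
        assert est.N == pytest.approx(8 / 3)
        assert est.pS == pytest.approx(3.0)
        assert est.dS is None
        assert est.flag == "undefined"

    def test_symmetry(self):
        rng = np.random.default_rng(9)
        codons_a = rng.choice(list(SENSE_CODONS), size=120)
        pairs_ab = []
        for ca in codons_a:
            cb = ca
            if rng.random() < 0.2:
                cb = str(rng.choice(list(SENSE_CODONS)))
            pairs_ab.append((ca, cb))
        est_ab = nei_gojobori(CodonAlignment(pairs_ab, 0))
        est_ba = nei_gojobori(CodonAlignment([(b, a) for a, b in pairs_ab], 0))
        for fld in ("N", "S", "Nd", "Sd"):
            assert getattr(est_ab, fld) == pytest.approx(getattr(est_ba, fld))

    def test_planted_changes_counted(self):
        """100 codons with 6 synonymous + 1 nonsynonymous planted changes."""
        base = ["GGT"] * 100  # glycine, GGx all synonymous
        mutant = list(base)
        for i in range(6):
            mutant[i] = "GGC"  # synonymous third-position change
        mutant[50] = "GTT"  # G→V, nonsynonymous
        aln = CodonAlignment(list(zip(base, mutant)), 0)
        est = nei_gojobori(aln)
        assert est.Sd == pytest.approx(6.0)
        assert est.Nd == pytest.approx(1.0)
        assert est.ratio is not None and est.ratio < 1
        assert est.flag == "not_positive"
        # cross-check totals against the oracle
        S = sum((oracle_syn_sites(a) + oracle_syn_sites(b)) / 2
                for a, b in aln.pairs)
        assert est.S == pytest.approx(S)

    def test_neutral_simulation_median_near_one(self):
        """Substitutions applied regardless of codon effect → dN/dS ≈ 1."""
        rng = np.random.default_rng(31)
        ratios = []
        flagged = 0
        n_reps = 120
        for _ in range(n_reps):
            codons = list(rng.choice(list(SENSE_CODONS), size=300))
            mutated = []
            for codon in codons:
                out = codon
                for pos in range(3):
                    if rng.random() < 0.04:
                        base = BASES[rng.integers(4)]
                        cand = out[:pos] + base + out[pos + 1:]
                        if cand not in STOP_CODONS:
                            out = cand
                mutated.append(out)
            est = nei_gojobori(CodonAlignment(list(zip(codons, mutated)), 0))
            if est.ratio is not None:
                ratios.append(est.ratio)
                if est.ratio > 1:
                    flagged += 1
        assert len(ratios) > 100
        med = float(np.median(ratios))
        assert 0.85 < med < 1.15
        assert 0.15 < flagged / len(ratios) < 0.85


class TestFlagging:
    def _est(self, ratio, n_codons=200):
        return DnDsEstimate(
            n_codons=n_codons, N=400, S=200, Nd=10, Sd=5, pN=0.025, pS=0.025,
            dN=0.03 if ratio is not None else None,
            dS=(0.03 / ratio if ratio else None),
            ratio=ratio,
            flag="positive" if (ratio or 0) > 1 else "not_positive",
        )

    def test_ratio_above_one_flagged(self):
        report = flag_positive_selection([("p1", self._est(1.5))])
        assert report.flagged == ["p1"]

    def test_ratio_exactly_one_not_flagged(self):
        report = flag_positive_selection([("p1", self._est(1.0))])
        assert report.flagged == []

    def test_undefined_reported_separately(self):
        est = DnDsEstimate(200, 400, 200, 10, 0, 0.025, 0.0, 0.03, None, None,
                           "undefined")
        report = flag_positive_selection([("p1", est)])
        assert report.flagged == []
        assert report.undefined == ["p1"]

    def test_codon_gate_applies(self):
        report = flag_positive_selection([("p1", self._est(1.5, n_codons=20))])
        assert report.flagged == []
        assert report.too_short == ["p1"]
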