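"""Clustering: alignment engine, greedy rule, paralog removal, recovery."""

from __future__ import annotations

import numpy as np
import pytest

from panprev import (
    GeneFamily,
    SimConfig,
    align_pair,
    generate_collection,
    greedy_cluster,
    mutate_protein,
    remove_paralogs,
)
from panprev.cluster import matches_family
from panprev.io import collection_proteins

from conftest import random_protein


def sw_score(a: str, b: str, match=1.0, mismatch=-1.0, open_=-2.0, ext=-1.0) -> float:
    """Gotoh local-alignment score, independent dynamic-programming oracle."""
    n, m = len(a), len(b)
    NEG = -1e18
    H = np.zeros((n + 1, m + 1))
    E = np.full((n + 1, m + 1), NEG)  # gap in a (consume b)
    F = np.full((n + 1, m + 1), NEG)  # gap in b (consume a)
    best = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            E[i][j] = max(H[i][j - 1] + open_, E[i][j - 1] + ext)
            F[i][j] = max(H[i - 1][j] + open_, F[i - 1][j] + ext)
            s = match if a[i - 1] == b[j - 1] else mismatch
            H[i][j] = max(0.0, H[i - 1][j - 1] + s, E[i][j], F[i][j])
            best = max(best, H[i][j])
    return best


def naive_greedy_cluster(proteins, identity_thr=0.5, coverage_thr=0.5):
    """Rule-literal greedy clustering without any prescreen speedups."""
    entries = sorted(proteins, key=lambda e: (-len(e[2]), e[1], e[0]))
    reps: list[str] = []
    assignment: list[list[tuple[str, str]]] = []
    for genome_id, gene_id, seq in entries:
        for idx, rep in enumerate(reps):
            if matches_family(rep, seq, identity_thr, coverage_thr):
                assignment[idx].append((genome_id, gene_id))
                break
        else:
            reps.append(seq)
            assignment.append([(genome_id, gene_id)])
    return [frozenset(members) for members in assignment]


class TestAlignPair:
    def test_self_alignment(self):
        aln = align_pair("MKVLAQWERTY", "MKVLAQWERTY")
        assert aln.identity == 1.0
        assert aln.coverage_a == aln.coverage_b == 1.0

    def test_disjoint_alphabets_score_zero(self):
        aln = align_pair("AAAA", "TTTT")
        assert aln.identity == 0.0
        assert aln.coverage_a == aln.coverage_b == 0.0

    def test_trailing_mismatch_trimmed_by_local_alignment(self):
        # best local alignment of MKVLA/MKVLG is the 4-column exact block
        # MKVL (score 4), not the 5-column one including the mismatch
        aln = align_pair("MKVLA", "MKVLG")
        assert aln.aligned_length == 4
        assert aln.matches == 4
        assert aln.identity == 1.0

    @pytest.mark.parametrize("seed", range(12))
    def test_alignment_score_matches_dp_oracle(self, seed):
        rng = np.random.default_rng(seed)
        a = random_protein(rng, int(rng.integers(10, 40)))
        b = mutate_protein(a, 0.7, seed) if seed % 2 else random_protein(
            rng, int(rng.integers(10, 40))
        )
        oracle = sw_score(a, b)
        from Bio import Align

        aligner = Align.PairwiseAligner()
        aligner.mode = "local"
        aligner.match_score = 1
        aligner.mismatch_score = -1
        aligner.open_gap_score = -2
        aligner.extend_gap_score = -1
        assert aligner.align(a, b).score == pytest.approx(oracle)
        # PairAlignment internals consistent with the optimal alignment
        aln = align_pair(a, b)
        if oracle > 0:
            assert aln.matches <= aln.aligned_length
            assert 0 < aln.identity <= 1

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            align_pair("", "MK")


class TestGreedyCluster:
    def test_identical_sequences_one_family(self):
        seq = "MKVLAQWERTYL"
        proteins = [(f"G{i}", "g1", seq) for i in range(5)]
        families = greedy_cluster(proteins)
        assert len(families) == 1
        assert families[0].size == 5

    def test_dissimilar_sequences_stay_apart(self):
        rng = np.random.default_rng(4)
        proteins = [
            ("G1", "a", random_protein(rng, 200)),
            ("G2", "b", random_protein(rng, 200)),
            ("G3", "c", random_protein(rng, 200)),
        ]
        # the membership rule rejects every cross pair (oracle check first)
        for i in range(3):
            for j in range(3):
                if i != j:
                    assert not matches_family(
                        proteins[i][2], proteins[j][2], 0.5, 0.5
                    )
        assert len(greedy_cluster(proteins)) == 3

    def test_sixty_percent_identity_pair_joins(self):
        rng = np.random.default_rng(8)
        a = random_protein(rng, 200)
        b = mutate_protein(a, 0.6, seed=2)
        c = random_protein(rng, 200)
        assert matches_family(a, b, 0.5, 0.5)
        families = greedy_cluster([("G1", "a", a), ("G2", "b", b), ("G3", "c", c)])
        grouped = sorted(
            tuple(sorted(g for g, _ in fam.members)) for fam in families
        )
        assert grouped == [("G1", "G2"), ("G3",)]

    def test_duplicate_gene_id_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            greedy_cluster([("G1", "x", "MKVLA"), ("G1", "x", "MKVLA")])

    def test_partition_property(self, clustered_two_niche):
        records, _, families, _, _ = clustered_two_niche
        all_genes = {(r.genome_id, g) for r in records for g in r.gene_ids}
        clustered = [
            gene
            for fam in families
            for gene in list(fam.members) + list(fam.removed_paralogs)
        ]
        assert len(clustered) == len(all_genes)
        assert set(clustered) == all_genes

    def test_threshold_monotonicity(self):
        rng = np.random.default_rng(11)
        proteins = []
        for f in range(5):
            anc = random_protein(rng, 100)
            for g in range(3):
                proteins.append((f"G{g}", f"f{f}", mutate_protein(anc, 0.75, f * 3 + g)))
        counts = [
            len(greedy_cluster(proteins, identity_thr=thr))
            for thr in (0.3, 0.5, 0.7, 0.9)
        ]
        assert counts == sorted(counts)

    @pytest.mark.parametrize("seed", range(20))
    def test_greedy_equals_rule_literal_oracle(self, seed):
        """greedy_cluster matches a naive re-implementation of the rule."""
        rng = np.random.default_rng(seed)
        n_fam = int(rng.integers(2, 8))
        proteins = []
        idx = 0
        for f in range(n_fam):
            anc = random_protein(rng, int(rng.integers(40, 90)))
            for _ in range(int(rng.integers(1, 5))):
                idx += 1
                proteins.append(
                    (f"G{idx % 4}", f"g{idx:03d}",
                     mutate_protein(anc, 0.75, int(rng.integers(2**31))))
                )
        proteins = proteins[:30]
        got = greedy_cluster(proteins)
        got_sets = {frozenset(f.members) for f in got}
        assert got_sets == set(naive_greedy_cluster(proteins))
        assert len(got) == len(got_sets)

    @pytest.mark.parametrize("seed", range(6))
    def test_prescreen_agrees_at_protein_scale(self, seed):
        """The 4-mer prescreen does not change results on collections of
        realistic-length proteins (≥ 100 residues, ≥ 0.75 identity)."""
        rng = np.random.default_rng(100 + seed)
        proteins = []
        idx = 0
        for f in range(int(rng.integers(3, 7))):
            anc = random_protein(rng, int(rng.integers(120, 250)))
            for _ in range(int(rng.integers(1, 5))):
                idx += 1
                proteins.append(
                    (f"G{idx % 4}", f"g{idx:03d}",
                     mutate_protein(anc, 0.8, int(rng.integers(2**31))))
                )
        fast = greedy_cluster(proteins, prescreen_min_kmers=1)
        plain = greedy_cluster(proteins)
        assert {frozenset(f.members) for f in fast} == {
            frozenset(f.members) for f in plain
        }


class TestRemoveParalogs:
    def test_longest_member_retained(self):
        fam = GeneFamily(
            "FAM1",
            ("g1", "x"),
            members={("g1", "x"): "M" * 300, ("g1", "y"): "M" * 250,
                     ("g2", "z"): "M" * 280},
        )
        (out,) = remove_paralogs([fam])
        assert set(out.members) == {("g1", "x"), ("g2", "z")}
        assert set(out.removed_paralogs) == {("g1", "y")}

    def test_no_paralogs_unchanged(self):
        fam = GeneFamily(
            "FAM1", ("g1", "x"), members={("g1", "x"): "MKV", ("g2", "y"): "MKV"}
        )
        (out,) = remove_paralogs([fam])
        assert out.members == fam.members
        assert not out.removed_paralogs

    def test_removed_genes_share_genome_with_retained(self):
        cfg = SimConfig(
            n_genomes=4,
            niche_assignment={f"G{i}": "GIT" for i in range(4)},
            n_core=15,
            n_shared_accessory=0,
            n_singletons=2,
            paralog_rate=0.3,
            protein_length_mean=100,
            protein_length_sd=20,
            seed=6,
        )
        records, truth = generate_collection(cfg)
        families = remove_paralogs(
            greedy_cluster(collection_proteins(records), prescreen_min_kmers=1)
        )
        removed_any = False
        for fam in families:
            genomes_retained = {g for g, _ in fam.members}
            for genome_id, gene_id in fam.removed_paralogs:
                removed_any = True
                assert genome_id in genomes_retained
                # removed gene is planted in the same truth family as a
                # retained member of that genome
                fid = truth.gene_family[(genome_id, gene_id)]
                retained_fids = {
                    truth.gene_family[key]
                    for key in fam.members
                    if key[0] == genome_id
                }
                assert fid in retained_fids
        assert removed_any


class TestRecovery:
    def test_families_equal_planted_truth(self, clustered_two_niche):
        _, truth, families, _, _ = clustered_two_niche
        recovered = {
            frozenset(list(f.members) + list(f.removed_paralogs)) for f in families
        }
        planted = {frozenset(m) for m in truth.family_members.values()}
        assert recovered == planted
        assert len(families) == len(truth.family_members)

    def test_rule_separation_within_vs_between(self, two_niche_collection):
        """Every within-family pair passes the membership rule; no
        between-family pair does (identity AND coverage jointly)."""
        records, truth = two_niche_collection
        seqs = {
            (r.genome_id, g): s for r in records for g, s in r.proteins
        }
        fams = [m for m in truth.family_members.values() if len(m) > 1][:6]
        for members in fams:
            pairs = sorted(members)
            for i in range(len(pairs) - 1):
                assert matches_family(
                    seqs[pairs[i]], seqs[pairs[i + 1]], 0.5, 0.5
                )
        rng = np.random.default_rng(0)
        fam_ids = sorted(truth.family_members)
        for _ in range(60):
            fa, fb = rng.choice(len(fam_ids), size=2, replace=False)
            ga = sorted(truth.family_members[fam_ids[fa]])[0]
            gb = sorted(truth.family_members[fam_ids[fb]])[0]
            assert not matches_family(seqs[ga], seqs[gb], 0.5, 0.5)
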