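"""Dating and phylogeny: K2P closed form, age arithmetic, alignment DP
oracle, mode detection, UPGMA vs independent oracles, ultrametricity."""

from __future__ import annotations

import math

import numpy as np
import pytest
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from ltrkit import (
    SaturationError,
    SimConfig,
    age_distribution,
    align_ltr_pair,
    date_ltr_pairs,
    estimate_age,
    kimura2p,
    pdistance_matrix,
    upgma_tree,
)
from ltrkit.family import default_family, random_dna
from ltrkit.simulate import simulate_ltr_cohort


def _fake_alignment(pairs: list[tuple[str, str]]):
    """Minimal alignment stand-in exposing [0] and [1] rows."""

    class _Aln:
        def __init__(self, a, b):
            self._rows = (a, b)

        def __getitem__(self, i):
            return self._rows[i]

    return _Aln("".join(p[0] for p in pairs), "".join(p[1] for p in pairs))


class TestKimura2P:
    def test_identical_sequences_give_zero(self):
        aln = _fake_alignment([("A", "A")] * 100)
        P, Q, K = kimura2p(aln)
        assert (P, Q, K) == (0.0, 0.0, 0.0)

    def test_closed_form_transitions_only(self):
        # P=0.1, Q=0 over 100 columns: K = -0.5 ln(0.8)
        cols = [("A", "G")] * 10 + [("C", "C")] * 90
        P, Q, K = kimura2p(_fake_alignment(cols))
        assert P == pytest.approx(0.1, abs=1e-15)
        assert Q == 0.0
        assert K == pytest.approx(-0.5 * math.log(0.8), abs=1e-12)

    @pytest.mark.parametrize("n_ts,n_tv", [(5, 3), (0, 7), (20, 10), (1, 0)])
    def test_closed_form_general(self, n_ts, n_tv):
        n = 200
        cols = ([("A", "G")] * n_ts + [("A", "C")] * n_tv
                + [("T", "T")] * (n - n_ts - n_tv))
        P, Q, K = kimura2p(_fake_alignment(cols))
        p, q = n_ts / n, n_tv / n
        expected = -0.5 * math.log(1 - 2 * p - q) - 0.25 * math.log(1 - 2 * q)
        assert K == pytest.approx(expected, abs=1e-12)

    def test_gap_columns_excluded(self):
        cols = [("A", "-")] * 50 + [("A", "G")] * 10 + [("C", "C")] * 90
        P, Q, K = kimura2p(_fake_alignment(cols))
        assert P == pytest.approx(0.1)

    def test_saturation_raises(self):
        # P=0.3, Q=0.4: 1 - 2P - Q = 0
        cols = [("A", "G")] * 30 + [("A", "C")] * 40 + [("T", "T")] * 30
        with pytest.raises(SaturationError):
            kimura2p(_fake_alignment(cols))


class TestAlignLtrPair:
    def test_identical_ltrs_no_mismatch_columns(self):
        seq = random_dna(np.random.default_rng(0), 200)
        aln = align_ltr_pair(seq, seq)
        assert all(a == b for a, b in zip(aln[0], aln[1]))

    def test_single_substitution_one_mismatch(self):
        seq = random_dna(np.random.default_rng(1), 200)
        other = seq[:100] + ("A" if seq[100] != "A" else "C") + seq[101:]
        aln = align_ltr_pair(seq, other)
        mismatches = sum(1 for a, b in zip(aln[0], aln[1])
                         if a != "-" and b != "-" and a != b)
        assert mismatches == 1

    def test_short_sequences_rejected(self):
        with pytest.raises(ValueError):
            align_ltr_pair("ACGT" * 10, "ACGT" * 30)

    def test_score_matches_dp_oracle(self):
        rng = np.random.default_rng(2)
        a = random_dna(rng, 80)
        b = a[:30] + a[33:70] + "ACG" + a[70:]  # deletion + insertion
        aln = align_ltr_pair(a, b)
        assert aln.score == _needleman_wunsch_score(a, b)


def _needleman_wunsch_score(a: str, b: str, match=1.0, mismatch=-1.0,
                            gap_open=-4.0, gap_extend=-1.0) -> float:
    """Independent affine-gap global alignment score (Gotoh)."""
    n, m = len(a), len(b)
    neg = float("-inf")
    H = [[neg] * (m + 1) for _ in range(n + 1)]
    E = [[neg] * (m + 1) for _ in range(n + 1)]  # gap in a (move in b)
    F = [[neg] * (m + 1) for _ in range(n + 1)]  # gap in b (move in a)
    H[0][0] = 0.0
    for j in range(1, m + 1):
        E[0][j] = gap_open + gap_extend * (j - 1)
        H[0][j] = E[0][j]
    for i in range(1, n + 1):
        F[i][0] = gap_open + gap_extend * (i - 1)
        H[i][0] = F[i][0]
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            E[i][j] = max(H[i][j - 1] + gap_open, E[i][j - 1] + gap_extend)
            F[i][j] = max(H[i - 1][j] + gap_open, F[i - 1][j] + gap_extend)
            s = match if a[i - 1] == b[j - 1] else mismatch
            H[i][j] = max(H[i - 1][j - 1] + s, E[i][j], F[i][j])
    return H[n][m]


class TestEstimateAge:
    def test_zero_distance_zero_age(self):
        assert estimate_age(0.0) == 0.0

    def test_burst_arithmetic(self):
        assert estimate_age(0.0052, mu=1.3e-8) == pytest.approx(200_000.0)

    def test_linearity(self):
        assert estimate_age(0.01) == pytest.approx(2 * estimate_age(0.005))

    def test_alternative_divisor(self):
        assert estimate_age(0.0052, mu=1.3e-8, divisor=1.0) == pytest.approx(400_000.0)

    def test_bad_mu_rejected(self):
        with pytest.raises(ValueError):
            estimate_age(0.1, mu=0.0)


class TestAgeDistribution:
    def test_constant_sample_single_mode(self):
        res = age_distribution([0.2] * 50)
        assert res.modes == [0.2]

    def test_tiny_sample_histogram_fallback(self):
        res = age_distribution([0.1, 0.2, 0.3])
        assert res.method == "histogram"

    def test_simulated_burst_mode_recovered(self):
        fam = default_family()
        cfg = SimConfig(seed=0)
        rng = np.random.default_rng(3)
        cohort = simulate_ltr_cohort(200, 200_000.0, cfg, fam, rng)
        ests = date_ltr_pairs([(a, b) for a, b, _ in cohort])
        res = age_distribution([e.age_years / 1e6 for e in ests])
        global_mode = float(res.grid[np.argmax(res.density)])
        assert 0.15 <= global_mode <= 0.25

    def test_bimodal_mixture_recovered(self):
        fam = default_family()
        cfg = SimConfig(seed=0)
        rng = np.random.default_rng(4)
        young = simulate_ltr_cohort(100, 100_000.0, cfg, fam, rng)
        old = simulate_ltr_cohort(100, 1_000_000.0, cfg, fam, rng)
        ests = date_ltr_pairs([(a, b) for a, b, _ in young + old])
        res = age_distribution([e.age_years / 1e6 for e in ests])
        assert len(res.modes) >= 2
        assert any(abs(m - 0.1) < 0.07 for m in res.modes)
        assert any(abs(m - 1.0) < 0.25 for m in res.modes)

    def test_age_rank_tracks_true_age(self):
        # larger true age gives stochastically larger K (requires spread >= 4x)
        from scipy.stats import spearmanr

        fam = default_family()
        cfg = SimConfig(seed=0)
        rng = np.random.default_rng(5)
        true_ages = list(np.linspace(100_000, 1_000_000, 200))
        cohort = simulate_ltr_cohort(200, true_ages, cfg, fam, rng)
        ests = date_ltr_pairs([(a, b) for a, b, _ in cohort])
        rho = spearmanr(true_ages[: len(ests)],
                        [e.age_years for e in ests]).statistic
        assert rho > 0.8


# ---------------------------------------------------------------------------
# UPGMA
# ---------------------------------------------------------------------------

def _leaf_depths(newick: str) -> dict[str, float]:
    import dendropy

    tree = dendropy.Tree.get(data=newick, schema="newick")
    return {leaf.taxon.label: leaf.distance_from_root()
            for leaf in tree.leaf_node_iter()}


def _cophenetic_from_newick(newick: str) -> dict[tuple[str, str], float]:
    import dendropy

    tree = dendropy.Tree.get(data=newick, schema="newick")
    pdm = tree.phylogenetic_distance_matrix()
    out = {}
    taxa = list(tree.taxon_namespace)
    for i in range(len(taxa)):
        for j in range(i + 1, len(taxa)):
            key = tuple(sorted((taxa[i].label, taxa[j].label)))
            out[key] = pdm.distance(taxa[i], taxa[j])
    return out


class TestUpgma:
    def test_two_taxa(self):
        ids = ["A", "B"]
        mat = np.array([[0.0, 0.2], [0.2, 0.0]])
        tree = upgma_tree(ids, mat)
        assert tree.root_height == pytest.approx(0.1)
        depths = _leaf_depths(tree.newick)
        assert depths["A"] == pytest.approx(0.1)
        assert depths["B"] == pytest.approx(0.1)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_scipy_average_linkage(self, seed):
        # cophenetic distances must equal scipy's UPGMA (average) linkage
        rng = np.random.default_rng(seed)
        n = 6
        cond = rng.uniform(0.05, 1.0, size=n * (n - 1) // 2)
        mat = squareform(cond)
        ids = [f"L{i}" for i in range(n)]
        tree = upgma_tree(ids, mat)
        mine = _cophenetic_from_newick(tree.newick)
        Z = hierarchy.average(cond)
        coph = squareform(hierarchy.cophenet(Z))
        for i in range(n):
            for j in range(i + 1, n):
                key = tuple(sorted((ids[i], ids[j])))
                assert mine[key] == pytest.approx(coph[i, j], abs=1e-9)

    @pytest.mark.parametrize("seed", [7, 8])
    def test_ultrametric_output(self, seed):
        rng = np.random.default_rng(seed)
        n = 5
        mat = squareform(rng.uniform(0.1, 1.0, size=n * (n - 1) // 2))
        tree = upgma_tree([f"x{i}" for i in range(n)], mat)
        depths = list(_leaf_depths(tree.newick).values())
        assert max(depths) - min(depths) < 1e-9
        assert max(depths) == pytest.approx(tree.root_height, abs=1e-9)

    def test_invalid_matrices_rejected(self):
        with pytest.raises(ValueError):
            upgma_tree(["A", "B"], np.array([[0.0, 0.1], [0.2, 0.0]]))
        with pytest.raises(ValueError):
            upgma_tree(["A", "B"], np.array([[0.0, -0.1], [-0.1, 0.0]]))


class TestPDistance:
    def test_known_pdistance(self):
        seqs = {"A": "ACGTACGTAC", "B": "ACGTACGTAC", "C": "ACGTACGTAA"}
        ids, mat = pdistance_matrix(seqs)
        ia, ib, ic = ids.index("A"), ids.index("B"), ids.index("C")
        assert mat[ia, ib] == 0.0
        assert mat[ia, ic] == pytest.approx(0.1)
        assert np.allclose(mat, mat.T)
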