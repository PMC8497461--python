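"""Classification: ORF finding vs a brute-force oracle, domain scanning vs
a quadratic DP oracle, class/group recovery on planted elements, family
majority rule, and region identities."""

from __future__ import annotations

import numpy as np
import pytest
from Bio.Seq import Seq

from ltrkit import (
    ClassifyThresholds,
    DomainHit,
    assign_family,
    classify_element,
    longest_orf,
    region_identity,
    scan_domains,
)
from ltrkit.classify import RegionNotLocatedError
from ltrkit.family import random_dna
from ltrkit.mining import Interval, LtrElement

from conftest import match_truth


# ---------------------------------------------------------------------------
# longest ORF
# ---------------------------------------------------------------------------

def _orf_lengths_bruteforce(seq: str) -> int:
    """Independent six-frame scan: longest ATG..stop run in nt."""
    best = 0
    rc = str(Seq(seq).reverse_complement())
    for s in (seq, rc):
        for frame in range(3):
            codons = [s[i : i + 3] for i in range(frame, len(s) - 2, 3)]
            start = None
            for i, c in enumerate(codons):
                aa = str(Seq(c).translate())
                if aa == "M" and start is None:
                    start = i
                elif aa == "*" and start is not None:
                    best = max(best, 3 * (i - start + 1))
                    start = None
    return best


class TestLongestOrf:
    def test_simple_orf_found(self):
        body = "GCT" * 100
        seq = "TTTT" + "ATG" + body + "TAA" + "TTTT"
        orf = longest_orf(seq, min_codons=30)
        assert orf is not None
        assert orf.nt_seq == "ATG" + body + "TAA"
        assert orf.aa_seq == "M" + "A" * 100

    def test_tie_prefers_plus_strand_5prime_most(self):
        orf_nt = "ATG" + "GCT" * 40 + "TAA"
        # same ORF twice on plus strand: 5'-most wins
        seq = "CC" + orf_nt + "CCCC" + orf_nt + "CC"
        orf = longest_orf(seq, min_codons=30)
        assert orf.strand == "+"
        assert seq.index(orf.nt_seq) == 2

    def test_short_orfs_rejected(self):
        seq = "ATG" + "GCT" * 10 + "TAA"  # 12 codons < 30
        assert longest_orf(seq, min_codons=30) is None

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_matches_bruteforce_on_random_sequence(self, seed):
        rng = np.random.default_rng(seed)
        seq = random_dna(rng, 6000)
        expected = _orf_lengths_bruteforce(seq)
        orf = longest_orf(seq, min_codons=1)
        found = len(orf.nt_seq) if orf else 0
        assert found == expected


# ---------------------------------------------------------------------------
# domain scanning
# ---------------------------------------------------------------------------

def _smith_waterman_score(a: str, b: str, matrix, gap_open=-11.0, gap_extend=-1.0):
    """Independent affine-gap local alignment (Gotoh), max score only."""
    n, m = len(a), len(b)
    neg = float("-inf")
    H = [[0.0] * (m + 1) for _ in range(n + 1)]
    E = [[neg] * (m + 1) for _ in range(n + 1)]
    F = [[neg] * (m + 1) for _ in range(n + 1)]
    best = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            E[i][j] = max(H[i][j - 1] + gap_open, E[i][j - 1] + gap_extend)
            F[i][j] = max(H[i - 1][j] + gap_open, F[i - 1][j] + gap_extend)
            sub = H[i - 1][j - 1] + matrix[a[i - 1], b[j - 1]]
            H[i][j] = max(0.0, sub, E[i][j], F[i][j])
            best = max(best, H[i][j])
    return best


class TestScanDomains:
    def test_canonical_orf_has_four_ordered_hits(self, family):
        orf_aa = str(Seq(family.orf_group1_ref).translate()).rstrip("*")
        hits = scan_domains(orf_aa, family)
        assert [h.domain_name for h in hits] == ["GAG", "GAG_PRE_INT", "INT_CORE", "RT"]
        assert all(h.score >= 0.60 for h in hits)

    def test_missing_motif_yields_three_hits(self, family):
        orf_aa = str(Seq(family.orf_group1_ref).translate()).rstrip("*")
        rt = family.domain_motifs["RT"]
        truncated = orf_aa[: orf_aa.index(rt)]
        hits = scan_domains(truncated, family)
        assert len(hits) == 3
        assert "RT" not in [h.domain_name for h in hits]

    def test_shuffled_sequence_has_no_hits(self, family, rng):
        aas = list("ACDEFGHIKLMNPQRSTVWY")
        shuffled = "".join(rng.choice(aas, size=400))
        assert scan_domains(shuffled, family) == []

    def test_scores_match_dp_oracle(self, family, rng):
        from Bio.Align import substitution_matrices

        blosum = substitution_matrices.load("BLOSUM62")
        motif = family.domain_motifs["GAG"]
        target = ("".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=120))
                  + motif + "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=80)))
        hits = scan_domains(target, family)
        gag = [h for h in hits if h.domain_name == "GAG"][0]
        oracle = _smith_waterman_score(target, motif, blosum)
        self_score = _smith_waterman_score(motif, motif, blosum)
        assert gag.score == pytest.approx(oracle / self_score, abs=1e-9)


# ---------------------------------------------------------------------------
# element classification and recovery on planted truth
# ---------------------------------------------------------------------------

def _bare_element(internal: str, family, strand="+") -> LtrElement:
    ltr = family.ltr_seq
    n5, ni = len(ltr), len(internal)
    return LtrElement(
        element_id="t", chrom="c", strand=strand,
        ltr5=Interval(0, n5), internal=Interval(n5, n5 + ni),
        ltr3=Interval(n5 + ni, 2 * n5 + ni), ltr_pair_identity=1.0,
        ltr5_seq=ltr, ltr3_seq=ltr, internal_seq=internal,
    )


class TestClassifyElement:
    def test_exact_nis_reference_is_nis(self, family):
        elem = _bare_element(family.internal_seq("nis"), family)
        assert classify_element(elem, family) == ("nis", None)

    def test_group1_reference_is_orf_full_group1(self, family):
        elem = _bare_element(family.internal_seq("orf_group1"), family)
        assert classify_element(elem, family) == ("orf_full", 1)

    def test_group2_reference_is_orf_full_group2(self, family):
        elem = _bare_element(family.internal_seq("orf_group2"), family)
        assert classify_element(elem, family) == ("orf_full", 2)

    def test_randomized_internal_is_other(self, family, rng):
        elem = _bare_element(random_dna(rng, 4500), family)
        assert classify_element(elem, family) == ("other", None)

    def test_recovery_on_planted_elements(self, sim_genome, classified_elements):
        _, truth, _ = sim_genome
        total = correct = 0
        for e in classified_elements:
            t = match_truth(e, truth)
            if t is None:
                continue
            total += 1
            want = "other" if t.true_class == "degenerate" else t.true_class
            class_ok = e.class_label == want
            group_ok = (t.true_group is None) or (e.group == t.true_group)
            if class_ok and group_ok:
                correct += 1
        assert total >= 30
        assert correct / total >= 0.95


class TestAssignFamily:
    @pytest.mark.parametrize("labels,expected", [
        (["Angela", "Angela", "Angela", "Ale"], "Angela"),  # 0.75 > 0.5
        (["Angela", "Ale"], "unknown"),  # exactly 0.5 is not > 0.5
        ([], "unknown"),
        (["Ale"], "Ale"),
    ])
    def test_majority_rule_boundary(self, labels, expected):
        hits = [
            DomainHit("GAG", 0, 10, 0.9, label, 0.6) for label in labels
        ]
        assert assign_family(hits) == expected


class TestRegionIdentity:
    def test_identical_elements_give_100(self, family):
        a = _bare_element(family.internal_seq("nis"), family)
        b = _bare_element(family.internal_seq("nis"), family)
        for region in ("PBS_ATG", "3_ATrich", "3_cons"):
            assert region_identity(a, b, region, family) == pytest.approx(100.0)

    def test_quarter_substituted_region_near_75(self, family):
        internal = family.internal_seq("nis")
        # substitute 25% of 3_cons (the last 300 bp of the internal region)
        cons = family.cons3_seq
        cycle = {"A": "C", "C": "G", "G": "T", "T": "A"}
        mutated = list(cons)
        n = len(cons) // 4
        for k in range(n):
            i = k * len(cons) // n
            mutated[i] = cycle[mutated[i]]
        internal_b = internal[: -len(cons)] + "".join(mutated)
        a = _bare_element(internal, family)
        b = _bare_element(internal_b, family)
        ident = region_identity(a, b, "3_cons", family)
        assert 70.0 <= ident <= 80.0

    def test_unalignable_region_flagged(self, family, rng):
        a = _bare_element(family.internal_seq("nis"), family)
        b = _bare_element(random_dna(rng, 4500), family)
        b_scrambled = LtrElement(
            element_id="x", chrom="c", strand="+",
            ltr5=Interval(0, 100), internal=Interval(100, 4600),
            ltr3=Interval(4600, 4700), ltr_pair_identity=1.0,
            ltr5_seq=random_dna(rng, 100), ltr3_seq=random_dna(rng, 100),
            internal_seq=b.internal_seq,
        )
        with pytest.raises(RegionNotLocatedError):
            region_identity(a, b_scrambled, "3_cons", family)

    def test_unknown_region_rejected(self, family):
        a = _bare_element(family.internal_seq("nis"), family)
        with pytest.raises(ValueError):
            region_identity(a, a, "LTR", family)


def test_thresholds_validation():
    with pytest.raises(ValueError):
        ClassifyThresholds(min_domain_score=0.0)
    with pytest.raises(ValueError):
        ClassifyThresholds(nis_min_identity=1.5)
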