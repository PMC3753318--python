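import numpy as np
import pytest

from hkascan.diversity import (
    complete_deletion,
    haplotype_count,
    harmonic_number,
    nucleotide_diversity,
    outgroup_divergence,
    segregating_sites,
    watterson_theta,
)
from hkascan.io import pool_slice
from hkascan.simulate import SimConfig, simulate_alignment

from conftest import make_alignment


def brute_retained(aln):
    """Independent per-column scan oracle for complete deletion."""
    keep = []
    for c in range(aln.alignment_length):
        col = [aln.sequence(i)[c] for i in range(aln.n)]
        if all(b not in "-N" for b in col):
            keep.append(c)
    return keep


def brute_pi(aln, retained):
    """Double loop over pairs: mean pairwise differences per retained site."""
    n = aln.n
    tot = 0
    for i in range(n):
        for j in range(i + 1, n):
            si, sj = aln.sequence(i), aln.sequence(j)
            tot += sum(si[c] != sj[c] for c in retained)
    return tot / (n * (n - 1) / 2) / len(retained)


class TestCompleteDeletion:
    def test_clean_alignment_keeps_everything(self):
        aln = make_alignment(["ACGT", "ACGT"], ["wild"] * 2)
        assert complete_deletion(aln).tolist() == [0, 1, 2, 3]

    def test_single_gap_drops_its_column(self):
        aln = make_alignment(["ACGTA", "ACG-A"], ["wild"] * 2)
        assert complete_deletion(aln).tolist() == [0, 1, 2, 4]

    def test_matches_bruteforce_on_random_missingness(self):
        rng = np.random.default_rng(42)
        for _ in range(10):
            mat = rng.choice(list("ACGT-N"), p=[0.2, 0.2, 0.2, 0.2, 0.1, 0.1], size=(6, 40))
            aln = make_alignment(["".join(r) for r in mat], ["wild"] * 6)
            assert complete_deletion(aln).tolist() == brute_retained(aln)


class TestPolymorphismStats:
    def test_hand_example(self, tiny_alignment):
        retained = complete_deletion(tiny_alignment)
        assert segregating_sites(tiny_alignment, retained) == 2
        assert nucleotide_diversity(tiny_alignment, retained) == pytest.approx((1 + 2 + 1) / 3 / 4)
        assert haplotype_count(tiny_alignment, retained) == 3

    def test_monomorphic_sample(self):
        aln = make_alignment(["ACGT"] * 4, ["wild"] * 4)
        retained = complete_deletion(aln)
        assert segregating_sites(aln, retained) == 0
        assert nucleotide_diversity(aln, retained) == 0.0
        assert haplotype_count(aln, retained) == 1

    def test_duplicated_haplotypes(self):
        aln = make_alignment(["AAAA", "AAAA", "AATT", "AATT"], ["wild"] * 4)
        assert haplotype_count(aln, complete_deletion(aln)) == 2

    @pytest.mark.parametrize(
        "S,n,L,expected",
        [(0, 5, 100, 0.0), (11, 4, 100, 11 / ((1 + 0.5 + 1 / 3) * 100)), (3, 2, 100, 0.03)],
    )
    def test_watterson_formula(self, S, n, L, expected):
        assert watterson_theta(S, n, L) == pytest.approx(expected)

    def test_watterson_undefined_for_zero_sites(self):
        assert np.isnan(watterson_theta(0, 4, 0))

    def test_n_below_two_is_error(self):
        aln = make_alignment(["ACGT"], ["wild"])
        with pytest.raises(ValueError):
            segregating_sites(aln, complete_deletion(aln))

    def test_pi_matches_bruteforce(self):
        rng = np.random.default_rng(7)
        for _ in range(5):
            mat = rng.choice(list("ACGTN"), p=[0.24, 0.24, 0.24, 0.24, 0.04], size=(8, 60))
            aln = make_alignment(["".join(r) for r in mat], ["wild"] * 8)
            retained = complete_deletion(aln)
            assert nucleotide_diversity(aln, retained) == pytest.approx(
                brute_pi(aln, retained), abs=1e-12
            )

    def test_order_permutation_invariance(self):
        rng = np.random.default_rng(3)
        mat = rng.choice(list("ACGT"), size=(6, 50))
        seqs = ["".join(r) for r in mat]
        aln = make_alignment(seqs, ["wild"] * 6)
        perm = rng.permutation(6)
        aln_p = make_alignment([seqs[i] for i in perm], ["wild"] * 6)
        r, rp = complete_deletion(aln), complete_deletion(aln_p)
        assert segregating_sites(aln, r) == segregating_sites(aln_p, rp)
        assert nucleotide_diversity(aln, r) == pytest.approx(nucleotide_diversity(aln_p, rp))
        assert haplotype_count(aln, r) == haplotype_count(aln_p, rp)

    def test_concatenation_is_length_weighted_average(self):
        rng = np.random.default_rng(9)
        m1 = rng.choice(list("ACGT"), size=(5, 30))
        m2 = rng.choice(list("ACGT"), size=(5, 70))
        a1 = make_alignment(["".join(r) for r in m1], ["wild"] * 5)
        a2 = make_alignment(["".join(r) for r in m2], ["wild"] * 5)
        cat = make_alignment(["".join(r1) + "".join(r2) for r1, r2 in zip(m1, m2)], ["wild"] * 5)
        for stat in (
            lambda a: nucleotide_diversity(a, complete_deletion(a)),
            lambda a: watterson_theta(segregating_sites(a, complete_deletion(a)), 5,
                                      len(complete_deletion(a))),
        ):
            expected = (30 * stat(a1) + 70 * stat(a2)) / 100
            assert stat(cat) == pytest.approx(expected)


class TestDivergence:
    def test_identical_outgroup(self):
        aln = make_alignment(["AAAA", "AAAA", "AAAA"], ["wild", "wild", "outgroup"])
        div = outgroup_divergence(aln, "wild")
        assert div.D == 0.0 and div.d_per_site == 0.0

    def test_hand_count(self):
        aln = make_alignment(["AAAA", "AAAA", "AATT"], ["wild", "wild", "outgroup"])
        div = outgroup_divergence(aln, "wild")
        assert div.D == pytest.approx(2.0)
        assert div.d_per_site == pytest.approx(0.5)
        assert div.D_rounded == 2

    def test_requires_single_outgroup(self):
        aln = make_alignment(["AAAA", "AAAA"], ["wild", "wild"])
        with pytest.raises(ValueError, match="outgroup"):
            outgroup_divergence(aln, "wild")

    def test_mean_divergence_matches_coalescent_expectation(self, panel_sheet):
        # E[D] = theta_site * L * (T + 1) for the wild pool
        cfg = SimConfig(seed=0, T=4.0, L=500)
        children = np.random.SeedSequence(123).spawn(400)
        Ds = []
        for ch in children:
            aln, _ = simulate_alignment(cfg, "x", seed_seq=ch, sheet=panel_sheet)
            Ds.append(outgroup_divergence(aln, "wild").D)
        Ds = np.asarray(Ds)
        expected = cfg.theta_site * cfg.L * (cfg.T + 1)
        assert abs(Ds.mean() - expected) < 3 * Ds.std() / np.sqrt(len(Ds))


def test_pi_and_watterson_agree_in_expectation(panel_sheet):
    """Both estimators are unbiased for theta on neutral data: the paired
    difference over simulated loci is zero within Monte-Carlo error."""
    cfg = SimConfig(seed=0, L=400)
    children = np.random.SeedSequence(2024).spawn(500)
    diffs = []
    for ch in children:
        aln, _ = simulate_alignment(cfg, "x", seed_seq=ch, sheet=panel_sheet)
        w = pool_slice(aln, "wild")
        ret = complete_deletion(w)
        S = segregating_sites(w, ret)
        diffs.append(nucleotide_diversity(w, ret) - watterson_theta(S, w.n, len(ret)))
    diffs = np.asarray(diffs)
    assert abs(diffs.mean()) < 3 * diffs.std() / np.sqrt(len(diffs))


def test_harmonic_number_values():
    assert harmonic_number(2) == 1.0
    assert harmonic_number(4) == pytest.approx(1 + 0.5 + 1 / 3)
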