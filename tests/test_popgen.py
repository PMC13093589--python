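import itertools

import numpy as np
import pytest

import recipcross as rc
from recipcross import MISSING, ValidationError


def toy_filter_matrix():
    """5 samples x 6 loci designed so that, at 0.20/0.20/0.01 thresholds:

    - locus L2 (40% missing) fails the locus-missingness filter;
    - sample s4 (missing at 3 of the 5 surviving loci = 60%) fails the
      individual filter;
    - locus L5 is monomorphic after s4 is removed and fails the MAF stage;
    - the remaining 4 loci survive.
    """
    m = MISSING
    geno = np.array(
        [
            # L1 L2 L3 L4 L5 L6
            [0,  1, 1, 2, 2, 0],
            [1,  m, 0, 1, 2, 1],
            [2,  m, 1, 0, 2, 2],
            [1,  0, 2, 1, 2, 0],
            [0,  1, m, m, m, 1],
        ],
        dtype=np.int8,
    )
    return rc.GenotypeMatrix(
        [f"s{i}" for i in range(5)], [f"chr1:{j + 1}" for j in range(6)], geno
    )


def king_pair_oracle(gi, gj):
    """Literal per-locus KING counting for one pair."""
    n_hethet = n_opp = n_het_i = n_het_j = 0
    for a, b in zip(gi, gj):
        if a == MISSING or b == MISSING:
            continue
        if a == 1 and b == 1:
            n_hethet += 1
        if {a, b} == {0, 2}:
            n_opp += 1
        if a == 1:
            n_het_i += 1
        if b == 1:
            n_het_j += 1
    denom = n_het_i + n_het_j
    return np.nan if denom == 0 else (n_hethet - 2 * n_opp) / denom


def wc_theta_oracle(ga, gb):
    """Scalar Weir-Cockerham theta for one biallelic locus, two pops."""
    pops = [np.asarray(g) for g in (ga, gb)]
    pops = [g[g != MISSING] for g in pops]
    r = 2
    n = np.array([len(g) for g in pops], dtype=float)
    p = np.array([g.sum() / (2 * len(g)) for g in pops])
    h = np.array([(g == 1).mean() for g in pops])
    nbar = n.mean()
    nc = (n.sum() - (n**2).sum() / n.sum()) / (r - 1)
    pbar = (n * p).sum() / n.sum()
    s2 = (n * (p - pbar) ** 2).sum() / ((r - 1) * nbar)
    hbar = (n * h).sum() / n.sum()
    a = nbar / nc * (
        s2 - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4) / (nbar - 1)
    )
    b = nbar / (nbar - 1) * (
        pbar * (1 - pbar) - (r - 1) / r * s2 - (2 * nbar - 1) / (4 * nbar) * hbar
    )
    c = hbar / 2
    tot = a + b + c
    return np.nan if tot == 0 else a / tot


class TestFilters:
    def test_toy_fixture_staged_removals(self):
        gm, report = rc.filter_genotypes(toy_filter_matrix())
        assert report.loci_removed_missing == ["chr1:2"]
        assert [s for s, _ in report.individuals_removed] == ["s4"]
        assert report.loci_removed_maf == ["chr1:5"]
        assert report.loci_retained == 4
        assert gm.shape == (4, 4)
        report.check_conservation()

    def test_clean_matrix_passes_unchanged(self):
        rng = np.random.default_rng(0)
        geno = rng.integers(0, 3, size=(10, 20)).astype(np.int8)
        # guarantee polymorphism
        geno[0] = 0
        geno[1] = 1
        gm = rc.GenotypeMatrix(
            [f"s{i}" for i in range(10)], [f"chr1:{j}" for j in range(20)], geno
        )
        out, report = rc.filter_genotypes(gm)
        assert out.shape == gm.shape
        assert not report.individuals_removed

    def test_filter_order_is_locus_then_individual_then_maf(self):
        """s4's missingness is 50% over all 6 loci but 60% over the loci
        surviving stage 1; with the stages swapped it would survive at a
        0.55 threshold.  This pins the stated order."""
        gm = toy_filter_matrix()
        _, report = rc.filter_genotypes(gm, indiv_missing_max=0.55)
        assert [s for s, _ in report.individuals_removed] == ["s4"]

    def test_all_removed_is_an_error(self):
        gm = toy_filter_matrix()
        with pytest.raises(ValidationError):
            rc.filter_genotypes(gm, locus_missing_max=-0.1)


class TestKingKinship:
    def test_self_pair_is_half(self):
        rng = np.random.default_rng(1)
        geno = rng.integers(0, 3, size=(4, 100)).astype(np.int8)
        gm = rc.GenotypeMatrix(
            [f"s{i}" for i in range(4)], [f"chr1:{j}" for j in range(100)], geno
        )
        km = rc.king_kinship(gm)
        np.testing.assert_allclose(np.diag(km.phi), 0.5)

    def test_hand_counted_toy_pair(self):
        geno = np.array([[0, 1, 2, 1], [2, 1, 0, 1]], dtype=np.int8)
        gm = rc.GenotypeMatrix(["i", "j"], [f"chr1:{k}" for k in range(4)], geno)
        km = rc.king_kinship(gm)
        # N_het,het=2, N_oppHom=2, N_het(i)=N_het(j)=2 -> (2-4)/4
        assert km.pair("i", "j") == pytest.approx(-0.5)

    def test_matches_brute_force_oracle_with_missingness(self):
        rng = np.random.default_rng(2)
        geno = rng.integers(0, 3, size=(10, 50)).astype(np.int8)
        geno[rng.random(geno.shape) < 0.1] = MISSING
        gm = rc.GenotypeMatrix(
            [f"s{i}" for i in range(10)], [f"chr1:{j}" for j in range(50)], geno
        )
        km = rc.king_kinship(gm)
        for i, j in itertools.combinations(range(10), 2):
            expect = king_pair_oracle(geno[i], geno[j])
            assert km.phi[i, j] == pytest.approx(expect, abs=1e-12)
            assert km.phi[j, i] == pytest.approx(expect, abs=1e-12)

    def test_invariance_to_locus_order_and_allele_relabeling(self):
        rng = np.random.default_rng(3)
        geno = rng.integers(0, 3, size=(6, 80)).astype(np.int8)
        gm = rc.GenotypeMatrix(
            [f"s{i}" for i in range(6)], [f"chr1:{j}" for j in range(80)], geno
        )
        base = rc.king_kinship(gm).phi
        perm = rng.permutation(80)
        km_perm = rc.king_kinship(
            rc.GenotypeMatrix(gm.sample_ids,
                              [gm.locus_ids[j] for j in perm], geno[:, perm])
        )
        np.testing.assert_allclose(km_perm.phi, base)
        flipped = geno.copy()
        flipped[:, :40] = 2 - flipped[:, :40]  # swap ref/alt at half the loci
        km_flip = rc.king_kinship(
            rc.GenotypeMatrix(gm.sample_ids, gm.locus_ids, flipped)
        )
        np.testing.assert_allclose(km_flip.phi, base)

    def test_full_sibs_near_quarter(self, design15):
        gm = rc.simulate_genotypes(
            rc.SimulationConfig(seed=61), design15, 10000,
            np.random.default_rng(61),
        )
        km = rc.king_kinship(gm)
        meta = design15.set_index("sample_id")
        phis = []
        for fam, grp in design15.groupby("family_code"):
            a, b = grp.sample_id.tolist()
            phis.append(km.pair(a, b))
        assert abs(np.mean(phis) - 0.25) < 0.03


class TestFst:
    def test_no_differentiation_near_zero(self):
        rng = np.random.default_rng(4)
        geno = rng.binomial(2, 0.4, size=(40, 1000)).astype(np.int8)
        gm = rc.GenotypeMatrix(
            [f"s{i}" for i in range(40)], [f"chr1:{j}" for j in range(1000)], geno
        )
        ids = gm.sample_ids
        _, mean = rc.mean_fst(gm, ids[:20], ids[20:])
        assert abs(mean) < 0.01

    def test_fixed_difference_is_one(self):
        geno = np.vstack([np.zeros((10, 1)), np.full((10, 1), 2)]).astype(np.int8)
        gm = rc.GenotypeMatrix([f"s{i}" for i in range(20)], ["chr1:1"], geno)
        theta, mean = rc.mean_fst(gm, gm.sample_ids[:10], gm.sample_ids[10:])
        assert theta[0] == pytest.approx(1.0)

    def test_matches_scalar_oracle(self):
        rng = np.random.default_rng(5)
        pa = rng.uniform(0.1, 0.9, size=200)
        pb = np.clip(pa + rng.normal(0, 0.05, size=200), 0.01, 0.99)
        ga = rng.binomial(2, pa, size=(15, 200)).astype(np.int8)
        gb = rng.binomial(2, pb, size=(12, 200)).astype(np.int8)
        geno = np.vstack([ga, gb])
        geno[rng.random(geno.shape) < 0.05] = MISSING
        gm = rc.GenotypeMatrix(
            [f"s{i}" for i in range(27)], [f"chr1:{j}" for j in range(200)], geno
        )
        theta, mean = rc.mean_fst(gm, gm.sample_ids[:15], gm.sample_ids[15:])
        expect = np.array(
            [wc_theta_oracle(geno[:15, j], geno[15:, j]) for j in range(200)]
        )
        np.testing.assert_allclose(theta, expect, atol=1e-6)
        assert mean == pytest.approx(np.nanmean(expect), abs=1e-6)

    def test_overlapping_groups_rejected(self):
        gm = toy_filter_matrix()
        with pytest.raises(ValidationError, match="overlap"):
            rc.mean_fst(gm, ["s0", "s1"], ["s1", "s2"])
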