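"""Titration curves, anomaly features and protonation coupling."""

import numpy as np
import pytest

from remotecat.simulate import gen_structure
from remotecat.structure import read_structure
from remotecat.titration import (
    COULOMB_KCAL,
    KT_KCAL,
    LN10_KT,
    IonizableSite,
    anomaly_features,
    build_sites,
    hh_curve,
    interaction_matrix,
    protonation_coupling,
    titration_curves,
)

PH = np.arange(0.0, 14.0 + 1e-9, 0.1)


def make_sites(specs):
    """specs: list of (type, pka, position)."""
    return [
        IonizableSite(f"{t}{i + 1}:A", t, pka, pos)
        for i, (t, pka, pos) in enumerate(specs)
    ]


def random_sites(rng, n, spread=18.0):
    table = {"ASP": 3.9, "GLU": 4.1, "HIS": 6.5, "CYS": 8.3,
             "TYR": 10.1, "LYS": 10.5, "ARG": 12.5}
    types = list(table)
    pos = rng.uniform(0, spread, (n, 3))
    return make_sites(
        [(types[i % len(types)], table[types[i % len(types)]], tuple(pos[i]))
         for i in range(n)]
    )


class TestBuildSites:
    def test_residues_plus_termini(self):
        pdb, manifest = gen_structure(ionizable=("ASP", "LYS"))
        s = read_structure(pdb)
        sites = build_sites(s)
        n_res_sites = len(manifest["ionizable_sites"])
        # residue sites + N-terminus + C-terminus of the single chain
        assert len(sites) == n_res_sites + 2
        assert sum(s_.site_type == "NTR" for s_ in sites) == 1
        assert sum(s_.site_type == "CTR" for s_ in sites) == 1

    def test_non_ionizable_chain_gives_termini_only(self):
        pdb, _ = gen_structure(ionizable=())
        sites = build_sites(read_structure(pdb))
        assert {s.site_type for s in sites} == {"NTR", "CTR"}

    def test_count_matches_sequence_scan(self):
        """Site count equals an independent scan of ionizable residue names."""
        pdb, _ = gen_structure(
            layer_plan={1: 4, 2: 3, 3: 2}, ionizable=("ASP", "HIS", "GLU", "LYS", "ARG")
        )
        s = read_structure(pdb)
        ionizable_names = {"ASP", "GLU", "HIS", "CYS", "TYR", "LYS", "ARG"}
        count = sum(
            1 for rid in s.residue_ids(het=False)
            if s.residue_name(rid) in ionizable_names
        )
        assert len(build_sites(s)) == count + 2


class TestInteractionMatrix:
    def test_closed_form_unscreened(self):
        sites = make_sites([("LYS", 10.5, (0, 0, 0)), ("ARG", 12.5, (10.0, 0, 0))])
        W = interaction_matrix(sites, dielectric=20.0, debye_length=np.inf)
        assert W[0, 1] == pytest.approx(COULOMB_KCAL / (20 * 10), rel=1e-12)
        assert W[0, 1] == pytest.approx(1.6603, abs=1e-4)

    def test_halving_dielectric_doubles_w(self):
        sites = make_sites([("ASP", 3.9, (0, 0, 0)), ("LYS", 10.5, (7.0, 0, 0))])
        W1 = interaction_matrix(sites, dielectric=20.0)
        W2 = interaction_matrix(sites, dielectric=10.0)
        np.testing.assert_allclose(W2, 2.0 * W1)

    def test_element_wise_brute_force(self, rng):
        sites = random_sites(rng, 5)
        W = interaction_matrix(sites, dielectric=20.0, debye_length=8.0)
        for i, si in enumerate(sites):
            for j, sj in enumerate(sites):
                if i == j:
                    assert W[i, j] == 0.0
                    continue
                r = np.linalg.norm(np.subtract(si.position, sj.position))
                expected = (
                    COULOMB_KCAL
                    * si.charged_form_charge
                    * sj.charged_form_charge
                    * np.exp(-r / 8.0)
                    / (20.0 * r)
                )
                assert W[i, j] == pytest.approx(expected, rel=1e-12)

    def test_coincident_sites_error(self):
        sites = make_sites([("ASP", 3.9, (0, 0, 0)), ("GLU", 4.1, (0.1, 0, 0))])
        with pytest.raises(ValueError, match="closer than"):
            interaction_matrix(sites)


class TestTitrationCurves:
    def test_single_acid_is_henderson_hasselbalch(self):
        sites = make_sites([("ASP", 4.0, (0, 0, 0))])
        curve = titration_curves(sites, None, PH)
        assert curve.for_site("ASP1:A")[PH == 4.0][0] == pytest.approx(0.5, abs=1e-12)
        np.testing.assert_allclose(curve.theta[0], hh_curve(PH, 4.0), atol=1e-12)

    def test_single_base_is_henderson_hasselbalch(self):
        sites = make_sites([("LYS", 10.5, (0, 0, 0))])
        curve = titration_curves(sites, None, PH)
        np.testing.assert_allclose(curve.theta[0], hh_curve(PH, 10.5), atol=1e-12)

    def test_zero_interaction_collapses_to_hh(self, rng):
        """W -> 0 limit: every enumerated curve equals its HH form."""
        sites = random_sites(rng, 6)
        curve = titration_curves(sites, np.zeros((6, 6)), PH)
        for k, s in enumerate(sites):
            np.testing.assert_allclose(curve.theta[k], hh_curve(PH, s.pka), atol=1e-9)

    def test_mc_matches_enumeration_two_acids(self):
        sites = make_sites([("ASP", 4.0, (0, 0, 0)), ("GLU", 4.5, (0, 0, 4.0))])
        W = interaction_matrix(sites)
        grid = np.arange(2.0, 7.0, 0.5)
        exact = titration_curves(sites, W, grid)
        mc = titration_curves(sites, W, grid, method="mc", seed=1234)
        assert np.abs(exact.theta - mc.theta).max() <= 0.01

    def test_mc_matches_enumeration_12_sites(self, rng):
        sites = random_sites(rng, 12)
        W = interaction_matrix(sites)
        grid = np.arange(2.0, 13.0, 1.5)
        exact = titration_curves(sites, W, grid)
        mc = titration_curves(sites, W, grid, method="mc", seed=1234)
        assert np.abs(exact.theta - mc.theta).max() <= 0.02

    def test_total_protonation_non_increasing(self, rng):
        sites = random_sites(rng, 8)
        W = interaction_matrix(sites)
        curve = titration_curves(sites, W, PH)
        total = curve.theta.sum(axis=0)
        assert (np.diff(total) <= 1e-10).all()

    def test_non_finite_interaction_errors(self):
        sites = make_sites([("ASP", 4.0, (0, 0, 0)), ("GLU", 4.5, (0, 0, 4.0))])
        W = np.array([[0.0, np.inf], [np.inf, 0.0]])
        with pytest.raises(FloatingPointError):
            titration_curves(sites, W, PH)


class TestAnomalyFeatures:
    def test_hh_curve_symmetric_and_zero_area(self):
        # pKa 7 centers the transition in the 0-14 window, so the buffering
        # density is exactly symmetric on the grid
        sites = make_sites([("ASP", 7.0, (0, 0, 0))])
        curve = titration_curves(sites, None, PH)
        feats = anomaly_features(curve, 0)
        assert feats.defined
        assert feats.m3 == pytest.approx(0.0, abs=1e-6)
        assert feats.hh_area == pytest.approx(0.0, abs=1e-6)
        assert feats.fitted_pka == pytest.approx(7.0, abs=1e-3)

    def test_flat_curve_flagged_undefined(self):
        # an Arg with pKa 12.5 barely titrates below pH 7
        sites = make_sites([("ARG", 12.5, (0, 0, 0))])
        curve = titration_curves(sites, None, np.arange(0.0, 7.0, 0.1))
        feats = anomaly_features(curve, 0)
        assert not feats.defined
        assert np.isnan(feats.m3)

    def test_moments_match_quadrature_oracle(self):
        """Coupled two-acid system: moments equal direct numerical
        integration of the enumerated curve."""
        sites = make_sites([("ASP", 5.0, (0, 0, 0)), ("GLU", 5.2, (0, 0, 3.0))])
        W = interaction_matrix(sites, dielectric=10.0, debye_length=np.inf)
        curve = titration_curves(sites, W, PH)
        feats = anomaly_features(curve, 0)

        th = curve.theta[0]
        f = -np.gradient(th, PH)
        f = np.clip(f, 0, None)
        f = f / np.trapezoid(f, PH)
        mu = np.trapezoid(PH * f, PH)
        m3 = np.trapezoid((PH - mu) ** 3 * f, PH)
        m4 = np.trapezoid((PH - mu) ** 4 * f, PH)
        assert feats.m3 == pytest.approx(m3, rel=1e-9)
        assert feats.m4 == pytest.approx(m4, rel=1e-9)
        assert feats.hh_area > 0.01  # genuinely anomalous


class TestCoupling:
    def test_independent_sites_uncorrelated(self):
        sites = make_sites([("ASP", 4.0, (0, 0, 0)), ("GLU", 4.5, (0, 0, 6.0))])
        corr, coupled = protonation_coupling(sites, np.zeros((2, 2)), ph=4.2)
        assert corr[0, 1] == pytest.approx(0.0, abs=1e-12)
        assert coupled == []

    def test_sign_matches_four_state_enumeration(self):
        """Two like-charged (acid) strongly interacting sites between their
        pKas: explicit 4-state Boltzmann enumeration fixes the sign."""
        sites = make_sites([("ASP", 4.0, (0, 0, 0)), ("GLU", 4.5, (0, 0, 3.0))])
        W = interaction_matrix(sites, dielectric=4.0, debye_length=np.inf)
        ph = 4.2
        corr, _ = protonation_coupling(sites, W, ph)

        # independent 4-state oracle
        energies, gammas = [], []
        for g0 in (0, 1):
            for g1 in (0, 1):
                c0 = 0 if g0 else -1
                c1 = 0 if g1 else -1
                E = LN10_KT * (g0 * (ph - 4.0) + g1 * (ph - 4.5)) + W[0, 1] * c0 * c1
                energies.append(E)
                gammas.append((g0, g1))
        w = np.exp(-np.array(energies) / KT_KCAL)
        w /= w.sum()
        g = np.array(gammas, float)
        mean = w @ g
        cov01 = (w * g[:, 0] * g[:, 1]).sum() - mean[0] * mean[1]
        assert np.sign(corr[0, 1]) == np.sign(cov01)

    def test_matrix_matches_enumeration_mc_10_sites(self, rng):
        sites = random_sites(rng, 10)
        W = interaction_matrix(sites)
        exact, _ = protonation_coupling(sites, W, ph=7.0)
        mc, _ = protonation_coupling(sites, W, ph=7.0, method="mc", seed=7)
        finite = np.isfinite(exact) & np.isfinite(mc)
        assert np.abs(exact[finite] - mc[finite]).max() <= 0.02

    def test_no_variance_reported_as_nan(self):
        # Arg at pH 2 is fully protonated: no variance
        sites = make_sites([("ARG", 12.5, (0, 0, 0)), ("ASP", 3.9, (0, 0, 6.0))])
        corr, _ = protonation_coupling(sites, np.zeros((2, 2)), ph=2.0)
        assert np.isnan(corr[0, 1])

    def test_permutation_invariance(self, rng):
        sites = random_sites(rng, 6)
        W = interaction_matrix(sites)
        corr, _ = protonation_coupling(sites, W, ph=7.0)
        perm = rng.permutation(6)
        sperm = [sites[i] for i in perm]
        corr_p, _ = protonation_coupling(sperm, W[np.ix_(perm, perm)], ph=7.0)
        np.testing.assert_allclose(corr_p, corr[np.ix_(perm, perm)], atol=1e-10)
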