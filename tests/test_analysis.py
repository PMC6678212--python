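"""Analysis operators: contacts, binding sites, capacity fits, geometric
estimators, secondary structure."""

import numpy as np
import pytest

import coronams as cm
from coronams.analysis import ContactTrace


class TestContactTrace:

    def make_single_frame(self, surface_dist):
        """One protein, one frame, beads at given surface distances."""
        nano = cm.build_gold_np(150.0, 60, -0.5)
        coords = np.zeros((1, len(surface_dist), 3))
        for i, d in enumerate(surface_dist):
            coords[0, i] = nano.center + np.array([75.0 + d, 0.0, 0.0])
        return cm.contact_trace(coords, nano)

    def test_contact_boundary_strict(self):
        """6.4 Å is a contact, exactly 6.5 Å is not (strict <)."""
        trace = self.make_single_frame([6.4, 6.5, 6.6])
        assert trace.matrix[0, 0]
        assert not trace.matrix[1, 0]
        assert not trace.matrix[2, 0]

    def test_far_beads_all_false(self):
        trace = self.make_single_frame([25.0, 30.0, 40.0])
        assert not trace.matrix.any()
        assert not trace.adsorbed.any()

    def test_equals_brute_force_distances(self, rng):
        """Vectorized trace equals an explicit per-bead loop."""
        nano = cm.build_gold_np(40.0, 50, -0.5)
        coords = rng.normal(0, 30, size=(6, 20, 3))
        trace = cm.contact_trace(coords, nano)
        for f in range(6):
            for i in range(20):
                d = np.linalg.norm(coords[f, i] - nano.center) - nano.radius
                assert trace.matrix[i, f] == (d < 6.5)

    def test_invariant_contact_implies_adsorbed(self):
        with pytest.raises(ValueError):
            ContactTrace(matrix=np.array([[True]]),
                         adsorbed=np.array([False]))


class TestContactProbability:

    def test_fixture_fractions_recovered(self):
        trace = cm.make_contact_fixture(3, [1.0, 0.5, 0.0], 100)
        prob = cm.contact_probability(trace)
        np.testing.assert_allclose(prob.per_residue, [1.0, 0.5, 0.0])

    def test_all_contacts_from_lysine(self):
        trace = cm.make_contact_fixture(3, [0.6, 0.0, 0.0], 50)
        prob = cm.contact_probability(trace, sequence="KAG")
        assert prob.class_shares["charged"] == pytest.approx(100.0)
        assert prob.class_shares["non-polar"] == pytest.approx(0.0)

    def test_class_shares_sum_to_100(self):
        trace = cm.make_contact_fixture(6, [0.9, 0.7, 0.5, 0.3, 0.2, 0.1],
                                        200)
        prob = cm.contact_probability(trace, sequence="KASLQG")
        assert sum(prob.class_shares.values()) == pytest.approx(100.0,
                                                                abs=1e-9)

    def test_never_adsorbed_warns_empty(self):
        trace = ContactTrace(matrix=np.zeros((4, 10), dtype=bool))
        with pytest.warns(UserWarning):
            prob = cm.contact_probability(trace)
        assert prob.n_adsorbed_frames == 0
        assert prob.class_shares == {}


class TestBindingSite:

    def test_inclusive_70_percent_rule(self):
        trace = cm.make_contact_fixture(3, [0.8, 0.7, 0.6], 100)
        site = cm.binding_site(trace)
        np.testing.assert_array_equal(site.residues, [0, 1])
        np.testing.assert_allclose(site.fractions, [0.8, 0.7])

    def test_threshold_zero_gives_every_contacting_residue(self):
        trace = cm.make_contact_fixture(4, [0.5, 0.01, 0.0, 1.0], 100)
        site = cm.binding_site(trace, threshold=0.0)
        # threshold 0 admits all residues (fractions >= 0), per the rule
        assert set(site.residues) == {0, 1, 2, 3}

    def test_no_contacts_empty_site(self):
        trace = ContactTrace(matrix=np.zeros((3, 5), dtype=bool))
        assert len(cm.binding_site(trace)) == 0

    def test_site_subset_of_contacting_residues(self, rng):
        fr = rng.uniform(0, 1, size=12)
        trace = cm.make_contact_fixture(12, fr, 200)
        site = cm.binding_site(trace)
        contacting = set(np.flatnonzero(trace.matrix.any(axis=1)))
        assert set(site.residues) <= contacting


class TestNBoundCurve:

    def test_counts_from_flags(self):
        class FakeTraj:
            times = np.array([0.0, 1.0, 2.0])
            adsorbed_flags = np.array([[0, 0, 0], [1, 0, 1], [1, 1, 1]],
                                      dtype=bool)
        curve = cm.n_bound_curve(FakeTraj())
        np.testing.assert_array_equal(curve.total, [0, 2, 3])

    def test_empty_trajectory(self):
        class FakeTraj:
            times = np.empty(0)
            adsorbed_flags = np.empty((0, 0))
        assert len(cm.n_bound_curve(FakeTraj())) == 0

    def test_per_type_split(self):
        class FakeTraj:
            times = np.array([0.0, 1.0])
            adsorbed_flags = np.array([[1, 0, 1], [1, 1, 1]], dtype=bool)
            labels = np.array(["MB", "HB", "MB"])
        curve = cm.n_bound_curve(FakeTraj())
        np.testing.assert_array_equal(curve.per_type["MB"], [2, 2])
        np.testing.assert_array_equal(curve.per_type["HB"], [0, 1])


class TestCapacityFit:

    def test_noiseless_recovery(self):
        spec = cm.SyntheticAdsorptionSpec(n_max=46, tau=50, alpha=0.8,
                                          n_points=500, noise_sd=0.0)
        res = cm.fit_capacity(cm.make_adsorption_series(spec))
        assert res.success
        # series is rounded to integers, so recovery is near- but not
        # sub-0.1%-exact; the unrounded model recovers to machine precision
        assert res.n_max == pytest.approx(46, rel=0.01)
        t = np.linspace(0, 500, 500)
        exact = cm.AdsorptionCurve(
            times=t, total=cm.stretched_exponential(t, 46, 50, 0.8))
        res2 = cm.fit_capacity(exact)
        assert res2.n_max == pytest.approx(46, rel=1e-3)
        assert res2.tau == pytest.approx(50, rel=1e-3)
        assert res2.alpha == pytest.approx(0.8, rel=1e-3)

    def test_noisy_mean_recovery(self):
        """Across 20 noisy realizations the mean N_max error is below 5%."""
        estimates = []
        for seed in range(20):
            spec = cm.SyntheticAdsorptionSpec(
                n_max=46, tau=50, alpha=0.8, n_points=500, noise_sd=1.0,
                seed=seed)
            res = cm.fit_capacity(cm.make_adsorption_series(spec))
            assert res.success
            estimates.append(res.n_max)
        assert abs(np.mean(estimates) - 46) / 46 < 0.05

    def test_constant_zero_flags_failure(self):
        curve = cm.AdsorptionCurve(times=np.arange(20.0),
                                   total=np.zeros(20))
        res = cm.fit_capacity(curve)
        assert not res.success

    def test_too_few_points(self):
        curve = cm.AdsorptionCurve(times=np.arange(5.0), total=np.arange(5.0))
        with pytest.raises(ValueError):
            cm.StretchedExponentialModel(curve)

    def test_summary_mentions_parameters(self):
        spec = cm.SyntheticAdsorptionSpec(n_max=20, tau=10, alpha=1.0,
                                          n_points=100)
        res = cm.fit_capacity(cm.make_adsorption_series(spec))
        text = res.summary()
        assert "N_max" in text and "tau" in text and "alpha" in text


class TestGeometricEstimators:

    @pytest.mark.parametrize("rg,expected", [(16.39, 84), (25.30, 35),
                                             (17.19, 76)])
    def test_wang_reported_values(self, rg, expected):
        assert cm.nmax_wang(75.0, rg) == expected

    def test_wang_degenerate(self):
        assert cm.nmax_wang(75.0, 150.0) == 1

    def test_calzolai_equal_radii(self):
        assert cm.nmax_calzolai(10.0, 10.0) == round(0.65 * 26)

    def test_calzolai_backcalculated_radius(self):
        assert cm.nmax_calzolai(75.0, 21.4) == pytest.approx(80, abs=1)

    def test_dellorco_half_radius(self):
        assert cm.nmax_dellorco(10.0, 5.0) == 4

    def test_dellorco_backcalculated_radius(self):
        assert cm.nmax_dellorco(75.0, 21.4) == pytest.approx(25, abs=1)

    def test_dellorco_domain(self):
        with pytest.raises(ValueError):
            cm.nmax_dellorco(10.0, 10.0)

    @pytest.mark.parametrize("fn", [cm.nmax_wang, cm.nmax_calzolai,
                                    cm.nmax_dellorco])
    def test_monotone_decreasing_in_protein_size(self, fn):
        sizes = np.linspace(5.0, 40.0, 12)
        values = [fn(75.0, s) for s in sizes]
        assert all(a >= b for a, b in zip(values, values[1:]))


class TestSecondaryStructure:

    def test_ideal_helix(self, helix20):
        ss = cm.assign_secondary_structure(helix20)
        assert ss.percentages["helix"] >= 90.0

    def test_ideal_hairpin_strands(self, hairpin20):
        from coronams.synthetic import hairpin_strand_indices
        ss = cm.assign_secondary_structure(hairpin20)
        s1, s2 = hairpin_strand_indices(20)
        res = np.concatenate([s1, s2])
        assert (ss.labels[res] == "E").mean() >= 0.70

    def test_random_coil_mostly_unstructured(self):
        totals = []
        for seed in range(10):
            p = cm.make_toy_protein(cm.ToyProteinSpec(40, "coil", seed=seed))
            ss = cm.assign_secondary_structure(p)
            totals.append(ss.percentages["helix"] + ss.percentages["sheet"])
        assert np.mean(totals) < 20.0

    def test_percentages_sum_100(self, helix20, hairpin20):
        for p in (helix20, hairpin20):
            ss = cm.assign_secondary_structure(p)
            assert sum(ss.percentages.values()) == pytest.approx(100.0,
                                                                 abs=0.5)

    def test_too_short(self):
        p = cm.CGProtein(coords=np.zeros((4, 3)) +
                         np.arange(4)[:, None] * [3.8, 0, 0],
                         sequence="AAAA")
        with pytest.raises(ValueError):
            cm.assign_secondary_structure(p)


class TestSSChange:

    def test_identical_zero(self, helix20):
        ss = cm.assign_secondary_structure(helix20)
        deltas = cm.ss_change(ss, ss)
        assert all(v == 0.0 for v in deltas.values())

    def test_helix_loss_sign(self, helix20):
        from coronams.analysis import SSAssignment
        before = SSAssignment(labels=np.array(["H"] * 20),
                              percentages={"helix": 76.0, "sheet": 0.0,
                                           "turn": 1.0, "unordered": 23.0})
        after = SSAssignment(labels=np.array(["H"] * 20),
                             percentages={"helix": 71.0, "sheet": 0.0,
                                          "turn": 1.0, "unordered": 28.0})
        deltas = cm.ss_change(before, after)
        assert deltas["helix"] == pytest.approx(-5.0)

    def test_deltas_sum_to_zero(self, helix20, hairpin20):
        d = cm.ss_change(cm.assign_secondary_structure(helix20),
                         cm.assign_secondary_structure(hairpin20))
        assert sum(d.values()) == pytest.approx(0.0, abs=0.5)

    def test_length_mismatch(self, helix20):
        ss20 = cm.assign_secondary_structure(helix20)
        p30 = cm.make_toy_protein(cm.ToyProteinSpec(30, "helix", seed=0))
        ss30 = cm.assign_secondary_structure(p30)
        with pytest.raises(ValueError):
            cm.ss_change(ss20, ss30)
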