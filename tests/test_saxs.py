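"""Guinier analysis, Debye forward scattering, P(r), and the IFT round trip."""

import math

import numpy as np
import pytest

from rtkquant import saxs
from rtkquant.synthetic import gen_toy_structure


def gaussian_curve(rg: float, i0: float = 7.0, n: int = 200) -> saxs.ScatteringCurve:
    q = np.linspace(0.005, 1.2 / rg, n)
    return saxs.ScatteringCurve(q, i0 * np.exp(-(q**2) * rg**2 / 3.0))


class TestScatteringIO:
    def test_three_column_with_comments(self, tmp_path):
        path = tmp_path / "curve.dat"
        path.write_text(
            "# sample buffer-subtracted\n% another comment\n"
            "0.01 100.0 1.0\n0.02 90.0 1.1\n0.03, 80.0, 1.2\n"
        )
        c = saxs.read_scattering(path)
        assert len(c.q) == 3
        assert c.sigma is not None
        np.testing.assert_allclose(c.q, [0.01, 0.02, 0.03])

    def test_negative_intensity_flagged_retained(self, tmp_path):
        path = tmp_path / "neg.dat"
        path.write_text("0.1 5.0\n0.2 1.0\n0.3 -0.2\n")
        c = saxs.read_scattering(path)
        assert len(c.q) == 3
        assert c.negative_intensity_mask.tolist() == [False, False, True]
        assert len(c.trimmed().q) == 2

    def test_round_trip(self, tmp_path):
        c = gaussian_curve(20.0, n=50)
        path = tmp_path / "rt.dat"
        saxs.write_scattering(c, path)
        back = saxs.read_scattering(path)
        np.testing.assert_allclose(back.q, c.q, rtol=1e-9)
        np.testing.assert_allclose(back.intensity, c.intensity, rtol=1e-9)

    def test_non_monotone_q_rejected(self):
        with pytest.raises(ValueError, match="increasing"):
            saxs.ScatteringCurve([0.1, 0.1, 0.2], [1, 1, 1])


class TestPdbIO:
    def test_round_trip_via_gemmi(self, tmp_path):
        atoms = gen_toy_structure("solid_sphere_beads", radius=10.0, n_points=50)
        path = tmp_path / "beads.pdb"
        saxs.write_pdb(atoms, path)
        back = saxs.read_pdb(path)
        assert len(back) == 50
        np.testing.assert_allclose(
            back.coordinates, np.round(atoms.coordinates, 3), atol=1e-6
        )


class TestGuinier:
    def test_exact_gaussian_inversion(self):
        res = saxs.guinier_fit(gaussian_curve(25.0, i0=7.0))
        assert res.rg == pytest.approx(25.0, abs=1e-9)
        assert res.i0 == pytest.approx(7.0, rel=1e-9)
        assert res.qmax_rg <= 1.3

    def test_solid_sphere_debye_curve(self, sphere_beads):
        q = np.linspace(0.004, 0.12, 80)
        curve = saxs.debye_intensity(sphere_beads, q, method="histogram")
        res = saxs.guinier_fit(curve)
        assert res.rg == pytest.approx(30.0 * math.sqrt(3.0 / 5.0), rel=0.02)

    def test_noisy_recovery_median_within_2pct(self):
        truth = 22.0
        estimates = []
        for seed in range(50):
            rng = np.random.default_rng(seed)
            base = gaussian_curve(truth, n=150)
            noisy = saxs.ScatteringCurve(
                base.q, base.intensity * (1 + 0.01 * rng.standard_normal(len(base.q)))
            )
            estimates.append(saxs.guinier_fit(noisy).rg)
        assert np.median(estimates) == pytest.approx(truth, rel=0.02)

    def test_aggregated_input_rejected(self):
        q = np.linspace(0.005, 0.05, 30)
        rising = saxs.ScatteringCurve(q, 1.0 + 100 * q**2)
        with pytest.raises(ValueError, match="non-globular|aggregated"):
            saxs.guinier_fit(rising)


class TestDebye:
    def test_single_point_constant(self):
        atoms = saxs.AtomSet([[0.0, 0.0, 0.0]], weights=[2.0])
        c = saxs.debye_intensity(atoms, [0.01, 0.1, 1.0])
        np.testing.assert_allclose(c.intensity, 4.0)

    def test_two_point_closed_form(self):
        d = 10.0
        atoms = saxs.AtomSet([[0, 0, 0], [d, 0, 0]])
        q = np.array([0.01, 0.1, 0.5, 1.0])
        c = saxs.debye_intensity(atoms, q)
        expected = 2.0 + 2.0 * np.sin(q * d) / (q * d)
        np.testing.assert_allclose(c.intensity, expected, rtol=1e-12)

    def test_forward_value_at_zero_angle_limit(self):
        atoms = saxs.AtomSet(np.random.default_rng(3).normal(size=(20, 3)))
        c = saxs.debye_intensity(atoms, [1e-8])
        assert c.intensity[0] == pytest.approx(400.0, rel=1e-6)  # (sum w)^2

    def test_histogram_matches_direct(self):
        rng = np.random.default_rng(4)
        atoms = saxs.AtomSet(rng.uniform(-20, 20, size=(500, 3)))
        q = np.linspace(0.01, 0.3, 40)
        direct = saxs.debye_intensity(atoms, q, method="direct")
        hist = saxs.debye_intensity(atoms, q, method="histogram", bin_width=0.1)
        rel = np.abs(hist.intensity - direct.intensity) / direct.intensity
        assert rel.max() < 1e-3

    def test_empty_q_grid_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            saxs.debye_intensity(saxs.AtomSet([[0, 0, 0]]), [])


class TestPrFromStructure:
    def test_two_points_single_bin(self):
        atoms = saxs.AtomSet([[0, 0, 0], [50.0, 0, 0]])
        pr = saxs.pr_from_structure(atoms, bin_width=1.0)
        assert pr.d_max == pytest.approx(50.0)
        occupied = pr.r[pr.p > 0]
        assert len(occupied) == 1
        assert occupied[0] == pytest.approx(50.0, abs=0.5)

    def test_sphere_rg_consistent_with_coordinates(self, sphere_beads):
        pr = saxs.pr_from_structure(sphere_beads)
        assert pr.rg == pytest.approx(
            saxs.radius_of_gyration(sphere_beads), rel=0.01
        )

    def test_dumbbell_dmax_geometry(self, dumbbell_beads):
        pr = saxs.pr_from_structure(dumbbell_beads)
        assert pr.d_max == pytest.approx(110.0, abs=2.0)

    def test_unit_area_and_support(self, sphere_beads):
        pr = saxs.pr_from_structure(sphere_beads, bin_width=0.5)
        assert np.sum(pr.p) * 0.5 == pytest.approx(1.0, abs=1e-12)
        assert pr.p[0] == 0.0
        assert pr.p[-1] == 0.0
        assert np.all(pr.p >= 0)

    def test_single_point_rejected(self):
        with pytest.raises(ValueError, match=">= 2 points"):
            saxs.pr_from_structure(saxs.AtomSet([[0, 0, 0]]))


class TestIft:
    def test_sphere_round_trip(self, sphere_beads):
        pr0 = saxs.pr_from_structure(sphere_beads)
        q = np.linspace(0.005, 0.35, 120)
        curve = saxs.debye_intensity(sphere_beads, q, method="histogram")
        pr = saxs.ift_pr(curve, np.arange(30.0, 101.0, 5.0))
        assert pr.d_max == pytest.approx(60.0, rel=0.10)
        assert pr.rg == pytest.approx(pr0.rg, rel=0.03)

    def test_dumbbell_round_trip_correlates(self, dumbbell_beads):
        pr0 = saxs.pr_from_structure(dumbbell_beads)
        q = np.linspace(0.005, 0.35, 120)
        curve = saxs.debye_intensity(dumbbell_beads, q, method="histogram")
        pr = saxs.ift_pr(curve, np.arange(60.0, 161.0, 5.0))
        assert pr.d_max == pytest.approx(110.0, rel=0.10)
        interp = np.interp(pr0.r, pr.r, pr.p, left=0.0, right=0.0)
        assert np.corrcoef(interp, pr0.p)[0, 1] > 0.98

    def test_undersized_candidates_rejected_by_chi2(self):
        # a 25 A-Rg Gaussian curve cannot be fit on supports far below its
        # extent: truncated candidates must carry a much larger chi^2
        curve = gaussian_curve(25.0, n=120)
        pr, diags = saxs.ift_pr(
            curve, [20.0, 30.0, 80.0], return_diagnostics=True
        )
        by_d = {d["d_max"]: d["chi2_red"] for d in diags}
        assert by_d[20.0] > 100 * by_d[80.0]
        assert by_d[30.0] > 100 * by_d[80.0]
        assert pr.d_max > 50.0

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError, match=">= 50"):
            saxs.ift_pr(gaussian_curve(20.0, n=30), [60.0])


class TestRgConsistency:
    def test_three_routes_agree_on_globular_fixture(self, sphere_beads):
        rg_coord = saxs.radius_of_gyration(sphere_beads)
        q = np.linspace(0.004, 0.12, 80)
        curve = saxs.debye_intensity(sphere_beads, q, method="histogram")
        rg_guinier = saxs.guinier_fit(curve).rg
        rg_pr = saxs.pr_from_structure(sphere_beads).rg
        assert rg_guinier == pytest.approx(rg_coord, rel=0.02)
        assert rg_pr == pytest.approx(rg_coord, rel=0.02)


class TestComparePr:
    def test_identical_inputs_zero_deltas(self, sphere_beads):
        pr = saxs.pr_from_structure(sphere_beads)
        rep = saxs.compare_pr(pr, pr)
        assert rep["delta_d_max"] == 0.0
        assert rep["delta_rg"] == 0.0
        assert rep["delta_tail_mass"] == pytest.approx(0.0, abs=1e-15)
        assert rep["l1_distance"] == pytest.approx(0.0, abs=1e-15)

    def test_elongated_vs_compact(self, sphere_beads, dumbbell_beads):
        compact = saxs.pr_from_structure(sphere_beads)
        elongated = saxs.pr_from_structure(dumbbell_beads)
        rep = saxs.compare_pr(elongated, compact)
        assert rep["delta_d_max"] > 0
        assert rep["delta_tail_mass"] > 0

    def test_swap_negates_deltas(self, sphere_beads, dumbbell_beads):
        a = saxs.pr_from_structure(sphere_beads)
        b = saxs.pr_from_structure(dumbbell_beads)
        ab = saxs.compare_pr(a, b)
        ba = saxs.compare_pr(b, a)
        assert ab["delta_d_max"] == -ba["delta_d_max"]
        assert ab["delta_rg"] == -ba["delta_rg"]
        assert ab["delta_tail_mass"] == pytest.approx(-ba["delta_tail_mass"])
        assert ab["l1_distance"] == pytest.approx(ba["l1_distance"])
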