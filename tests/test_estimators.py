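"""Jarzynski PMF, error bands, surfaces, pathway classes, correlations."""

import numpy as np
import pytest

from dnapull import (
    AnalysisError,
    LambdaMap,
    WorkCurve,
    beta_kcal,
    boltzmann_surface_2d,
    classify_pathway,
    correlate_max_work_rmsd,
    delta_delta_w,
    delta_w,
    jarzynski_pmf,
    kt_kcal,
    read_work_curves,
    work_std,
)
from dnapull.estimators import PATH_QGR, PATH_RGQ
from dnapull.toysim import gaussian_work_ensemble, write_toy_colvar

T = 298.0
BETA = beta_kcal(T)
LAM = np.linspace(1.0, 0.0, 21)


def curve(terminal, run_id="r", units="kcal/mol", groups=None, rmsd=None):
    return WorkCurve(
        run_id=run_id,
        lambda_grid=LAM,
        work=terminal * (1.0 - LAM),
        units=units,
        groups=groups,
        rmsd=rmsd,
    )


class TestJarzynskiPMF:
    def test_identical_curves_reproduce_work(self):
        curves = [curve(8.0, f"r{i}") for i in range(5)]
        pmf = jarzynski_pmf(curves, T)
        assert np.allclose(pmf.phi, 8.0 * (1.0 - LAM))
        assert np.allclose(pmf.sigma, 0.0)

    def test_gaussian_closed_form(self, gaussian_ensemble):
        # N(10, 1) kcal/mol terminal work: Phi = mu - beta s^2 / 2
        pmf = jarzynski_pmf(gaussian_ensemble, T)
        expected = 10.0 - 1.0 / (2.0 * kt_kcal(T))
        g = np.exp(-BETA * np.array([c.work[-1] for c in gaussian_ensemble]))
        se = g.std(ddof=1) / (g.mean() * np.sqrt(g.size)) / BETA
        assert abs(pmf.phi[-1] - expected) < 3.0 * se

    def test_two_curve_closed_form(self):
        W = 3.0
        pmf = jarzynski_pmf([curve(0.0, "a"), curve(W, "b")], T)
        expected = -np.log((1.0 + np.exp(-BETA * W)) / 2.0) / BETA
        assert pmf.phi[-1] == pytest.approx(expected, rel=1e-12)

    def test_single_curve_degenerates_to_work(self, caplog):
        import logging

        with caplog.at_level(logging.WARNING):
            pmf = jarzynski_pmf([curve(5.0)], T)
        assert np.allclose(pmf.phi, 5.0 * (1.0 - LAM))
        assert any("single" in r.message for r in caplog.records)

    def test_jensen_bound_everywhere(self, gaussian_ensemble):
        pmf = jarzynski_pmf(gaussian_ensemble, T)
        mean_w = np.mean([c.work for c in gaussian_ensemble], axis=0)
        assert np.all(pmf.phi <= mean_w + 1e-9)
        # strict once curves differ (away from the anchored start)
        assert np.all(pmf.phi[5:] < mean_w[5:])

    def test_exponential_average_stays_within_min_and_mean(self):
        curves = [curve(w, f"r{w}") for w in (2.0, 5.0, 9.0)]
        duplicated = curves + [curve(5.0, "dup")]
        pmf = jarzynski_pmf(duplicated, T)
        works = np.stack([c.work for c in duplicated])
        assert np.all(pmf.phi >= works.min(axis=0) - 1e-9)
        assert np.all(pmf.phi <= works.mean(axis=0) + 1e-9)

    def test_mismatched_grids_rejected(self):
        a = curve(1.0, "a")
        b = WorkCurve("b", np.linspace(1, 0, 11), np.zeros(11), units="kcal/mol")
        with pytest.raises(AnalysisError, match="grid"):
            jarzynski_pmf([a, b], T)


class TestWorkStd:
    def test_identical_curves_zero(self):
        sigma, sd = work_std([curve(4.0, "a"), curve(4.0, "b")], T)
        assert np.allclose(sigma, 0.0) and np.allclose(sd, 0.0)

    def test_two_point_closed_form(self):
        W = 6.0
        sigma, sd = work_std([curve(0.0, "a"), curve(W, "b")], T)
        assert sigma[-1] == pytest.approx((BETA / 2.0) * (W / 2.0), rel=1e-12)
        assert sd[-1] == pytest.approx(W / 2.0, rel=1e-12)

    def test_gaussian_limit(self, gaussian_ensemble):
        sigma, sd = work_std(gaussian_ensemble, T)
        assert sd[-1] == pytest.approx(1.0, abs=0.05)
        assert sigma[-1] == pytest.approx(BETA / 2.0, rel=0.05)


class TestDeltaW:
    def test_monotone_profile(self):
        pmf = jarzynski_pmf([curve(12.5, "a"), curve(12.5, "b")], T)
        assert delta_w(pmf) == pytest.approx(12.5)

    def test_interior_maximum(self):
        lam = np.linspace(1.0, 0.0, 41)
        bump = 15.0 * np.sin(np.pi * (1 - lam))  # max in the middle, ends at 0
        curves = [
            WorkCurve(f"r{i}", lam, bump, units="kcal/mol") for i in range(2)
        ]
        assert delta_w(jarzynski_pmf(curves, T)) == pytest.approx(15.0, rel=1e-6)

    def test_flat_profile(self):
        curves = [
            WorkCurve(f"r{i}", LAM, np.zeros_like(LAM), units="kcal/mol")
            for i in range(2)
        ]
        assert delta_w(jarzynski_pmf(curves, T)) == 0.0

    def test_sequence_specificity_difference(self):
        pmf_a = jarzynski_pmf([curve(23.27, "a1"), curve(23.27, "a2")], T)
        pmf_b = jarzynski_pmf([curve(15.05, "b1"), curve(15.05, "b2")], T)
        assert delta_delta_w(pmf_a, pmf_b) == pytest.approx(8.22)
        assert delta_delta_w(pmf_b, pmf_a) == pytest.approx(8.22)
        assert delta_delta_w(pmf_a, pmf_a) == 0.0


class TestSurface2D:
    def test_samples_partition_into_bins(self):
        rng = np.random.default_rng(0)
        curves = [
            curve(
                float(w),
                f"r{i}",
                groups={
                    "Q112": rng.uniform(0, 11, LAM.size),
                    "R114": rng.uniform(0, 24, LAM.size),
                },
            )
            for i, w in enumerate(rng.uniform(1, 10, 8))
        ]
        surf = boltzmann_surface_2d(curves, "Q112", "R114", bins=100, temperature=T)
        n_samples = 8 * LAM.size
        assert surf.n_samples == n_samples  # every sample in exactly one bin
        assert surf.occupied_bins <= n_samples
        assert surf.fill > surf.z[surf.counts > 0].max()

    def test_isolated_samples_keep_their_work(self):
        lam = np.array([1.0, 0.0])
        w = 4.0
        c = WorkCurve(
            "r",
            lam,
            np.array([0.0, w]),
            units="kcal/mol",
            groups={"x": np.array([0.0, 10.0]), "y": np.array([0.0, 10.0])},
        )
        surf = boltzmann_surface_2d([c], "x", "y", bins=10, temperature=T)
        occ = surf.z[surf.counts > 0]
        assert sorted(occ) == pytest.approx([0.0, w])
        assert np.all(surf.z[surf.counts == 0] == surf.fill)
        assert surf.fill == pytest.approx(1.05 * w)

    def test_shared_bin_two_sample_closed_form(self):
        lam = np.array([1.0, 0.0])
        W = 5.0
        c = WorkCurve(
            "r",
            lam,
            np.array([0.0, W]),
            units="kcal/mol",
            groups={"x": np.array([1.0, 1.0]), "y": np.array([1.0, 1.0])},
        )
        surf = boltzmann_surface_2d([c], "x", "y", bins=5, temperature=T)
        occ = surf.z[surf.counts > 0]
        assert occ.size == 1
        expected = W * np.exp(-BETA * W) / (1.0 + np.exp(-BETA * W))
        assert occ[0] == pytest.approx(expected, rel=1e-12)

    def test_missing_group_rejected(self):
        with pytest.raises(AnalysisError, match="Q112"):
            boltzmann_surface_2d([curve(1.0)], "Q112", "R114")


def path_curve(cq_at_crossing, run_id="r", points=101):
    """Total contacts decay 39 -> 0; C_Q tuned to hit a value at total=30."""
    lam = np.linspace(1.0, 0.0, points)
    total = 39.0 * lam
    q = (cq_at_crossing * 39.0 / 30.0) * lam
    g = 5.0 * lam
    r = total - q - g
    return WorkCurve(
        run_id,
        lam,
        10.0 * (1.0 - lam),
        units="kcal/mol",
        groups={"Q112": q, "G113": g, "R114": r},
    )


class TestPathwayClassifier:
    def test_low_q_is_rgq(self):
        pc = classify_pathway(path_curve(4.0))
        assert pc.label == PATH_RGQ
        assert pc.c_q == pytest.approx(4.0, abs=1e-6)

    def test_high_q_is_qgr(self):
        pc = classify_pathway(path_curve(7.0))
        assert pc.label == PATH_QGR
        assert pc.c_q == pytest.approx(7.0, abs=1e-6)

    def test_exact_tie_flagged_rgq(self):
        pc = classify_pathway(path_curve(5.0, points=40))
        assert pc.label == PATH_RGQ
        assert pc.tied

    def test_first_crossing_convention(self):
        # total dips below 30, recovers, then decays: classify at first dip
        lam = np.linspace(1.0, 0.0, 201)
        total = 39.0 * lam.copy()
        total[40:60] = 28.0  # transient dip
        total[60:80] = 35.0  # recovery
        total[80:] = 39.0 * lam[80:]
        q = np.linspace(9.0, 0.0, 201)
        g = np.zeros(201)
        r = total - q - g
        c = WorkCurve(
            "r",
            lam,
            np.zeros(201),
            units="kcal/mol",
            groups={"Q112": q, "G113": g, "R114": r},
        )
        pc = classify_pathway(c)
        # q at the first crossing (~index 40) is still high -> Q-G-R
        assert pc.label == PATH_QGR
        assert pc.c_q > 7.0

    def test_invariant_under_resampling(self):
        c = path_curve(4.0, points=101)
        resampled = c.resample(np.linspace(1.0, 0.0, 467))
        a = classify_pathway(c)
        b = classify_pathway(resampled)
        assert a.label == b.label
        assert a.c_q == pytest.approx(b.c_q, abs=1e-6)

    def test_never_crossing_rejected(self):
        lam = np.linspace(1.0, 0.0, 11)
        c = WorkCurve(
            "r",
            lam,
            np.zeros(11),
            units="kcal/mol",
            groups={"Q112": np.full(11, 20.0), "R114": np.full(11, 20.0)},
        )
        with pytest.raises(AnalysisError, match="never crosses"):
            classify_pathway(c)


class TestWorkRmsdCorrelation:
    def _curves(self, works, rmsds):
        return [
            curve(w, f"r{i}", rmsd=np.full(LAM.size, r))
            for i, (w, r) in enumerate(zip(works, rmsds))
        ]

    def test_proportional_is_one(self):
        works = [1.0, 2.0, 3.0, 4.0]
        r, _ = correlate_max_work_rmsd(self._curves(works, [2 * w for w in works]), T)
        assert r == pytest.approx(1.0)

    def test_antiproportional_is_minus_one(self):
        works = [1.0, 2.0, 3.0, 4.0]
        r, _ = correlate_max_work_rmsd(self._curves(works, [9 - w for w in works]), T)
        assert r == pytest.approx(-1.0)

    def test_matches_brute_force_formula(self):
        works = [3.0, 7.0, 5.0, 9.0, 4.0]
        rmsds = [0.2, 0.5, 0.3, 0.9, 0.4]
        r, table = correlate_max_work_rmsd(self._curves(works, rmsds), T)
        w = np.array(works)
        v = np.array(rmsds)
        brute = np.mean((w - w.mean()) * (v - v.mean())) / (w.std() * v.std())
        assert r == pytest.approx(brute, rel=1e-12)
        assert len(table) == 5

    def test_zero_variance_undefined(self):
        r, table = correlate_max_work_rmsd(
            self._curves([2.0, 2.0, 2.0], [0.1, 0.2, 0.3]), T
        )
        assert r is None
        assert len(table) == 3


class TestReadWorkCurves:
    def _write_ensemble(self, tmp_path, n=5, seed=0):
        from dnapull.toysim import LangevinSpec, ToySchedule, simulate_steered_langevin

        spec = LangevinSpec(potential="flat", dt=0.004, n_steps=500, seed=seed)
        sched = ToySchedule(k_trap=5.0, x0=1.0, x1=-1.0, n_runs=n)
        paths = []
        for i, (series, wc) in enumerate(simulate_steered_langevin(spec, sched)):
            p = tmp_path / f"run_{i:02d}.colvar"
            write_toy_colvar(p, series, wc, seed)
            paths.append((p, wc))
        return paths

    def test_round_trip(self, tmp_path):
        pairs = self._write_ensemble(tmp_path)
        curves = read_work_curves(
            [p for p, _ in pairs], LambdaMap(1.0, -1.0), units="kT"
        )
        assert len(curves) == 5
        for loaded, (_, original) in zip(curves, pairs):
            assert np.allclose(loaded.work, original.work, atol=1e-8)
            assert np.allclose(loaded.lambda_grid, original.lambda_grid, atol=1e-9)

    def test_nonzero_start_shifted_with_warning(self, tmp_path, caplog):
        import logging

        (p, _), *_ = self._write_ensemble(tmp_path, n=1)
        text = p.read_text().splitlines()
        # add a constant to every work value
        fixed = []
        for ln in text:
            if ln.startswith("#"):
                fixed.append(ln)
            else:
                vals = ln.split()
                vals[3] = str(float(vals[3]) + 2.5)
                fixed.append(" ".join(vals))
        p.write_text("\n".join(fixed))
        with caplog.at_level(logging.WARNING):
            (c,) = read_work_curves([p], LambdaMap(1.0, -1.0), units="kT")
        assert c.work[0] == 0.0
        assert any("shifting" in r.message for r in caplog.records)

    def test_empty_file_rejected(self, tmp_path):
        p = tmp_path / "empty.colvar"
        p.write_text("")
        with pytest.raises(AnalysisError, match="empty"):
            read_work_curves([p], LambdaMap(1.0, -1.0))

    def test_grids_unified_by_resampling(self, tmp_path):
        pairs = self._write_ensemble(tmp_path, n=2)
        # thin out the second file to a coarser grid
        p2 = pairs[1][0]
        lines = p2.read_text().splitlines()
        head = [ln for ln in lines if ln.startswith("#")]
        data = [ln for ln in lines if not ln.startswith("#")]
        p2.write_text("\n".join(head + data[::5]) + "\n")
        curves = read_work_curves(
            [p for p, _ in pairs], LambdaMap(1.0, -1.0), units="kT"
        )
        assert len(curves[0]) == len(curves[1])
        assert np.allclose(curves[0].lambda_grid, curves[1].lambda_grid)
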