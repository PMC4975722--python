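"""Shell grouping, spherical-mean fitting, volume runner, tensor comparison."""

import numpy as np
import pytest

import smtdwi as smt
from smtdwi.estimation import ShellMeans, compute_shell_means
from smtdwi.exceptions import EstimationError

from conftest import MEAN_B1, MEAN_B25, TRUTH


class TestGroupShells:
    def test_protocol_partition(self, protocol_scheme):
        part = smt.group_shells(protocol_scheme)
        assert part.b0_indices.size == 10
        assert part.n_shells == 2
        assert [ix.size for ix in part.shell_indices] == [76, 75]
        np.testing.assert_allclose(part.shell_bvals, [1.0, 2.5])

    def test_clustering_within_tolerance(self):
        scheme = smt.GradientScheme(
            [0.0, 0.995, 1.005, 2.5],
            [[0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1]],
        )
        part = smt.group_shells(scheme)
        assert part.n_shells == 2
        assert part.shell_bvals[0] == pytest.approx(1.0)

    def test_single_shell_rejected(self):
        scheme = smt.GradientScheme([0.0, 1.0], [[0, 0, 0], [0, 0, 1]])
        with pytest.raises(EstimationError, match="two nonzero"):
            smt.group_shells(scheme)
        part = smt.group_shells(scheme, require_multi_shell=False)
        assert part.n_shells == 1


class TestShellMean:
    def test_constant_signal(self):
        assert smt.shell_mean(np.full(20, 0.37), np.arange(20)) == pytest.approx(0.37)

    def test_minimum_members(self):
        with pytest.raises(ValueError):
            smt.shell_mean(np.ones(5), np.arange(5))

    def test_noiseless_synthesized_means_match_closed_form(
        self, hyper, protocol_scheme
    ):
        part = smt.group_shells(protocol_scheme)
        for seed in [2, 9]:
            fod = smt.sample_dpm_fod(hyper, rng_seed=seed)
            sig = smt.synthesize_signal(fod, protocol_scheme, TRUTH)
            sm = compute_shell_means(sig, part)
            assert sm.means[0] == pytest.approx(MEAN_B1, abs=0.005)
            assert sm.means[1] == pytest.approx(MEAN_B25, abs=0.005)


class TestFitSMT:
    def test_recovers_truth_from_exact_means(self):
        sm = ShellMeans([1.0, 2.5], [MEAN_B1, MEAN_B25], [76, 75])
        fit = smt.fit_smt(sm)
        assert fit.params.lam_par == pytest.approx(2.5, abs=1e-6)
        assert fit.params.lam_perp == pytest.approx(0.1, abs=1e-6)
        assert not any(fit.at_bound.values())
        assert fit.md == pytest.approx(0.9, abs=1e-6)
        assert fit.ratio == pytest.approx(25.0, rel=1e-4)

    def test_recovers_truth_from_rounded_printed_means(self):
        # inputs rounded to 3 decimals perturb the inverse by a few 1e-3
        fit = smt.fit_smt(ShellMeans([1.0, 2.5], [0.503, 0.282], [76, 75]))
        assert fit.params.lam_par == pytest.approx(2.5, abs=5e-3)
        assert fit.params.lam_perp == pytest.approx(0.1, abs=5e-3)

    def test_noiseless_round_trip_sweep(self, rng):
        for _ in range(60):
            lam_par = float(rng.uniform(0.05, 3.04))
            lam_perp = float(rng.uniform(0.0, lam_par))
            p = smt.MicroParams(lam_par, lam_perp)
            means = [smt.spherical_mean_model(b, p) for b in (1.0, 2.5)]
            fit = smt.fit_smt(ShellMeans([1.0, 2.5], means, [76, 75]))
            assert fit.params.lam_par == pytest.approx(lam_par, abs=1e-6)
            assert fit.params.lam_perp == pytest.approx(lam_perp, abs=1e-6)

    def test_free_water_hits_upper_corner(self):
        lam = smt.LAMBDA_FREE
        means = [np.exp(-1.0 * lam), np.exp(-2.5 * lam)]
        fit = smt.fit_smt(ShellMeans([1.0, 2.5], means, [76, 75]))
        assert fit.at_bound["par_at_free"]
        assert fit.at_bound["equal_diffusivities"]
        assert fit.params.lam_par == pytest.approx(lam, abs=1e-5)

    def test_pure_noise_means_give_flagged_zero_fit(self):
        fit = smt.fit_smt(ShellMeans([1.0, 2.5], [1.0, 1.0], [76, 75]))
        assert fit.at_bound["perp_at_zero"]
        assert fit.params.lam_par == pytest.approx(0.0, abs=1e-6)

    def test_constraint_triangle_always_respected(self, rng):
        for _ in range(50):
            means = rng.uniform(0.01, 1.2, size=2)
            means.sort()
            fit = smt.fit_smt(ShellMeans([1.0, 2.5], means[::-1], [76, 75]))
            p = fit.params
            assert 0.0 <= p.lam_perp <= p.lam_par <= smt.LAMBDA_FREE

    def test_invalid_inputs(self):
        with pytest.raises(EstimationError):
            smt.fit_smt(ShellMeans([1.0], [0.5], [76]))
        with pytest.raises(ValueError):
            smt.fit_smt(ShellMeans([1.0, 2.5], [np.nan, 0.3], [76, 75]))

    def test_invariance_across_fods(self, hyper, protocol_scheme):
        """Different orientation distributions, same microstructure ->
        statistically indistinguishable shell means and fits."""
        part = smt.group_shells(protocol_scheme)
        fits = []
        for seed in [1, 2, 3]:
            fod = smt.sample_dpm_fod(hyper, rng_seed=seed)
            sig = smt.synthesize_signal(fod, protocol_scheme, TRUTH)
            sm = compute_shell_means(sig, part)
            fits.append(smt.fit_smt(sm).params.as_tuple())
        fits = np.array(fits)
        assert np.ptp(fits[:, 0]) < 0.02
        assert np.ptp(fits[:, 1]) < 0.01


def _synthetic_volume(scheme, hyper, shape=(3, 3, 2), snr=None, seed=0):
    n_vox = int(np.prod(shape))
    data = np.zeros((n_vox, len(scheme)))
    seeds = np.random.SeedSequence(seed).spawn(n_vox)
    for i in range(n_vox):
        fod = smt.sample_dpm_fod(hyper, seeds[i])
        data[i] = smt.synthesize_signal(fod, scheme, TRUTH)
    if snr is not None:
        data = smt.add_rician_noise(data, 1.0 / snr, rng_seed=seed + 1)
    return data.reshape(*shape, len(scheme))


class TestFitVolume:
    def test_noiseless_exact_recovery(self, small_scheme, hyper):
        dwi = _synthetic_volume(small_scheme, hyper)
        maps = smt.fit_volume(dwi, small_scheme)
        inside = maps.mask
        # 16 directions per shell leave a small sampling error in the means
        assert np.nanmedian(maps.lam_par_map[inside]) == pytest.approx(2.5, abs=0.05)
        assert np.nanmedian(maps.lam_perp_map[inside]) == pytest.approx(0.1, abs=0.02)
        assert np.all(np.isnan(maps.lam_par_map[~inside]))

    def test_noisy_recovery_with_adjustment(self, small_scheme, hyper):
        snr = 17.5
        dwi = _synthetic_volume(small_scheme, hyper, shape=(4, 4, 3), snr=snr, seed=3)
        maps = smt.fit_volume(
            dwi, small_scheme, noise=smt.NoiseModel(1.0 / snr)
        )
        assert np.nanmedian(maps.lam_par_map[maps.mask]) == pytest.approx(
            2.5, rel=0.10
        )
        assert np.nanmedian(maps.lam_perp_map[maps.mask]) == pytest.approx(
            0.1, rel=0.25
        )

    def test_zero_voxel_inside_mask_flagged_not_crashed(self, small_scheme, hyper):
        dwi = _synthetic_volume(small_scheme, hyper)
        dwi[0, 0, 0] = 0.0
        maps = smt.fit_volume(
            dwi, small_scheme, noise=smt.NoiseModel(0.02)
        )
        assert not maps.mask[0, 0, 0]
        assert np.isnan(maps.lam_par_map[0, 0, 0])

    def test_shape_mismatch_errors(self, small_scheme):
        with pytest.raises(ValueError):
            smt.fit_volume(np.ones((2, 2, 2, 5)), small_scheme)
        with pytest.raises(ValueError):
            smt.fit_volume(
                np.ones((2, 2, 2, len(small_scheme))),
                small_scheme,
                mask=np.ones((3, 3, 3), dtype=bool),
            )


class TestDTIComparison:
    def test_coherent_fiber_tensor_fa_matches_micro_fa(self, protocol_scheme):
        fod = smt.FiberOD([smt.WatsonComponent(1.0, np.array([0, 0, 1.0]), 800.0)])
        sig = smt.synthesize_signal(fod, protocol_scheme, TRUTH)
        _, fa, md = smt.dti_fit(sig, protocol_scheme)
        assert fa == pytest.approx(smt.micro_fa(TRUTH), abs=0.08)
        assert md == pytest.approx(smt.micro_md(TRUTH), rel=0.25)

    def test_crossing_fibers_depress_tensor_fa_not_micro_fa(self, protocol_scheme):
        """The voxel-scale tensor conflates crossing with isotropy; the
        per-axon FA does not."""
        comps = [
            smt.WatsonComponent(0.5, np.array([1.0, 0, 0]), 50.0),
            smt.WatsonComponent(0.5, np.array([0, 1.0, 0]), 50.0),
        ]
        sig = smt.synthesize_signal(smt.FiberOD(comps), protocol_scheme, TRUTH)
        _, fa_dti, _ = smt.dti_fit(sig, protocol_scheme)
        part = smt.group_shells(protocol_scheme)
        fit = smt.fit_smt(compute_shell_means(sig, part))
        assert fit.fa > 0.9
        assert fa_dti < 0.6
        assert fa_dti < fit.fa

    def test_isotropic_signal_fa_zero(self, protocol_scheme):
        iso = smt.MicroParams(1.0, 1.0)
        sig = np.exp(-protocol_scheme.bvals * 1.0)
        _, fa, md = smt.dti_fit(sig, protocol_scheme)
        assert fa == pytest.approx(0.0, abs=1e-6)
        assert md == pytest.approx(1.0, rel=1e-6)

    def test_needs_enough_directions(self):
        scheme = smt.GradientScheme(
            [0.0, 1.0, 1.0],
            [[0, 0, 0], [1, 0, 0], [0, 1, 0]],
        )
        with pytest.raises(EstimationError):
            smt.dti_fit(np.array([1.0, 0.5, 0.5]), scheme)


class TestMonteCarlo:
    def test_noiseless_trials_recover_truth(self, hyper):
        df = smt.monte_carlo_experiment(
            snr_grid=[np.inf],
            ndir_grid=[],
            n_trials=3,
            truth=TRUTH,
            hyper=hyper,
            rng_seed=5,
        )
        # the 76-direction sample mean carries ~2e-4 sampling error, which
        # the inverse map amplifies ~15x into the diffusivities
        assert np.allclose(df.lam_par_hat, 2.5, atol=0.01)
        assert np.allclose(df.lam_perp_hat, 0.1, atol=0.005)

    def test_table_layout_and_reproducibility(self, hyper):
        kwargs = dict(
            snr_grid=[10.0], ndir_grid=[12], n_trials=4, truth=TRUTH,
            hyper=hyper, rng_seed=8,
        )
        df1 = smt.monte_carlo_experiment(**kwargs)
        df2 = smt.monte_carlo_experiment(**kwargs)
        assert set(df1.sweep) == {"snr", "ndirs"}
        assert {"mean_b1", "mean_b2", "lam_par_hat", "lam_perp_hat"} <= set(
            df1.columns
        )
        assert df1.equals(df2)
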