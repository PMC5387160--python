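"""Empirical-Bayes inversion: modes, priors, ReML free energy."""

import dataclasses

import numpy as np
import pytest

from hippomeg import invert as inv
from hippomeg import simulate as sim
from hippomeg.anatomy import make_source_space
from hippomeg.forward import LeadField


class TestTemporalModes:
    def test_rank1_data_fully_retained(self, rng):
        data = np.outer(rng.normal(size=30), np.sin(np.arange(100)))
        m = inv.reduce_temporal_modes(data, 1)
        assert np.isclose(m.retained_variance_fraction, 1.0, atol=1e-9)

    def test_mode_vectors_orthonormal(self, rng):
        data = rng.normal(size=(40, 200))
        m = inv.reduce_temporal_modes(data, 16)
        gram = m.mode_vectors.T @ m.mode_vectors
        assert np.abs(gram - np.eye(16)).max() < 1e-9

    def test_reduction_matches_best_rank_k(self, rng):
        data = rng.normal(size=(20, 60))
        k = 5
        m = inv.reduce_temporal_modes(data, k)
        u, s, vt = np.linalg.svd(data, full_matrices=False)
        best = u[:, :k] * s[:k] @ vt[:k]
        recon = m.reduced_data @ m.mode_vectors.T
        assert np.allclose(recon, best, atol=1e-9)
        assert np.allclose(m.reduced_data, data @ m.mode_vectors)

    def test_invalid_mode_count(self, rng):
        with pytest.raises(ValueError, match="n_modes"):
            inv.reduce_temporal_modes(rng.normal(size=(4, 9)), 5)


class TestPriors:
    def test_mne_identity_over_space(self, tiny_bundle):
        for space in (tiny_bundle.space_cortical, tiny_bundle.space_combined):
            p = inv.build_prior_mne(space)
            assert len(p.components) == 1
            c = p.components[0]
            assert c.kind == "diag"
            assert np.array_equal(c.values, np.ones(space.n_vertices))

    def test_ebb_peaks_at_active_source(self, tiny_bundle):
        b = tiny_bundle
        w = sim.sinusoid_waveform()
        v = 321
        data = sim.simulate_patch_source(b.space_combined,
                                         b.leadfield_combined, v, w,
                                         fwhm_mm=0.5)
        modes = inv.reduce_temporal_modes(data, 1)
        p = inv.build_prior_ebb(b.leadfield_combined, modes)
        q = p.components[0].values
        assert int(np.argmax(q)) == v
        assert np.isclose(q.max(), 1.0)
        assert (q > 0).all()

    def test_ebb_scale_invariant(self, tiny_bundle):
        b = tiny_bundle
        w = sim.sinusoid_waveform()
        data = sim.simulate_patch_source(b.space_combined,
                                         b.leadfield_combined, 100, w)
        q1 = inv.build_prior_ebb(b.leadfield_combined,
                                 inv.reduce_temporal_modes(data, 1))
        q2 = inv.build_prior_ebb(b.leadfield_combined,
                                 inv.reduce_temporal_modes(10 * data, 1))
        assert np.allclose(q1.components[0].values,
                           q2.components[0].values, rtol=1e-9)

    def test_msp_patch_set(self, tiny_bundle):
        b = tiny_bundle
        rng = np.random.default_rng(0)
        seeds = rng.choice(b.space_combined.n_vertices, 100, replace=False)
        p = inv.build_prior_msp(b.space_combined, seeds, fwhm_mm=6.0)
        assert len(p.components) == 100
        from hippomeg.anatomy import patch_weights
        for comp, sv in list(zip(p.components, seeds))[::17]:
            assert comp.kind == "rank1"
            # support confined to the truncated patch of its seed
            support = comp.values > 0
            assert support[sv]
            Q = np.outer(comp.values, comp.values)
            evals = np.linalg.eigvalsh(Q[np.ix_(support, support)])
            assert evals.min() >= -1e-12 * evals.max()
            assert np.linalg.matrix_rank(Q[np.ix_(support, support)]) == 1

    def test_msp_duplicate_seeds_rejected(self, tiny_bundle):
        with pytest.raises(ValueError, match="duplicate"):
            inv.build_prior_msp(tiny_bundle.space_combined, [3, 3, 5])


def _reml_on(bundle, data, scheme="EBB", leadfield=None, n_modes=1, **kw):
    lf = leadfield or bundle.leadfield_combined
    modes = inv.reduce_temporal_modes(data, n_modes)
    if scheme == "MNE":
        priors = inv.build_prior_mne(bundle.space_combined)
    else:
        priors = inv.build_prior_ebb(lf, modes)
    return inv.reml_optimize(modes, lf, priors, **kw), modes


class TestReml:
    def test_deterministic(self, tiny_bundle):
        b = tiny_bundle
        data = sim.simulate_patch_source(
            b.space_combined, b.leadfield_combined, 50,
            sim.sinusoid_waveform())
        ds = sim.add_sensor_noise(data, snr_db=-5.0, rng_seed=3)
        r1, _ = _reml_on(b, ds.data)
        r2, _ = _reml_on(b, ds.data)
        assert r1.free_energy == r2.free_energy
        assert np.array_equal(r1.posterior_source_amplitude,
                              r2.posterior_source_amplitude)

    def test_accuracy_minus_complexity(self, tiny_bundle):
        b = tiny_bundle
        data = sim.simulate_patch_source(
            b.space_combined, b.leadfield_combined, 50,
            sim.sinusoid_waveform())
        ds = sim.add_sensor_noise(data, snr_db=-5.0, rng_seed=3)
        r, _ = _reml_on(b, ds.data)
        assert np.isclose(r.free_energy,
                          r.accuracy_term - r.complexity_term, atol=1e-9)
        assert r.complexity_term >= 0.0

    def test_hyperparameter_ratio_recovery(self, tiny_bundle):
        # data generated under the MNE generative model with known variances
        b = tiny_bundle
        lf = b.leadfield_combined
        rng = np.random.default_rng(5)
        nc, ns = lf.n_channels, lf.n_sources
        n_modes = 400
        sigma_s, sigma_n = 0.05, 2.0
        J = rng.normal(scale=sigma_s, size=(ns, n_modes))
        Y = lf.gain @ J + rng.normal(scale=sigma_n, size=(nc, n_modes))
        modes = inv.TemporalModes(reduced_data=Y,
                                  mode_vectors=np.eye(n_modes),
                                  n_modes=n_modes,
                                  retained_variance_fraction=1.0)
        priors = inv.build_prior_mne(b.space_combined)
        r = inv.reml_optimize(modes, lf, priors)
        lam = r.hyperparameters
        # undo the internal trace normalization of L L' to compare variances
        LLt_trace = np.trace(lf.gain @ lf.gain.T)
        est_ratio = np.exp(lam[1]) * (nc / LLt_trace) / np.exp(lam[0])
        true_ratio = sigma_s**2 / sigma_n**2
        assert abs(est_ratio / true_ratio - 1.0) < 0.10

    def test_duplicate_component_gains_nothing(self, tiny_bundle):
        """A redundant copy of a covariance component cannot improve the
        fit; the complexity penalty keeps F from rising beyond the Laplace
        log-coordinate slack for the degenerate pair (0.5 ln 2 nats, the
        split of one hyperparameter across two log-scale coordinates),
        which is far below the 3-nat decision threshold."""
        b = tiny_bundle
        data = sim.simulate_patch_source(
            b.space_combined, b.leadfield_combined, 50,
            sim.sinusoid_waveform())
        ds = sim.add_sensor_noise(data, snr_db=0.0, rng_seed=1)
        modes = inv.reduce_temporal_modes(ds.data, 1)
        base = inv.build_prior_ebb(b.leadfield_combined, modes)
        dup = inv.PriorComponentSet(
            scheme="MSP",  # container permitting multiple components
            components=base.components + base.components,
            n_sources=base.n_sources)
        r1 = inv.reml_optimize(modes, b.leadfield_combined, base)
        r2 = inv.reml_optimize(modes, b.leadfield_combined, dup)
        assert r2.accuracy_term <= r1.accuracy_term + 1e-6
        assert r2.free_energy <= r1.free_energy + 0.5 * np.log(2) + 1e-6

    def test_free_energy_matches_independent_objective(self, tiny_bundle):
        """Oracle: re-evaluate the Laplace free energy at the returned
        hyperparameters with an independent dense implementation."""
        b = tiny_bundle
        data = sim.simulate_patch_source(
            b.space_combined, b.leadfield_combined, 50,
            sim.sinusoid_waveform())
        ds = sim.add_sensor_noise(data, snr_db=-5.0, rng_seed=2)
        modes = inv.reduce_temporal_modes(ds.data, 1)
        rng = np.random.default_rng(0)
        seeds = rng.choice(b.space_combined.n_vertices, 30, replace=False)
        priors = inv.build_prior_msp(b.space_combined, seeds, fwhm_mm=6.0)
        r = inv.reml_optimize(modes, b.leadfield_combined, priors)

        # --- independent evaluation, dense matrices throughout
        Y = modes.reduced_data
        nc, nm = Y.shape
        S = Y @ Y.T / nm
        S = S / (np.trace(S) / nc)
        L = b.leadfield_combined.gain
        comps = [np.eye(nc)]
        for c in priors.components:
            Q = np.outer(L @ c.values, L @ c.values)
            comps.append(Q * nc / np.trace(Q))
        lam = r.hyperparameters
        active = np.isfinite(lam)
        Sigma = sum(np.exp(lam[j]) * comps[j]
                    for j in range(len(comps)) if active[j])
        sgn, logdet = np.linalg.slogdet(Sigma)
        ll = -0.5 * nm * (nc * np.log(2 * np.pi) + logdet
                          + np.trace(np.linalg.solve(Sigma, S)))
        pi = 1.0 / 256.0
        act = np.flatnonzero(active)
        quad = 0.5 * pi * np.sum((lam[act] + 5.0) ** 2)
        P = np.linalg.inv(Sigma)
        k = len(act)
        H = np.zeros((k, k))
        for a, ja in enumerate(act):
            for b_, jb in enumerate(act):
                H[a, b_] = 0.5 * nm * np.trace(
                    P @ (np.exp(lam[ja]) * comps[ja])
                    @ P @ (np.exp(lam[jb]) * comps[jb]))
        occam = 0.5 * np.linalg.slogdet(np.eye(k) + H / pi)[1]
        F_oracle = ll - quad - occam
        assert np.isclose(r.free_energy, F_oracle, atol=1e-6)

    def test_nonconvergence_flagged_not_fatal(self, tiny_bundle):
        b = tiny_bundle
        data = sim.simulate_patch_source(
            b.space_combined, b.leadfield_combined, 50,
            sim.sinusoid_waveform())
        ds = sim.add_sensor_noise(data, snr_db=-5.0, rng_seed=3)
        modes = inv.reduce_temporal_modes(ds.data, 1)
        priors = inv.build_prior_ebb(b.leadfield_combined, modes)
        r = inv.reml_optimize(modes, b.leadfield_combined, priors, max_iter=2)
        assert not r.converged
        assert np.isfinite(r.free_energy)


class TestVarianceExplained:
    def test_noiseless_rank1_near_perfect(self, tiny_bundle):
        b = tiny_bundle
        data = sim.simulate_patch_source(
            b.space_combined, b.leadfield_combined, 50,
            sim.sinusoid_waveform())
        r, modes = _reml_on(b, data, scheme="MNE")
        assert r.variance_explained_pct >= 99.9
        assert np.isclose(
            inv.variance_explained(r, modes, b.leadfield_combined),
            r.variance_explained_pct, atol=1e-9)

    def test_zero_posterior_explains_nothing(self, tiny_bundle):
        b = tiny_bundle
        data = sim.simulate_patch_source(
            b.space_combined, b.leadfield_combined, 50,
            sim.sinusoid_waveform())
        r, modes = _reml_on(b, data)
        z = dataclasses.replace(
            r, posterior_mean_sources=np.zeros_like(r.posterior_mean_sources))
        assert inv.variance_explained(z, modes, b.leadfield_combined) == 0.0

    def test_bounds(self, tiny_bundle):
        b = tiny_bundle
        data = sim.simulate_patch_source(
            b.space_combined, b.leadfield_combined, 50,
            sim.sinusoid_waveform())
        ds = sim.add_sensor_noise(data, snr_db=-20.0, rng_seed=0)
        r, _ = _reml_on(b, ds.data)
        assert 0.0 <= r.variance_explained_pct <= 100.0


class TestCentralMechanism:
    """High-SNR hippocampal sources must favour the combined model."""

    @pytest.mark.parametrize("scheme", ["EBB", "MSP"])
    def test_combined_beats_cortical_on_hippocampal_data(self, tiny_bundle,
                                                         scheme):
        b = tiny_bundle
        rng = np.random.default_rng(2)
        hip = b.hippo_offset + rng.choice(b.hippocampus.n_vertices, 3,
                                          replace=False)
        cort_seeds = rng.choice(b.cortex.n_vertices, 90, replace=False)
        for v in hip:
            data = sim.simulate_patch_source(
                b.space_combined, b.leadfield_combined, int(v),
                sim.sinusoid_waveform())
            ds = sim.add_sensor_noise(data, snr_db=0.0, rng_seed=int(v))
            modes = inv.reduce_temporal_modes(ds.data, 1)
            if scheme == "EBB":
                F = {}
                for name, lf in (("combined", b.leadfield_combined),
                                 ("cortical", b.leadfield_cortical)):
                    p = inv.build_prior_ebb(lf, modes)
                    F[name] = inv.reml_optimize(modes, lf, p).free_energy
            else:
                hip_set = np.concatenate([[v], b.hippo_offset + rng.choice(
                    b.hippocampus.n_vertices, 9, replace=False)])
                hip_set = np.unique(hip_set)
                pc = inv.build_prior_msp(
                    b.space_combined, np.concatenate([cort_seeds[:90],
                                                      hip_set]))
                po = inv.build_prior_msp(b.space_combined, cort_seeds[:90])
                F = {"combined": inv.reml_optimize(
                        modes, b.leadfield_combined, pc).free_energy,
                     "cortical": inv.reml_optimize(
                        modes, b.leadfield_combined, po).free_energy}
            assert F["combined"] > F["cortical"]
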