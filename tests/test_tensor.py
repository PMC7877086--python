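import dataclasses

import numpy as np
import pytest

from ecvtask import pipeline, tensor
from ecvtask.realtime import BinAssignment
from ecvtask.sequence import T1Basis


def random_orthonormal(rng, n, k):
    q, _ = np.linalg.qr(rng.standard_normal((n, k)))
    return q


def make_multilinear(rng, shape, ranks):
    core = rng.standard_normal(ranks)
    factors = [random_orthonormal(rng, n, r) for n, r in zip(shape, ranks)]
    return tensor.tucker_reconstruct(core, factors), factors


class TestTensorAlgebra:
    def test_unfold_fold_roundtrip(self):
        rng = np.random.default_rng(0)
        t = rng.standard_normal((4, 5, 6, 7))
        for mode in range(4):
            np.testing.assert_array_equal(
                tensor.fold(tensor.unfold(t, mode), mode, t.shape), t)

    def test_mode_product_matches_unfold(self):
        rng = np.random.default_rng(1)
        t = rng.standard_normal((4, 5, 6))
        m = rng.standard_normal((3, 5))
        out = tensor.mode_product(t, m, 1)
        ref = tensor.fold(m @ tensor.unfold(t, 1), 1, (4, 3, 6))
        np.testing.assert_allclose(out, ref, atol=1e-12)

    def test_hosvd_exact_for_low_rank(self):
        rng = np.random.default_rng(2)
        t, _ = make_multilinear(rng, (10, 8, 6), (3, 2, 2))
        factors, core = tensor.hosvd(t, (3, 2, 2))
        rec = tensor.tucker_reconstruct(core, factors)
        np.testing.assert_allclose(rec, t, atol=1e-10)
        for u in factors:
            np.testing.assert_allclose(u.conj().T @ u, np.eye(u.shape[1]),
                                       atol=1e-10)

    def test_hosvd_error_bound(self):
        # truncation error^2 <= sum of discarded singular values^2 over modes
        rng = np.random.default_rng(3)
        t = rng.standard_normal((8, 7, 6))
        ranks = (4, 3, 3)
        factors, core = tensor.hosvd(t, ranks)
        rec = tensor.tucker_reconstruct(core, factors)
        bound = 0.0
        for mode, r in enumerate(ranks):
            s = np.linalg.svd(tensor.unfold(t, mode), compute_uv=False)
            bound += np.sum(s[r:] ** 2)
        assert np.linalg.norm(rec - t) ** 2 <= bound + 1e-9

    def test_rank_too_large_raises(self):
        with pytest.raises(ValueError):
            tensor.mode_svd(np.zeros((3, 4)), 0, 10)


class TestFormTrainingTensor:
    def test_cells_and_mask(self, tiny_cfg, tiny_dataset):
        ds = tiny_dataset
        bins = BinAssignment(
            readout_id=np.arange(ds.n_readouts), scan=ds.scan.copy(),
            cardiac_bin=ds.ground_truth.cardiac_bin.copy(),
            resp_bin=ds.ground_truth.resp_bin.copy(),
            t1_index=ds.t1_index.copy(),
            n_cardiac=tiny_cfg.phantom.n_cardiac_bins,
            n_resp=tiny_cfg.phantom.n_resp_bins)
        tt = tensor.form_training_tensor(ds, bins)
        n = ds.seq.readouts_per_period
        assert tt.data.shape == (ds.seq.matrix, 10, 5, 2 * n)
        # only even t1 indices are training
        occupied_tau = np.any(tt.counts > 0, axis=(0, 1))
        assert not np.any(occupied_tau[0::2])  # odd tau (0-based even) empty
        assert 0.0 < tt.observed_fraction < 1.0
        # spot check one cell mean
        tr = ds.is_training
        c, r = 1, 1
        tau = 2
        sel = (tr & (ds.ground_truth.cardiac_bin == c)
               & (ds.ground_truth.resp_bin == r) & (ds.t1_index == tau)
               & (ds.scan == 0))
        if np.any(sel):
            np.testing.assert_allclose(
                tt.data[:, c - 1, r - 1, tau - 1],
                ds.lines[sel].mean(axis=0), atol=1e-12)

    def test_averaging_identical_lines(self, tiny_dataset):
        ds = tiny_dataset
        # all readouts into one cell: mean of identical lines equals the line
        line = ds.lines[ds.is_training][:1]
        import copy
        ds2 = copy.copy(ds)
        n_tr = int(np.sum(ds.is_training))
        ds2.lines = np.tile(line, (ds.n_readouts, 1))
        bins = BinAssignment(
            readout_id=np.arange(ds.n_readouts), scan=np.zeros(ds.n_readouts, int),
            cardiac_bin=np.ones(ds.n_readouts, int),
            resp_bin=np.ones(ds.n_readouts, int),
            t1_index=np.full(ds.n_readouts, 2), n_cardiac=1, n_resp=1)
        tt = tensor.form_training_tensor(ds2, bins)
        np.testing.assert_allclose(tt.data[:, 0, 0, 1], line[0], atol=1e-12)


class TestCompletion:
    def test_fixed_point_fully_observed(self):
        rng = np.random.default_rng(4)
        shape, ranks = (16, 6, 4, 32), (5, 3, 2, 4)
        t, factors = make_multilinear(rng, shape, ranks)
        u_t1 = factors[3]
        tt = tensor.TrainingTensor(data=t.astype(complex),
                                   mask=np.ones(shape, bool),
                                   counts=np.ones(shape[1:]))
        completed, info = tensor.complete_training_tensor(
            tt, u_t1, ranks, max_iter=5)
        assert np.linalg.norm(completed - t) / np.linalg.norm(t) < 1e-10
        assert info["observed_residual"] < 1e-10

    def test_synthetic_completion_oracle(self):
        # multilinear-rank-(8,3,2,4) tensor, 32x10x5x64, 40% observed
        rng = np.random.default_rng(5)
        shape, ranks = (32, 10, 5, 64), (8, 3, 2, 4)
        t, factors = make_multilinear(rng, shape, ranks)
        mask = rng.random(shape) < 0.4
        data = np.where(mask, t, 0.0).astype(complex)
        tt = tensor.TrainingTensor(data=data, mask=mask,
                                   counts=mask[0].astype(float))
        completed, info = tensor.complete_training_tensor(
            tt, factors[3], ranks, tol=1e-12, max_iter=2000)
        err = np.linalg.norm(completed - t) / np.linalg.norm(t)
        assert err < 1e-3

    def test_more_masking_not_better(self):
        # prediction error on the entries of the FULL observation set grows
        # (or stays) as observations are removed from it
        rng = np.random.default_rng(6)
        shape, ranks = (16, 8, 4, 32), (5, 3, 2, 4)
        t, factors = make_multilinear(rng, shape, ranks)
        noisy = t + 0.01 * rng.standard_normal(shape)
        u = rng.random(shape)
        probe = u >= 0.7  # never observed at any masking level
        errs = []
        for frac in (0.7, 0.45, 0.2):
            mask = u < frac  # nested masks: smaller frac = strictly fewer obs
            tt = tensor.TrainingTensor(data=np.where(mask, noisy, 0.0).astype(complex),
                                       mask=mask, counts=mask[0].astype(float))
            completed, _ = tensor.complete_training_tensor(
                tt, factors[3], ranks, tol=1e-10, max_iter=400)
            errs.append(np.linalg.norm(completed[probe] - t[probe])
                        / np.linalg.norm(t[probe]))
        assert errs[0] <= errs[1] * 1.05 <= errs[2] * 1.1

    def test_empty_tensor_raises(self, tiny_dataset):
        import copy
        ds = copy.copy(tiny_dataset)
        ds.lines = tiny_dataset.lines.copy()
        bad = BinAssignment(
            readout_id=np.arange(ds.n_readouts), scan=ds.scan.copy(),
            cardiac_bin=np.ones(ds.n_readouts, int),
            resp_bin=np.ones(ds.n_readouts, int),
            t1_index=ds.t1_index.copy(), n_cardiac=1, n_resp=1)
        import numpy as _np
        ds.is_training = _np.zeros(ds.n_readouts, bool)
        with pytest.raises(ValueError):
            tensor.form_training_tensor(ds, bad)


class TestFactorsAndPhi:
    def _factored(self, rng, shape=(16, 6, 4, 32), ranks=(5, 3, 2, 4)):
        t, factors = make_multilinear(rng, shape, ranks)
        cfg = tensor.ReconConfig(rank_spatial=ranks[0], rank_cardiac=ranks[1],
                                 rank_resp=ranks[2], rank_t1=ranks[3])
        return t, factors, tensor.extract_factors(t, factors[3], cfg)

    def test_phi_kronecker_formula(self):
        rng = np.random.default_rng(7)
        t, factors, fimg = self._factored(rng)
        kron = np.kron(np.kron(fimg.u_c, fimg.u_r), fimg.u_t1)
        c1 = tensor.unfold(fimg.core, 0)
        np.testing.assert_allclose(fimg.phi, c1 @ kron.T, atol=1e-10)

    def test_phi_reconstructs_mode1_unfolding(self):
        rng = np.random.default_rng(8)
        t, factors, fimg = self._factored(rng)
        a1 = tensor.unfold(t, 0)
        np.testing.assert_allclose(fimg.u_k @ fimg.phi, a1, atol=1e-8)

    def test_orthonormal_factors(self):
        rng = np.random.default_rng(9)
        _, _, fimg = self._factored(rng)
        for u in (fimg.u_c, fimg.u_r):
            np.testing.assert_allclose(u.conj().T @ u, np.eye(u.shape[1]),
                                       atol=1e-10)

    def test_rank1_tensor(self):
        rng = np.random.default_rng(10)
        t, factors, fimg = self._factored(rng, ranks=(1, 1, 1, 1))
        core = fimg.core.ravel()
        assert abs(core[0]) > 0
        np.testing.assert_allclose(fimg.u_k @ fimg.phi, tensor.unfold(t, 0),
                                   atol=1e-8)

    def test_out_of_range_bin_raises(self):
        rng = np.random.default_rng(11)
        _, _, fimg = self._factored(rng)
        fimg.u_x = np.zeros((16, fimg.phi.shape[0]))
        with pytest.raises(IndexError):
            tensor.reconstruct_image(fimg, 99, 1)


class TestSpatialSolve:
    @pytest.fixture(scope="class")
    def recon_setup(self, tiny_cfg, tiny_dataset):
        dictionary, basis = pipeline.build_t1_model(tiny_cfg)
        bins, _, _ = pipeline.run_binning(tiny_dataset, basis, tiny_cfg,
                                          dictionary)
        tt = tensor.form_training_tensor(tiny_dataset, bins)
        completed, _ = tensor.complete_training_tensor(
            tt, basis, tiny_cfg.recon.ranks, max_iter=40)
        fimg = tensor.extract_factors(completed, basis, tiny_cfg.recon)
        return bins, fimg

    def test_negative_lambda_rejected(self):
        with pytest.raises(ValueError):
            tensor.ReconConfig(lam=-1.0)

    def test_two_solver_agreement_lambda_zero(self, tiny_cfg, tiny_dataset,
                                              recon_setup):
        bins, fimg = recon_setup
        import copy
        f1 = copy.deepcopy(fimg)
        cfg = dataclasses.replace(tiny_cfg.recon, lam=0.0, fista_max_iter=300,
                                  fista_tol=1e-12)
        tensor.solve_spatial_basis(tiny_dataset, bins, f1, cfg, damp=1e-9)
        u_cg = tensor.solve_spatial_basis_cg(tiny_dataset, bins, fimg,
                                             tol=1e-10, max_iter=2000)
        # both minimize the same least-squares objective
        sampler, d = tensor._imaging_sampler(tiny_dataset, bins, fimg.dims)
        r1 = np.linalg.norm(sampler.forward(f1.u_x, fimg.phi) - d)
        r2 = np.linalg.norm(sampler.forward(u_cg, fimg.phi) - d)
        # CG converges slowly on this ill-conditioned undersampled system;
        # exact-route agreement at tight tolerance is covered on the
        # well-conditioned synthetic problem in test_realtime
        assert abs(r1 - r2) / np.linalg.norm(d) < 1e-3

    def test_zero_data_zero_solution(self, tiny_cfg, tiny_dataset, recon_setup):
        bins, fimg = recon_setup
        import copy
        ds = copy.copy(tiny_dataset)
        ds.lines = np.zeros_like(tiny_dataset.lines)
        f = copy.deepcopy(fimg)
        cfg = dataclasses.replace(tiny_cfg.recon, lam=0.0, fista_max_iter=20)
        tensor.solve_spatial_basis(ds, bins, f, cfg)
        assert np.linalg.norm(f.u_x) < 1e-10

    def test_series_has_2n_frames(self, tiny_cfg, tiny_dataset, recon_setup):
        bins, fimg = recon_setup
        import copy
        f = copy.deepcopy(fimg)
        cfg = dataclasses.replace(tiny_cfg.recon, fista_max_iter=10)
        tensor.solve_spatial_basis(tiny_dataset, bins, f, cfg)
        series = tensor.fitting_series(f, 1, 1)
        assert series.shape == (tiny_dataset.seq.matrix ** 2,
                                2 * tiny_dataset.seq.readouts_per_period)
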