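"""Low-rank tensor completion, HOSVD factorization and spatial-basis recovery.

The binned training lines form a 4-way tensor D_tr with modes
(k-readout, cardiac, respiratory, T1-recovery); the T1 mode spans the
832-sample pre+post concatenation.  Completion alternates (a) projection of
the T1 mode onto the Bloch-simulated subspace, (b) multilinear rank truncation
by HOSVD and (c) restoration of the observed entries.  The completed tensor's
HOSVD fixes the temporal subspace Phi = C_(1) (U_c kron U_r kron U_T1)^T; the
spatial basis U_x is then recovered from the imaging lines by FISTA with an
orthogonal-wavelet l1 penalty.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from . import wavelet
from .encoding import LineSampler, cg_solve, direct_solve
from .phantom import KSpaceDataset
from .realtime import BinAssignment
from .sequence import T1Basis


@dataclass
class ReconConfig:
    rank_spatial: int = 32      # L: mode-1 (k/spatial) rank
    rank_cardiac: int = 6
    rank_resp: int = 4
    rank_t1: int = 12
    lam: float | None = 0.0     # None -> lam_scale * max |W(E^H d)|
    lam_scale: float = 0.01
    damp: float = 0.05          # relative Tikhonov weight on U_x
    wavelet_levels: int = 3
    fista_max_iter: int = 150
    fista_tol: float = 1e-6
    completion_max_iter: int = 100
    completion_tol: float = 1e-6

    def __post_init__(self) -> None:
        for r in (self.rank_spatial, self.rank_cardiac, self.rank_resp, self.rank_t1):
            if r <= 0:
                raise ValueError("ranks must be positive")
        if self.lam is not None and self.lam < 0:
            raise ValueError("lambda must be >= 0")

    @property
    def ranks(self) -> tuple:
        return (self.rank_spatial, self.rank_cardiac, self.rank_resp, self.rank_t1)


@dataclass
class TrainingTensor:
    data: np.ndarray      # (matrix, Kc, Kr, 2N) complex, cell means
    mask: np.ndarray      # same shape, True where observed
    counts: np.ndarray    # (Kc, Kr, 2N) lines averaged per cell

    @property
    def observed_fraction(self) -> float:
        return float(np.mean(self.counts > 0))


@dataclass
class FactoredImage:
    """U_x Phi factorization with Phi assembled from HOSVD factors."""

    u_c: np.ndarray              # (Kc, Lc)
    u_r: np.ndarray              # (Kr, Lr)
    u_t1: np.ndarray             # (2N, Lt)
    core: np.ndarray             # (L, Lc, Lr, Lt)
    phi: np.ndarray              # (L, Kc*Kr*2N)
    dims: tuple                  # (Kc, Kr, 2N)
    matrix: int
    u_x: np.ndarray | None = None  # (n_pixels, L)
    u_k: np.ndarray | None = None  # (matrix, L) k-mode factor of D_tr
    meta: dict = field(default_factory=dict)

    def phi_column(self, c: int, r: int, tau: int) -> int:
        kc, kr, nt = self.dims
        if not (0 <= c < kc and 0 <= r < kr and 0 <= tau < nt):
            raise IndexError(f"bin index ({c}, {r}, {tau}) out of range {self.dims}")
        return (c * kr + r) * nt + tau


# --------------------------------------------------------------------------- #
# tensor algebra
# --------------------------------------------------------------------------- #


def unfold(t: np.ndarray, mode: int) -> np.ndarray:
    return np.moveaxis(t, mode, 0).reshape(t.shape[mode], -1)


def fold(mat: np.ndarray, mode: int, shape: tuple) -> np.ndarray:
    full = [shape[mode]] + [s for i, s in enumerate(shape) if i != mode]
    return np.moveaxis(mat.reshape(full), 0, mode)


def mode_product(t: np.ndarray, m: np.ndarray, mode: int) -> np.ndarray:
    """Tensor-times-matrix along ``mode`` (m: new_dim x old_dim)."""
    return np.moveaxis(np.tensordot(m, t, axes=(1, mode)), 0, mode)


def mode_svd(t: np.ndarray, mode: int, rank: int) -> np.ndarray:
    mat = unfold(t, mode)
    if rank > min(mat.shape):
        raise ValueError(f"rank {rank} exceeds mode-{mode} dimension {mat.shape}")
    u, _, _ = np.linalg.svd(mat, full_matrices=False)
    return u[:, :rank]


def hosvd(t: np.ndarray, ranks: tuple):
    """Orthonormal factors and core of a truncated HOSVD."""
    factors = [mode_svd(t, m, r) for m, r in enumerate(ranks)]
    core = t
    for m, u in enumerate(factors):
        core = mode_product(core, u.conj().T, m)
    return factors, core


def tucker_reconstruct(core: np.ndarray, factors: list) -> np.ndarray:
    t = core
    for m, u in enumerate(factors):
        t = mode_product(t, u, m)
    return t


# --------------------------------------------------------------------------- #
# training tensor
# --------------------------------------------------------------------------- #


def form_training_tensor(dataset: KSpaceDataset,
                         bins: BinAssignment) -> TrainingTensor:
    """Cell (k, c, r, tau) = mean of all training lines with that bin triple."""
    tr = dataset.is_training
    if not np.any(tr):
        raise ValueError("dataset contains no training readouts")
    n = dataset.seq.readouts_per_period
    m = dataset.seq.matrix
    kc, kr = bins.n_cardiac, bins.n_resp
    c = bins.cardiac_bin[tr] - 1
    r = bins.resp_bin[tr] - 1
    tau = bins.t1_index[tr] - 1 + dataset.scan[tr] * n
    acc = np.zeros((kc, kr, 2 * n, m), dtype=complex)
    counts = np.zeros((kc, kr, 2 * n))
    np.add.at(acc, (c, r, tau), dataset.lines[tr])
    np.add.at(counts, (c, r, tau), 1.0)
    if not np.any(counts):
        raise ValueError("all training-tensor cells are empty")
    with np.errstate(invalid="ignore", divide="ignore"):
        acc /= counts[..., None]
    acc[counts == 0] = 0.0
    data = np.moveaxis(acc, -1, 0)  # (m, kc, kr, 2N)
    mask = np.broadcast_to((counts > 0)[None], data.shape).copy()
    return TrainingTensor(data=data, mask=mask, counts=counts)


def _subspace_fill(data: np.ndarray, mask: np.ndarray,
                   u: np.ndarray) -> np.ndarray:
    """Initialize missing entries from the U_T1-projected observed fibers."""
    out = data.copy()
    nk, kc, kr, nt = data.shape
    cell_mask = mask[0] if np.all(mask == mask[:1]) else None
    if cell_mask is None:
        return out  # arbitrary mask: zero-fill initialization
    lam = 1e-3
    for c in range(kc):
        for r in range(kr):
            obs = cell_mask[c, r]
            if np.sum(obs) < 2 * u.shape[1]:
                continue  # too few samples for a stable fit; leave zeros
            ub = u[obs]
            gram = ub.T @ ub + lam * np.eye(u.shape[1])
            coef = np.linalg.solve(gram, ub.T @ data[:, c, r, obs].T)
            out[:, c, r, ~obs] = (u[~obs] @ coef).T
    return out


def complete_training_tensor(tensor: TrainingTensor, u_t1: T1Basis | np.ndarray,
                             ranks: tuple, *, tol: float = 1e-6,
                             max_iter: int = 100):
    """Bloch-constrained low-rank completion of the training tensor.

    Alternates T1-subspace projection, HOSVD rank truncation and restoration
    of the observed entries.  Returns ``(completed, info)`` where ``info``
    records iterations, convergence and the observed-entry model residual
    (before the final restore step).
    """
    u = u_t1.basis if isinstance(u_t1, T1Basis) else np.asarray(u_t1)
    data, mask = tensor.data, tensor.mask
    obs = data[mask]
    obs_norm = np.linalg.norm(obs)
    ranks = tuple(min(r, s) for r, s in zip(ranks, data.shape))
    lt = min(ranks[3], u.shape[1])
    u = u[:, :lt]
    t = _subspace_fill(data, mask, u)
    info = {"n_iter": 0, "converged": False, "observed_residual": np.inf}
    for it in range(max_iter):
        # (a) project the T1 mode onto span(U_T1)
        coef = np.tensordot(t, u.conj(), axes=(3, 0))  # (m, kc, kr, lt)
        # (b) multilinear rank truncation (modes 0-2 on the compressed tensor)
        eff = [min(r, coef.shape[mode], coef.size // coef.shape[mode])
               for mode, r in enumerate(ranks[:3])]
        factors = [mode_svd(coef, mode, r) for mode, r in enumerate(eff)]
        core = coef
        for mode, f in enumerate(factors):
            core = mode_product(core, f.conj().T, mode)
        t_new = tucker_reconstruct(core, factors)
        t_new = np.tensordot(t_new, u.T, axes=(3, 0))  # back to full T1 axis
        # (c) data consistency on observed entries
        resid = np.linalg.norm(t_new[mask] - obs) / max(obs_norm, 1e-300)
        t_new[mask] = obs
        change = np.linalg.norm(t_new - t) / max(np.linalg.norm(t), 1e-300)
        t = t_new
        info.update(n_iter=it + 1, observed_residual=float(resid))
        if change < tol:
            info["converged"] = True
            break
    if not info["converged"]:
        warnings.warn(
            f"tensor completion did not reach tol={tol} in {max_iter} "
            "iterations; returning best iterate", RuntimeWarning)
    return t, info


def extract_factors(completed: np.ndarray, u_t1: T1Basis | np.ndarray,
                    config: ReconConfig) -> FactoredImage:
    """HOSVD factors of the completed tensor and the assembled Phi."""
    u = u_t1.basis if isinstance(u_t1, T1Basis) else np.asarray(u_t1)
    nk, kc, kr, nt = completed.shape
    size = completed.size
    ranks = (min(config.rank_spatial, nk, size // nk),
             min(config.rank_cardiac, kc, size // kc),
             min(config.rank_resp, kr, size // kr),
             min(config.rank_t1, u.shape[1]))
    u = u[:, :ranks[3]]
    u_k = mode_svd(completed, 0, ranks[0])
    u_c = mode_svd(completed, 1, ranks[1])
    u_r = mode_svd(completed, 2, ranks[2])
    core = completed
    for mode, f in enumerate((u_k, u_c, u_r, u)):
        core = mode_product(core, f.conj().T, mode)
    phi_t = core
    for mode, f in enumerate((u_c, u_r, u), start=1):
        phi_t = mode_product(phi_t, f, mode)
    phi = phi_t.reshape(ranks[0], kc * kr * nt)
    return FactoredImage(u_c=u_c, u_r=u_r, u_t1=u, core=core, phi=phi,
                         dims=(kc, kr, nt), matrix=nk, u_k=u_k)


# --------------------------------------------------------------------------- #
# spatial basis recovery
# --------------------------------------------------------------------------- #


def _imaging_sampler(dataset: KSpaceDataset, bins: BinAssignment,
                     dims: tuple) -> tuple:
    kc, kr, nt = dims
    n = dataset.seq.readouts_per_period
    im = ~dataset.is_training
    tau = bins.t1_index[im] - 1 + dataset.scan[im] * n
    cols = ((bins.cardiac_bin[im] - 1) * kr + (bins.resp_bin[im] - 1)) * nt + tau
    sampler = LineSampler(dataset.ky_index[im], cols, dataset.seq.matrix)
    return sampler, dataset.lines[im]


def solve_spatial_basis(dataset: KSpaceDataset, bins: BinAssignment,
                        fimg: FactoredImage, config: ReconConfig,
                        damp: float | None = None) -> np.ndarray:
    """Wavelet-regularized spatial-basis recovery; updates ``fimg.u_x``.

    Minimizes ||d - Omega(E U Phi)||^2/2 + mu ||U||^2/2 + lam ||W U||_1 by
    FISTA, warm-started from the Tikhonov-damped per-ky-row direct solution
    (mu = damp * mean sampling density keeps rarely sampled frequencies from
    being amplified).
    """
    sampler, d = _imaging_sampler(dataset, bins, fimg.dims)
    rank = fimg.phi.shape[0]
    m = dataset.seq.matrix
    lev = config.wavelet_levels
    damp = config.damp if damp is None else damp
    # work in the row-equilibrated temporal basis so the quadratic penalty
    # weighs all temporal components uniformly (see encoding.direct_solve)
    row_scale = np.linalg.norm(fimg.phi, axis=1)
    row_scale = np.maximum(row_scale, 1e-12 * max(row_scale.max(), 1e-300))
    phi = fimg.phi / row_scale[:, None]
    lip = sampler.lipschitz(phi)
    # mu on the same scale as direct_solve (mean per-row Gram trace / rank)
    traces = [np.trace(phi[:, sampler.cols[idx]]
                       @ phi[:, sampler.cols[idx]].conj().T).real
              for _, idx in sampler._groups]
    mu = damp * max(float(np.mean(traces)) / rank, 1e-300)
    step = 1.0 / max(lip + mu, 1e-300)
    lam = config.lam
    if lam is None:
        g0 = sampler.adjoint(d, phi, rank)
        w0 = wavelet.dwt2(g0.T.reshape(rank, m, m), levels=lev)
        lam = config.lam_scale * float(np.max(np.abs(w0)))
    dmask = wavelet.detail_mask((m, m), levels=lev)

    def prox(u_mat: np.ndarray, thresh: float) -> np.ndarray:
        if thresh <= 0:
            return u_mat
        c = wavelet.dwt2(u_mat.T.reshape(rank, m, m), levels=lev)
        c[:, dmask] = wavelet.soft_threshold(c[:, dmask], thresh)
        return wavelet.idwt2(c, levels=lev).reshape(rank, m * m).T

    def objective(u_mat: np.ndarray) -> float:
        res = sampler.forward(u_mat, phi) - d
        f = 0.5 * np.vdot(res, res).real + 0.5 * mu * np.vdot(u_mat, u_mat).real
        if lam > 0:
            c = wavelet.dwt2(u_mat.T.reshape(rank, m, m), levels=lev)
            f += lam * float(np.sum(np.abs(c[:, dmask])))
        return f

    def gradient(u_mat: np.ndarray) -> np.ndarray:
        return sampler.adjoint(sampler.forward(u_mat, phi) - d, phi,
                               rank) + mu * u_mat

    x = direct_solve(sampler, d, fimg.phi, rank, damp=damp) * row_scale[None, :]
    y = x.copy()
    tk = 1.0
    obj_prev = objective(x)
    for _ in range(config.fista_max_iter):
        x_new = prox(y - step * gradient(y), lam * step)
        obj = objective(x_new)
        if obj > obj_prev:  # restart momentum on objective increase
            tk = 1.0
            x_new = prox(x - step * gradient(x), lam * step)
            obj = objective(x_new)
        tk_new = (1.0 + np.sqrt(1.0 + 4.0 * tk * tk)) / 2.0
        y = x_new + ((tk - 1.0) / tk_new) * (x_new - x)
        rel = abs(obj_prev - obj) / max(abs(obj_prev), 1e-300)
        x, tk, obj_prev = x_new, tk_new, obj
        if rel < config.fista_tol:
            break
    fimg.u_x = x / row_scale[None, :]
    fimg.meta["lambda"] = lam
    fimg.meta["mu"] = mu
    return fimg.u_x


def solve_spatial_basis_cg(dataset: KSpaceDataset, bins: BinAssignment,
                           fimg: FactoredImage, tol: float = 1e-8,
                           max_iter: int = 400) -> np.ndarray:
    """Unregularized least-squares solution (independent CG route)."""
    sampler, d = _imaging_sampler(dataset, bins, fimg.dims)
    return cg_solve(sampler, d, fimg.phi, fimg.phi.shape[0],
                    tol=tol, max_iter=max_iter)


def reconstruct_image(fimg: FactoredImage, cardiac_bin: int, resp_bin: int,
                      t1_range=None) -> np.ndarray:
    """Image series (n_tau, matrix, matrix) for one (cardiac, resp) bin pair."""
    if fimg.u_x is None:
        raise ValueError("spatial basis not solved yet")
    kc, kr, nt = fimg.dims
    taus = np.arange(nt) if t1_range is None else np.asarray(t1_range)
    cols = [fimg.phi_column(cardiac_bin - 1, resp_bin - 1, int(t)) for t in taus]
    m = int(np.sqrt(fimg.u_x.shape[0]))
    series = (fimg.u_x @ fimg.phi[:, cols]).T.reshape(len(cols), m, m)
    return series


def fitting_series(fimg: FactoredImage, cardiac_bin: int,
                   resp_bin: int) -> np.ndarray:
    """Per-pixel 2N-frame curves (n_pixels, 2N) at one motion state."""
    kc, kr, nt = fimg.dims
    start = fimg.phi_column(cardiac_bin - 1, resp_bin - 1, 0)
    return fimg.u_x @ fimg.phi[:, start:start + nt]
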