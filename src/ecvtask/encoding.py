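"""Single-coil Cartesian line-sampling encoding operator.

k-space uses the centered convention: the full spectrum of an image is
``fftshift(fft2(img, norm="ortho"))`` with DC at index ``matrix // 2`` and the
integer ky of row ``m`` equal to ``m - matrix // 2``.  Only one ky row is
sampled per readout (frequency encode fully sampled), so forward/adjoint are
grouped by ky for speed.
"""

from __future__ import annotations

import numpy as np


def fft2c(img: np.ndarray) -> np.ndarray:
    """Centered orthonormal 2D DFT over the last two axes."""
    return np.fft.fftshift(np.fft.fft2(img, norm="ortho"), axes=(-2, -1))


def ifft2c(ksp: np.ndarray) -> np.ndarray:
    """Inverse of :func:`fft2c`."""
    return np.fft.ifft2(np.fft.ifftshift(ksp, axes=(-2, -1)), norm="ortho")


class LineSampler:
    """Forward/adjoint of d = Omega(E U Phi) for per-readout (ky, column) pairs.

    Parameters
    ----------
    ky : (n_readouts,) int array, centered convention.
    cols : (n_readouts,) int array, column of Phi each readout maps to.
    matrix : image side length.
    """

    def __init__(self, ky: np.ndarray, cols: np.ndarray, matrix: int):
        if len(ky) == 0:
            raise ValueError("no readouts to sample")
        self.ky = np.asarray(ky, dtype=int)
        self.cols = np.asarray(cols, dtype=int)
        self.matrix = int(matrix)
        rows = self.ky + self.matrix // 2
        if rows.min() < 0 or rows.max() >= self.matrix:
            raise ValueError("ky index out of range")
        self._rows = rows
        order = np.argsort(rows, kind="stable")
        self._order = order
        uniq, starts = np.unique(rows[order], return_index=True)
        self._groups = [
            (int(u), order[s:e])
            for u, s, e in zip(uniq, starts, list(starts[1:]) + [len(rows)])
        ]

    @property
    def n_readouts(self) -> int:
        return len(self.ky)

    def forward(self, u: np.ndarray, phi: np.ndarray) -> np.ndarray:
        """U: (n_pix, L); Phi: (L, n_cols) -> lines (n_readouts, matrix)."""
        m, L = self.matrix, u.shape[1]
        g = fft2c(u.T.reshape(L, m, m))
        out = np.empty((self.n_readouts, m), dtype=complex)
        for row, idx in self._groups:
            out[idx] = phi[:, self.cols[idx]].T @ g[:, row, :]
        return out

    def adjoint(self, lines: np.ndarray, phi: np.ndarray, rank: int) -> np.ndarray:
        """Adjoint of :meth:`forward`; returns (n_pix, rank)."""
        m = self.matrix
        gadj = np.zeros((rank, m, m), dtype=complex)
        for row, idx in self._groups:
            gadj[:, row, :] += phi[:, self.cols[idx]].conj() @ lines[idx]
        return ifft2c(gadj).reshape(rank, m * m).T

    def normal(self, u: np.ndarray, phi: np.ndarray) -> np.ndarray:
        return self.adjoint(self.forward(u, phi), phi, u.shape[1])

    def lipschitz(self, phi: np.ndarray) -> float:
        """Upper bound on ||A||^2: largest eigenvalue of sum phi_i phi_i^H."""
        gram = phi[:, self.cols] @ phi[:, self.cols].conj().T
        return float(np.linalg.eigvalsh(gram)[-1])


def direct_solve(sampler: LineSampler, lines: np.ndarray, phi: np.ndarray,
                 rank: int, damp: float = 1e-9) -> np.ndarray:
    """Tikhonov-damped least-squares solution of d = Omega(E U Phi).

    Because E is a unitary DFT and every readout samples one full ky row, the
    normal equations decouple across ky rows of the spectrum G = F U: per row,
    G_k solves (sum_i phi_i phi_i^H + damp*s*I) G_k = sum_i phi_i d_i over the
    readouts i hitting that row, with ``s`` the mean per-row Gram trace (so
    ``damp`` is relative to the average sampling density).  Rows never sampled
    stay zero; weakly sampled rows are shrunk rather than inverted.  With
    damp -> 0 this is the exact minimum-norm LS solution.

    Phi rows are equilibrated to unit norm before solving (and the solution
    mapped back) so the ridge penalizes all temporal components uniformly
    instead of suppressing the weak, energy-ordered ones.
    """
    m = sampler.matrix
    row_scale = np.linalg.norm(phi, axis=1)
    row_scale = np.maximum(row_scale, 1e-12 * max(row_scale.max(), 1e-300))
    phi_eq = phi / row_scale[:, None]
    grams, rhss, traces = {}, {}, []
    for row, idx in sampler._groups:
        p = phi_eq[:, sampler.cols[idx]]         # (L, n_k)
        # forward applies phi^T, so the normal matrix is sum phi* phi^T
        grams[row] = p.conj() @ p.T
        rhss[row] = p.conj() @ lines[idx]        # (L, m)
        traces.append(np.trace(grams[row]).real)
    scale = max(float(np.mean(traces)) / rank, 1e-300)
    g = np.zeros((rank, m, m), dtype=complex)
    eye = np.eye(rank)
    for row, gram in grams.items():
        g[:, row, :] = np.linalg.solve(gram + damp * scale * eye, rhss[row])
    u = ifft2c(g).reshape(rank, m * m).T
    return u / row_scale[None, :]


def cg_solve(sampler: LineSampler, lines: np.ndarray, phi: np.ndarray,
             rank: int, tol: float = 1e-6, max_iter: int = 200) -> np.ndarray:
    """Conjugate gradient on the normal equations A^H A U = A^H d."""
    rhs = sampler.adjoint(lines, phi, rank)
    x = np.zeros_like(rhs)
    r = rhs.copy()
    p = r.copy()
    rs = np.vdot(r, r).real
    rs0 = rs
    if rs0 == 0:
        return x
    for _ in range(max_iter):
        ap = sampler.normal(p, phi)
        alpha = rs / np.vdot(p, ap).real
        x += alpha * p
        r -= alpha * ap
        rs_new = np.vdot(r, r).real
        if np.sqrt(rs_new / rs0) < tol:
            break
        p = r + (rs_new / rs) * p
        rs = rs_new
    return x
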