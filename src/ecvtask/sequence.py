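"""IR-prepared FLASH signal model, joint pre/post-contrast dictionary and SVD basis.

The sequence repeats an inversion pulse followed by ``N`` low-flip-angle
excitations, one readout per TR.  Readout ``n`` occurs at time ``(n-1)*TR``
after the inversion; between excitations the longitudinal magnetization
relaxes toward ``m0`` with ``E1 = exp(-TR/T1)`` and each excitation scales it
by ``cos(alpha)``.  This yields the geometric recursion

    M_n = M_ss* + (f(B) * m_init - M_ss*) * (E1 cos a)^n,
    M_ss* = m0 (1 - E1) / (1 - E1 cos a),

where ``M_n`` is the longitudinal magnetization before excitation ``n+1`` and
``f(B)`` is the multiplicative effect of the inversion pulse.  ``B`` ranges
from -1 (complete inversion, f = -1) to 0 (no inversion, f = +1); we use the
linear interpolation ``f(B) = 1 + 2B``.  The measured signal at readout ``n``
is ``sin(alpha) * M_{n-1}``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np


# --------------------------------------------------------------------------- #
# parameter containers
# --------------------------------------------------------------------------- #


@dataclass(frozen=True)
class SequenceParams:
    """Acquisition timing and geometry of the continuous IR-FLASH sequence."""

    tr: float = 7.0                 # ms
    te: float = 2.4                 # ms, informational only
    flip_nominal: float = 5.0       # deg
    recovery_period: float = 2912.0  # ms between inversion pulses (= N * TR)
    n_ir_pulses: int = 85
    readouts_per_period: int = 416
    matrix: int = 128
    fov: float = 40.0               # mm
    slice_thickness: float = 1.5    # mm

    def __post_init__(self) -> None:
        if self.tr <= 0:
            raise ValueError(f"tr must be positive, got {self.tr}")
        if self.n_ir_pulses < 1:
            raise ValueError("n_ir_pulses must be >= 1")
        if self.readouts_per_period * self.tr > self.recovery_period + self.tr:
            raise ValueError(
                "readouts_per_period * tr exceeds the recovery period: "
                f"{self.readouts_per_period} * {self.tr} > "
                f"{self.recovery_period} + {self.tr}"
            )
        if self.matrix <= 0 or self.fov <= 0:
            raise ValueError("matrix and fov must be positive")

    @property
    def n_readouts(self) -> int:
        """Total readouts in one scan (all IR blocks)."""
        return self.n_ir_pulses * self.readouts_per_period

    @property
    def voxel_size(self) -> float:
        """In-plane voxel size fov/matrix (mm)."""
        return self.fov / self.matrix


@dataclass(frozen=True)
class TissueParams:
    """Per-tissue relaxation/excitation parameters shared by both scans."""

    t1_pre: float           # ms
    t1_post: float          # ms
    m0: float = 1.0         # equilibrium longitudinal magnetization, a.u.
    alpha: float = 5.0      # actual flip angle, deg
    b: float = -1.0         # inversion efficiency in [-1, 0]

    def __post_init__(self) -> None:
        if self.t1_post <= 0 or self.t1_pre <= self.t1_post:
            raise ValueError(
                f"need t1_pre > t1_post > 0, got ({self.t1_pre}, {self.t1_post})"
            )
        if not -1.0 <= self.b <= 0.0:
            raise ValueError(f"inversion efficiency b must be in [-1, 0], got {self.b}")
        if self.m0 <= 0:
            raise ValueError("m0 must be positive")


@dataclass
class JointSignal:
    """Pre- and post-contrast signal curves of one tissue over one IR block each."""

    pre_curve: np.ndarray       # (N,)
    post_curve: np.ndarray      # (N,)
    t1_index: np.ndarray        # (N,) readout ordinal 1..N

    @property
    def concatenated(self) -> np.ndarray:
        return np.concatenate([self.pre_curve, self.post_curve])


def inversion_factor(b: float | np.ndarray) -> float | np.ndarray:
    """Multiplicative effect of the inversion pulse on longitudinal magnetization.

    b = -1 -> factor -1 (complete inversion); b = 0 -> factor +1 (no inversion).
    """
    return 1.0 + 2.0 * np.asarray(b, dtype=float) if np.ndim(b) else 1.0 + 2.0 * b


# --------------------------------------------------------------------------- #
# closed-form block simulation
# --------------------------------------------------------------------------- #


def _check_t1(t1) -> None:
    if np.any(np.asarray(t1) <= 0):
        raise ValueError("T1 must be positive")


def _block_coeffs(t1, alpha_deg, seq: SequenceParams, look_locker: bool = True):
    """Return (E1, cos_a, sin_a, r, mss_unit) for unit m0, broadcastable."""
    _check_t1(t1)
    t1 = np.asarray(t1, dtype=float)
    e1 = np.exp(-seq.tr / t1)
    if look_locker:
        a = np.deg2rad(np.asarray(alpha_deg, dtype=float))
        ca, sa = np.cos(a), np.sin(a)
    else:
        # alpha fixed to 0 in the recovery dynamics; readout amplitude is
        # absorbed into m0 (used for the inflowing-blood model).
        ca = np.ones_like(t1)
        sa = np.ones_like(t1)
    r = e1 * ca
    mss = (1.0 - e1) / (1.0 - r)
    return e1, ca, sa, r, mss


def simulate_ir_flash_block(
    tissue: TissueParams,
    seq: SequenceParams,
    m_init: float,
    *,
    look_locker: bool = True,
):
    """Simulate one IR block starting from longitudinal magnetization ``m_init``.

    Returns ``(trace, signal, m_end)`` where ``trace[n]`` is the longitudinal
    magnetization at readout ``n+1`` (time ``n*TR`` after inversion),
    ``signal = sin(alpha) * trace`` and ``m_end`` is the magnetization just
    before the next inversion pulse.
    """
    if not np.isfinite(m_init):
        raise ValueError("m_init must be finite")
    n = seq.readouts_per_period
    e1, ca, sa, r, mss_u = _block_coeffs(tissue.t1_pre, tissue.alpha, seq, look_locker)
    return _block_from_coeffs(tissue.t1_pre, tissue.m0, tissue.b, m_init,
                              seq, n, ca, sa, r, mss_u)


def _block_from_coeffs(t1, m0, b, m_init, seq, n, ca, sa, r, mss_u):
    mss = m0 * mss_u
    m_inv = inversion_factor(b) * m_init
    powers = r ** np.arange(n)
    trace = mss + (m_inv - mss) * powers
    signal = sa * trace
    t_tail = seq.recovery_period - (n - 1) * seq.tr
    e1t = np.exp(-t_tail / t1)
    m_end = m0 * (1.0 - e1t) + e1t * ca * trace[-1]
    return trace, signal, m_end


def periodic_steady_state(
    tissue: TissueParams,
    seq: SequenceParams,
    *,
    t1: float | None = None,
    look_locker: bool = True,
) -> float:
    """Longitudinal magnetization just before inversion in the periodic regime.

    One IR block maps m -> c0 + c1*m affinely; the fixed point is returned in
    closed form.  ``t1`` overrides ``tissue.t1_pre`` (used for the post scan).
    """
    t1 = tissue.t1_pre if t1 is None else t1
    n = seq.readouts_per_period
    e1, ca, sa, r, mss_u = _block_coeffs(t1, tissue.alpha, seq, look_locker)
    mss = tissue.m0 * mss_u
    t_tail = seq.recovery_period - (n - 1) * seq.tr
    e1t = np.exp(-t_tail / t1)
    c0 = tissue.m0 * (1.0 - e1t) + e1t * ca * mss * (1.0 - r ** (n - 1))
    c1 = e1t * ca * (r ** (n - 1)) * inversion_factor(tissue.b)
    return float(c0 / (1.0 - c1))


def simulate_joint_pair(
    tissue: TissueParams,
    seq: SequenceParams,
    *,
    look_locker: bool = True,
) -> JointSignal:
    """Jointly simulate one pre- and one post-contrast IR block.

    Both blocks share (m0, alpha, b) and each starts from its own periodic
    steady state.
    """
    n = seq.readouts_per_period
    curves = []
    for t1 in (tissue.t1_pre, tissue.t1_post):
        m_star = periodic_steady_state(tissue, seq, t1=t1, look_locker=look_locker)
        e1, ca, sa, r, mss_u = _block_coeffs(t1, tissue.alpha, seq, look_locker)
        _, sig, _ = _block_from_coeffs(t1, tissue.m0, tissue.b, m_star,
                                       seq, n, ca, sa, r, mss_u)
        curves.append(sig)
    return JointSignal(pre_curve=curves[0], post_curve=curves[1],
                       t1_index=np.arange(1, n + 1))


def scan_curve_batch(
    t1,
    alpha,
    b,
    seq: SequenceParams,
    *,
    m0=1.0,
    look_locker: bool = True,
) -> np.ndarray:
    """Vectorized single-scan periodic-steady-state curves, shape (n_combo, N)."""
    t1, alpha, b, m0 = np.broadcast_arrays(
        *(np.atleast_1d(np.asarray(x, dtype=float))
          for x in (t1, alpha, b, m0))
    )
    _check_t1(t1)
    n = seq.readouts_per_period
    f = inversion_factor(b)
    e1 = np.exp(-seq.tr / t1)
    if look_locker:
        a = np.deg2rad(alpha)
        ca, sa = np.cos(a), np.sin(a)
    else:
        ca = np.ones_like(t1)
        sa = np.ones_like(t1)
    r = e1 * ca
    mss = m0 * (1.0 - e1) / (1.0 - r)
    t_tail = seq.recovery_period - (n - 1) * seq.tr
    e1t = np.exp(-t_tail / t1)
    c0 = m0 * (1.0 - e1t) + e1t * ca * mss * (1.0 - r ** (n - 1))
    c1 = e1t * ca * (r ** (n - 1)) * f
    m_star = c0 / (1.0 - c1)
    powers = r[:, None] ** np.arange(n)[None, :]
    trace = mss[:, None] + (f * m_star - mss)[:, None] * powers
    return sa[:, None] * trace


def joint_curve_batch(
    t1_pre,
    t1_post,
    alpha,
    b,
    seq: SequenceParams,
    *,
    m0=1.0,
    look_locker: bool = True,
) -> np.ndarray:
    """Vectorized joint pre+post curves; returns shape (n_combo, 2N).

    All parameter arrays broadcast against each other.  Equivalent to calling
    :func:`simulate_joint_pair` per tuple but in closed form throughout.
    """
    pre = scan_curve_batch(t1_pre, alpha, b, seq, m0=m0, look_locker=look_locker)
    post = scan_curve_batch(t1_post, alpha, b, seq, m0=m0, look_locker=look_locker)
    return np.concatenate([pre, post], axis=1)


# --------------------------------------------------------------------------- #
# dictionary and SVD basis
# --------------------------------------------------------------------------- #


@dataclass(frozen=True)
class GridSpec:
    """Parameter grid generating the joint-curve dictionary (m0 fixed to 1)."""

    t1_values: np.ndarray
    flip_values: np.ndarray
    b_values: np.ndarray

    @classmethod
    def protocol(cls) -> "GridSpec":
        """101 T1 in [100, 3000] ms x 15 flips in [0.5, 7.5] deg x 21 B in [-1, 0]."""
        return cls(
            t1_values=np.linspace(100.0, 3000.0, 101),
            flip_values=np.linspace(0.5, 7.5, 15),
            b_values=np.linspace(-1.0, 0.0, 21),
        )

    @classmethod
    def reduced(cls, n_t1: int = 25, n_flip: int = 5, n_b: int = 5) -> "GridSpec":
        """Coarser grid with the same ranges, for desk-scale pipelines."""
        return cls(
            t1_values=np.linspace(100.0, 3000.0, n_t1),
            flip_values=np.linspace(0.5, 7.5, n_flip),
            b_values=np.linspace(-1.0, 0.0, n_b),
        )

    @property
    def n_atoms(self) -> int:
        nt = len(self.t1_values)
        return (nt * (nt - 1) // 2) * len(self.flip_values) * len(self.b_values)

    def tuples(self) -> np.ndarray:
        """All admissible (t1_pre, t1_post, alpha, b) tuples, shape (n_atoms, 4)."""
        t1 = np.sort(np.asarray(self.t1_values, dtype=float))
        pairs = np.array([(hi, lo) for lo, hi in combinations(t1, 2)])
        if pairs.size == 0:
            raise ValueError("grid admits no t1_pre > t1_post pair")
        fl, bv = np.meshgrid(self.flip_values, self.b_values, indexing="ij")
        fb = np.column_stack([fl.ravel(), bv.ravel()])
        out = np.empty((len(pairs) * len(fb), 4))
        out[:, :2] = np.repeat(pairs, len(fb), axis=0)
        out[:, 2:] = np.tile(fb, (len(pairs), 1))
        return out


@dataclass
class T1Dictionary:
    """Matrix of l2-normalized joint signal atoms plus their generating grid."""

    grid: np.ndarray          # (n_atoms, 4): t1_pre, t1_post, alpha, b
    atoms: np.ndarray         # (2N, n_atoms), columns unit-norm
    grid_spec: GridSpec


@dataclass
class T1Basis:
    """Orthonormal temporal basis for the concatenated pre+post recovery curves."""

    basis: np.ndarray             # (2N, rank)
    singular_values: np.ndarray   # full nonincreasing spectrum
    rank: int


_MAX_DICT_BYTES = 2 << 30  # refuse to materialize >2 GiB of atoms


def build_dictionary(grid_spec: GridSpec, seq: SequenceParams) -> T1Dictionary:
    """Simulate all admissible grid tuples into a normalized atom matrix."""
    tuples = grid_spec.tuples()
    nbytes = tuples.shape[0] * 2 * seq.readouts_per_period * 8
    if nbytes > _MAX_DICT_BYTES:
        raise MemoryError(
            f"dictionary would need {nbytes / 2**30:.1f} GiB; use "
            "compute_t1_basis_from_grid (streaming) or a reduced grid"
        )
    atoms = joint_curve_batch(tuples[:, 0], tuples[:, 1], tuples[:, 2],
                              tuples[:, 3], seq).T
    atoms = atoms / np.linalg.norm(atoms, axis=0, keepdims=True)
    return T1Dictionary(grid=tuples, atoms=atoms, grid_spec=grid_spec)


def _basis_from_gram(gram: np.ndarray, rank: int | None, energy: float) -> T1Basis:
    evals, evecs = np.linalg.eigh(gram)
    evals = np.maximum(evals[::-1], 0.0)
    evecs = evecs[:, ::-1]
    svals = np.sqrt(evals)
    if rank is None:
        frac = np.cumsum(evals) / np.sum(evals)
        rank = int(np.searchsorted(frac, energy) + 1)
    if rank > gram.shape[0]:
        raise ValueError(f"rank {rank} exceeds curve length {gram.shape[0]}")
    return T1Basis(basis=evecs[:, :rank], singular_values=svals, rank=rank)


def compute_t1_basis(
    dictionary: T1Dictionary,
    rank: int | None = None,
    *,
    energy: float = 0.999,
) -> T1Basis:
    """Top left-singular vectors of the atom matrix (via its 2N x 2N Gram).

    With ``rank=None`` the smallest rank capturing ``energy`` of the spectral
    energy is used.
    """
    if rank is not None and rank > min(dictionary.atoms.shape):
        raise ValueError("rank exceeds dictionary dimensions")
    gram = dictionary.atoms @ dictionary.atoms.T
    return _basis_from_gram(gram, rank, energy)


def compute_t1_basis_from_grid(
    grid_spec: GridSpec,
    seq: SequenceParams,
    rank: int | None = None,
    *,
    energy: float = 0.999,
    chunk: int = 20000,
) -> T1Basis:
    """Streaming Gram-accumulation SVD for grids too large to materialize."""
    tuples = grid_spec.tuples()
    two_n = 2 * seq.readouts_per_period
    gram = np.zeros((two_n, two_n))
    for start in range(0, len(tuples), chunk):
        t = tuples[start:start + chunk]
        a = joint_curve_batch(t[:, 0], t[:, 1], t[:, 2], t[:, 3], seq).T
        a /= np.linalg.norm(a, axis=0, keepdims=True)
        gram += a @ a.T
    return _basis_from_gram(gram, rank, energy)
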