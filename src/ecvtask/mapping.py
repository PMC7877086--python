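"""Pixel-wise joint T1 fitting, blood-pool fitting, ECV computation, statistics.

The joint model fits one concatenated pre+post curve (2N samples) with exactly
five free parameters -- T1_pre, T1_post and the shared M0, flip angle alpha
and inversion efficiency B -- versus eight if the two scans were fitted
independently.  Blood T1 is fitted on an M0-weighted average curve with alpha
fixed to 0 (no Look-Locker correction), modeling inflow of unexcited spins.
ECV = (1 - HCT) * dR1_myo / dR1_blood * 100 with dR1 = 1/T1_post - 1/T1_pre.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, stats
from scipy.optimize import least_squares

from .sequence import (GridSpec, SequenceParams, T1Dictionary,
                       build_dictionary, joint_curve_batch, scan_curve_batch)

JOINT_PARAM_NAMES = ("t1_pre", "t1_post", "m0", "alpha", "b")
SINGLE_PARAM_NAMES = ("t1", "m0", "alpha", "b")

N_JOINT_PARAMS = len(JOINT_PARAM_NAMES)                  # 5
N_INDEPENDENT_PARAMS = 2 * len(SINGLE_PARAM_NAMES)       # 8

_T1_BOUNDS = (50.0, 5000.0)
_ALPHA_BOUNDS = (0.1, 15.0)
_B_BOUNDS = (-1.0, 0.0)


@dataclass
class ParameterMaps:
    t1_pre: np.ndarray
    t1_post: np.ndarray
    m0: np.ndarray
    alpha: np.ndarray
    b: np.ndarray
    fit_residual: np.ndarray
    fitted_mask: np.ndarray
    blood_t1_pre: float = np.nan
    blood_t1_post: float = np.nan


@dataclass
class ECVResult:
    ecv_map: np.ndarray          # percent
    hct: float
    delta_r1_myo: np.ndarray     # 1/s map
    delta_r1_blood: float        # 1/s
    septal_mask: np.ndarray
    septal_delta_r1: float
    septal_ecv: float            # percent, from mean septal dR1
    septal_sd: float             # percent, pixel-wise SD within the mask
    qc_out_of_range: np.ndarray = field(default=None)


# --------------------------------------------------------------------------- #
# curve preparation and fitting
# --------------------------------------------------------------------------- #


def phase_correct(curves: np.ndarray) -> np.ndarray:
    """Rotate complex curves to real, preserving the recovery's sign pattern.

    The global phase is taken from the late, fully recovered part of the
    pre-contrast block where the signal is reliably positive.
    """
    curves = np.atleast_2d(curves)
    n = curves.shape[1] // 2
    ref = curves[:, max(0, n - n // 4):n].sum(axis=1)
    phase = np.exp(-1j * np.angle(ref))
    out = (curves * phase[:, None]).real
    return out


def fit_joint_t1_pixel(curve: np.ndarray, seq: SequenceParams,
                       dictionary: T1Dictionary) -> tuple:
    """Two-stage joint 5-parameter fit of one 2N-sample curve.

    Dictionary best-match (maximum normalized correlation) initializes a
    bounded trust-region least-squares refinement.  Returns
    (t1_pre, t1_post, m0, alpha, b, residual); residual is inf on failure.
    """
    curve = np.asarray(curve, dtype=float)
    if not np.all(np.isfinite(curve)):
        raise ValueError("curve contains non-finite samples")
    nrm = np.linalg.norm(curve)
    if nrm == 0:
        return (np.nan,) * 5 + (np.inf,)
    scores = dictionary.atoms.T @ (curve / nrm)
    best = int(np.argmax(scores))
    t1p0, t1s0, a0, b0 = dictionary.grid[best]
    raw = joint_curve_batch(t1p0, t1s0, a0, b0, seq)[0]
    m00 = max(float(curve @ raw / (raw @ raw)), 1e-6)
    x0 = np.array([t1p0, t1s0, m00, a0, min(max(b0, -0.999), -0.001)])

    def resid(x):
        return joint_curve_batch(x[0], x[1], x[3], x[4], seq, m0=x[2])[0] - curve

    lo = [_T1_BOUNDS[0], _T1_BOUNDS[0], 1e-9, _ALPHA_BOUNDS[0], _B_BOUNDS[0]]
    hi = [_T1_BOUNDS[1], _T1_BOUNDS[1], np.inf, _ALPHA_BOUNDS[1], _B_BOUNDS[1]]
    try:
        sol = least_squares(resid, x0, bounds=(lo, hi),
                            x_scale=[1000.0, 1000.0, max(m00, 1e-3), 1.0, 0.1],
                            xtol=1e-10, ftol=1e-10)
    except Exception:
        return (np.nan,) * 5 + (np.inf,)
    if not sol.success:
        return tuple(sol.x) + (np.inf,)
    return tuple(sol.x) + (float(np.linalg.norm(sol.fun)),)


def fit_independent_t1(curve: np.ndarray, seq: SequenceParams,
                       dictionary: T1Dictionary) -> tuple:
    """Two independent 4-parameter single-scan fits (8 free parameters total).

    Returns (t1_pre, t1_post) from fitting each half of the curve separately
    with its own (m0, alpha, b).
    """
    n = seq.readouts_per_period
    scores = dictionary.atoms.T @ (curve / max(np.linalg.norm(curve), 1e-300))
    t1p0, t1s0, a0, b0 = dictionary.grid[int(np.argmax(scores))]
    out = []
    for half, t10 in ((curve[:n], t1p0), (curve[n:], t1s0)):
        def resid(x):
            return scan_curve_batch(x[0], x[2], x[3], seq, m0=x[1])[0] - half
        raw = scan_curve_batch(t10, a0, b0, seq)[0]
        m00 = max(float(half @ raw / (raw @ raw)), 1e-6)
        x0 = [t10, m00, a0, min(max(b0, -0.999), -0.001)]
        lo = [_T1_BOUNDS[0], 1e-9, _ALPHA_BOUNDS[0], _B_BOUNDS[0]]
        hi = [_T1_BOUNDS[1], np.inf, _ALPHA_BOUNDS[1], _B_BOUNDS[1]]
        sol = least_squares(resid, x0, bounds=(lo, hi),
                            x_scale=[1000.0, max(m00, 1e-3), 1.0, 0.1],
                            xtol=1e-10, ftol=1e-10)
        out.append(float(sol.x[0]))
    return tuple(out)


def fit_t1_maps(curves: np.ndarray, mask: np.ndarray, seq: SequenceParams,
                dictionary: T1Dictionary, shape: tuple) -> ParameterMaps:
    """Fit every masked pixel of a (n_pixels, 2N) curve stack."""
    maps = {k: np.full(shape, np.nan) for k in JOINT_PARAM_NAMES}
    residual = np.full(shape, np.nan)
    flat = {k: v.reshape(-1) for k, v in maps.items()}
    res_flat = residual.reshape(-1)
    for p in np.flatnonzero(mask.reshape(-1)):
        vals = fit_joint_t1_pixel(curves[p], seq, dictionary)
        for k, v in zip(JOINT_PARAM_NAMES, vals[:5]):
            flat[k][p] = v
        res_flat[p] = vals[5]
    return ParameterMaps(
        t1_pre=maps["t1_pre"], t1_post=maps["t1_post"], m0=maps["m0"],
        alpha=maps["alpha"], b=maps["b"], fit_residual=residual,
        fitted_mask=np.asarray(mask, dtype=bool).reshape(shape),
    )


# --------------------------------------------------------------------------- #
# blood pool
# --------------------------------------------------------------------------- #


def select_blood_pixels(m0_map: np.ndarray, *, central_frac: float = 0.8,
                        threshold: float | None = None) -> np.ndarray:
    """Blood mask by Otsu thresholding of the fitted M0 map.

    Thresholds M0 within a central region, then keeps the connected component
    with the highest mean M0 (the aorta/blood pool).  Deterministic.
    """
    from skimage.filters import threshold_otsu

    m = m0_map.shape[0]
    lo = int(m * (1 - central_frac) / 2)
    region = np.zeros_like(m0_map, dtype=bool)
    region[lo:m - lo, lo:m - lo] = True
    vals = np.nan_to_num(m0_map, nan=0.0)
    cand = vals[region & np.isfinite(m0_map)]
    if cand.size == 0 or np.ptp(cand) < 1e-12 * max(np.max(np.abs(cand)), 1e-300):
        raise ValueError(
            "uniform M0 map: cannot threshold blood pixels; supply an "
            "explicit threshold or a manual mask"
        )
    thr = threshold_otsu(cand) if threshold is None else threshold
    mask = region & (vals >= thr)
    if not np.any(mask):
        raise ValueError(
            f"no pixels above threshold {thr:.4g}; lower the threshold")
    lab, n_comp = ndimage.label(mask)
    means = ndimage.mean(vals, lab, index=np.arange(1, n_comp + 1))
    return lab == (int(np.argmax(means)) + 1)


def fit_blood_t1(curves: np.ndarray, weights: np.ndarray,
                 seq: SequenceParams) -> tuple:
    """(blood_t1_pre, blood_t1_post) from the M0-weighted average curve.

    The average curve is fitted with alpha fixed at 0 (pure IR recovery, no
    Look-Locker correction); free parameters: t1_pre, t1_post, m0, b.
    """
    weights = np.asarray(weights, dtype=float)
    if curves.shape[0] == 0:
        raise ValueError("empty blood mask")
    if np.all(weights == 0):
        raise ValueError("all-zero M0 weights")
    avg = (weights[:, None] * curves).sum(axis=0) / weights.sum()

    grid = GridSpec(t1_values=np.linspace(200, 3000, 29),
                    flip_values=np.array([1.0]), b_values=np.linspace(-1, 0, 5))
    d0 = build_dictionary_alpha0(grid, seq)
    scores = d0.atoms.T @ (avg / max(np.linalg.norm(avg), 1e-300))
    t1p0, t1s0, _, b0 = d0.grid[int(np.argmax(scores))]
    raw = joint_curve_batch(t1p0, t1s0, 0.0, b0, seq, look_locker=False)[0]
    m00 = max(float(avg @ raw / (raw @ raw)), 1e-6)

    def resid(x):
        return joint_curve_batch(x[0], x[1], 0.0, x[3], seq, m0=x[2],
                                 look_locker=False)[0] - avg

    sol = least_squares(
        resid, [t1p0, t1s0, m00, min(max(b0, -0.999), -0.001)],
        bounds=([50.0, 50.0, 1e-9, -1.0], [5000.0, 5000.0, np.inf, 0.0]),
        x_scale=[1000.0, 1000.0, max(m00, 1e-3), 0.1],
        xtol=1e-10, ftol=1e-10)
    return float(sol.x[0]), float(sol.x[1])


def build_dictionary_alpha0(grid: GridSpec, seq: SequenceParams) -> T1Dictionary:
    """Pure-IR (alpha = 0) dictionary used to initialize the blood fit."""
    t = grid.tuples()
    atoms = joint_curve_batch(t[:, 0], t[:, 1], 0.0, t[:, 3], seq,
                              look_locker=False).T
    atoms = atoms / np.linalg.norm(atoms, axis=0, keepdims=True)
    return T1Dictionary(grid=t, atoms=atoms, grid_spec=grid)


def apparent_t1(t1: float, alpha_deg: float, tr: float) -> float:
    """Look-Locker apparent T1* = -TR / ln(E1 cos a) < T1 for a > 0."""
    e1 = np.exp(-tr / t1)
    return float(-tr / np.log(e1 * np.cos(np.deg2rad(alpha_deg))))


# --------------------------------------------------------------------------- #
# ECV
# --------------------------------------------------------------------------- #


def r1_from_t1_ms(t1_ms):
    """R1 in 1/s from T1 in ms."""
    return 1000.0 / np.asarray(t1_ms, dtype=float)


def ecv_from_r1(dr1_myo, dr1_blood: float, hct: float):
    return (1.0 - hct) * np.asarray(dr1_myo) / dr1_blood * 100.0


def compute_ecv(t1_pre_map, t1_post_map, blood_t1_pre: float,
                blood_t1_post: float, hct: float,
                septal_mask: np.ndarray,
                r1_calibration: tuple | None = None) -> ECVResult:
    """Pixel-wise ECV map and septal statistics.

    The septal ECV uses the mean delta-R1 within the septal mask (not the mean
    of pixel-wise ECV values).  ``r1_calibration=(slope, intercept)`` applies
    an affine map to all four R1 quantities before differencing; ECV is
    invariant to it.
    """
    if not 0.0 < hct < 1.0:
        raise ValueError(f"hct must be in (0, 1), got {hct}")
    r1_pre = r1_from_t1_ms(t1_pre_map)
    r1_post = r1_from_t1_ms(t1_post_map)
    rb_pre = float(r1_from_t1_ms(blood_t1_pre))
    rb_post = float(r1_from_t1_ms(blood_t1_post))
    if r1_calibration is not None:
        slope, intercept = r1_calibration
        r1_pre, r1_post, rb_pre, rb_post = (
            apply_linear_calibration(v, slope, intercept)
            for v in (r1_pre, r1_post, rb_pre, rb_post))
    dr1_myo = r1_post - r1_pre
    dr1_blood = rb_post - rb_pre
    if dr1_blood <= 0:
        raise ValueError(
            f"blood delta-R1 = {dr1_blood:.4g} <= 0: contrast did not "
            "shorten blood T1")
    ecv_map = ecv_from_r1(dr1_myo, dr1_blood, hct)
    sept = np.asarray(septal_mask, dtype=bool) & np.isfinite(ecv_map)
    septal_dr1 = float(np.mean(dr1_myo[sept])) if np.any(sept) else np.nan
    septal_ecv = float(ecv_from_r1(septal_dr1, dr1_blood, hct))
    septal_sd = float(np.std(ecv_map[sept], ddof=1)) if np.sum(sept) > 1 else np.nan
    qc = np.isfinite(ecv_map) & ((ecv_map < 0) | (ecv_map > 100))
    return ECVResult(
        ecv_map=ecv_map, hct=hct, delta_r1_myo=dr1_myo,
        delta_r1_blood=dr1_blood, septal_mask=sept,
        septal_delta_r1=septal_dr1, septal_ecv=septal_ecv,
        septal_sd=septal_sd, qc_out_of_range=qc)


def apply_linear_calibration(r1, slope: float, intercept: float):
    """Affine R1 calibration R1~ = slope * R1 + intercept."""
    if slope == 0:
        raise ValueError("calibration slope must be nonzero")
    return slope * np.asarray(r1, dtype=float) + intercept


def verify_ecv_invariance(t1_pre_map, t1_post_map, blood_t1_pre, blood_t1_post,
                          hct, septal_mask, slope: float,
                          intercept: float) -> float:
    """Max |ECV(calibrated R1) - ECV(raw R1)| over the map (should be ~0)."""
    base = compute_ecv(t1_pre_map, t1_post_map, blood_t1_pre, blood_t1_post,
                       hct, septal_mask)
    cal = compute_ecv(t1_pre_map, t1_post_map, blood_t1_pre, blood_t1_post,
                      hct, septal_mask, r1_calibration=(slope, intercept))
    diff = np.abs(cal.ecv_map - base.ecv_map)
    return float(np.nanmax(np.append(diff[np.isfinite(diff)],
                                     abs(cal.septal_ecv - base.septal_ecv))))


# --------------------------------------------------------------------------- #
# reporting statistics
# --------------------------------------------------------------------------- #


def icc_2_1(x: np.ndarray, y: np.ndarray) -> float:
    """ICC(2,1): two-way random effects, absolute agreement, single rater."""
    data = np.column_stack([x, y]).astype(float)
    n, k = data.shape
    grand = data.mean()
    ms_r = k * np.sum((data.mean(axis=1) - grand) ** 2) / (n - 1)
    ms_c = n * np.sum((data.mean(axis=0) - grand) ** 2) / (k - 1)
    ss_e = (np.sum((data - grand) ** 2)
            - np.sum((data.mean(axis=1) - grand) ** 2) * k
            - np.sum((data.mean(axis=0) - grand) ** 2) * n)
    ms_e = ss_e / ((n - 1) * (k - 1))
    return float((ms_r - ms_e)
                 / (ms_r + (k - 1) * ms_e + k * (ms_c - ms_e) / n))


def report_stats(group_a, group_b, paired_x=None, paired_y=None) -> dict:
    """Welch t-test between groups; Pearson / Bland-Altman / ICC / CoV on pairs."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need n >= 2 per group")
    out = {}
    if np.var(a) == 0 and np.var(b) == 0 and np.mean(a) == np.mean(b):
        out["welch"] = {"t": 0.0, "df": float(len(a) + len(b) - 2), "p": 1.0,
                        "zero_variance": True}
    else:
        res = stats.ttest_ind(a, b, equal_var=False)
        out["welch"] = {"t": float(res.statistic), "df": float(res.df),
                        "p": float(res.pvalue), "zero_variance": False}
    if paired_x is not None and paired_y is not None:
        x = np.asarray(paired_x, dtype=float)
        y = np.asarray(paired_y, dtype=float)
        pr = stats.pearsonr(x, y)
        diff = x - y
        bias = float(diff.mean())
        sd = float(diff.std(ddof=1))
        wsd = float(np.sqrt(np.mean(diff ** 2) / 2.0))
        out["pearson"] = {"r": float(pr.statistic), "p": float(pr.pvalue)}
        out["bland_altman"] = {"bias": bias,
                               "loa_low": bias - 1.96 * sd,
                               "loa_high": bias + 1.96 * sd}
        out["icc_2_1"] = icc_2_1(x, y)
        out["within_subject_cov_percent"] = 100.0 * wsd / float(
            np.mean(np.concatenate([x, y])))
    return out
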