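"""Ungated low-rank real-time reconstruction and k-means motion binning.

The k-space center (training) lines from both scans are concatenated and
SVD-ed into a real-time temporal basis; the imaging lines then determine the
real-time spatial basis by least squares.

Motion binning is a modified k-means on temporal features built from the
training-line projection profiles.  The modification addresses the contrast
change from T1 recovery: at a fixed readout index tau the contrast state is
identical in every IR block, so subtracting a per-(scan, tau) reference
profile -- regularized along tau with the low-rank magnitude-T1-recovery
model -- cancels the recovery contrast and leaves motion-induced deviations.
The deviations are band-split around the physiological rate bands
(respiration ~1 Hz, cardiac >= 3 Hz), reduced by PCA, and turned into a
respiratory displacement level and a cardiac phase.  Both rhythms are
quasi-periodic under anesthesia, so each is regularized by a narrowband
constant-rate phase model.  k-means then clusters the respiratory level into
K_resp bins and the cardiac phase into K_card bins; pre and post scans are
binned jointly so equal motion states share bins.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment
from scipy.signal import butter, hilbert, sosfiltfilt, welch
from sklearn.cluster import KMeans

from .encoding import LineSampler, cg_solve, direct_solve
from .phantom import KSpaceDataset
from .sequence import T1Basis


@dataclass
class RealTimeFactors:
    spatial: np.ndarray    # (n_pixels, L_rt)
    temporal: np.ndarray   # (L_rt, n_training_times), orthonormal rows
    rank: int


@dataclass
class BinAssignment:
    """Per-readout (cardiac, respiratory, T1) indices for both scans."""

    readout_id: np.ndarray
    scan: np.ndarray
    cardiac_bin: np.ndarray       # 1..n_cardiac
    resp_bin: np.ndarray          # 1..n_resp
    t1_index: np.ndarray          # 1..N
    n_cardiac: int
    n_resp: int
    end_expiration_bin: int = 1
    end_diastole_bin: int = 1
    extras: dict = field(default_factory=dict)


def estimate_realtime_basis(training_lines: np.ndarray, rank: int) -> np.ndarray:
    """Top right-singular vectors of the [matrix x n_times] training matrix.

    ``training_lines`` is (n_times, matrix) as stored; returns Phi_rt with
    shape (rank, n_times) and orthonormal rows.
    """
    d = np.asarray(training_lines).T  # (matrix, n_times)
    if rank > min(d.shape):
        raise ValueError(f"rank {rank} exceeds data dimensions {d.shape}")
    gram = d @ d.conj().T
    evals, evecs = np.linalg.eigh(gram)
    evals, evecs = evals[::-1], evecs[:, ::-1]
    u = evecs[:, :rank]
    s = np.sqrt(np.maximum(evals[:rank], 1e-300))
    phi = (u.conj().T @ d) / s[:, None]
    return phi


def _training_partner_cols(dataset: KSpaceDataset):
    """Map every readout to the index of its paired training line (same TR pair)."""
    tr_idx = np.flatnonzero(dataset.is_training)
    n_tr = len(tr_idx)
    ordinal_of_training = np.full(dataset.n_readouts, -1, dtype=int)
    ordinal_of_training[tr_idx] = np.arange(n_tr)
    cols = np.empty(dataset.n_readouts, dtype=int)
    cols[tr_idx] = ordinal_of_training[tr_idx]
    im_idx = np.flatnonzero(~dataset.is_training)
    # imaging readout immediately precedes its training partner
    partner = np.minimum(im_idx + 1, dataset.n_readouts - 1)
    bad = ordinal_of_training[partner] < 0
    partner[bad] = im_idx[bad] - 1
    cols[im_idx] = ordinal_of_training[partner]
    return cols, tr_idx


def solve_realtime_spatial(dataset: KSpaceDataset, phi_rt: np.ndarray,
                           method: str = "direct", tol: float = 1e-6,
                           max_iter: int = 150) -> np.ndarray:
    """Least-squares spatial basis U_x,rt from the imaging lines.

    ``method='direct'`` exploits the per-ky-row decoupling of the normal
    equations (exact minimizer); ``method='cg'`` iterates conjugate gradients
    on the normal equations to the same minimizer.
    """
    im = ~dataset.is_training
    if not np.any(im):
        raise ValueError("no imaging readouts in dataset")
    cols, _ = _training_partner_cols(dataset)
    sampler = LineSampler(dataset.ky_index[im], cols[im], dataset.seq.matrix)
    if method == "direct":
        return direct_solve(sampler, dataset.lines[im], phi_rt,
                            phi_rt.shape[0])
    return cg_solve(sampler, dataset.lines[im], phi_rt, phi_rt.shape[0],
                    tol=tol, max_iter=max_iter)


def assign_t1_index(timestamps: np.ndarray, ir_pulse_times: np.ndarray,
                    tr: float) -> np.ndarray:
    """Readout ordinal (1-based) since the most recent inversion pulse."""
    timestamps = np.asarray(timestamps, dtype=float)
    pulses = np.sort(np.asarray(ir_pulse_times, dtype=float))
    pos = np.searchsorted(pulses, timestamps + 1e-9) - 1
    if np.any(pos < 0):
        raise ValueError("readout precedes the first inversion pulse")
    since = timestamps - pulses[pos]
    return np.rint(since / tr).astype(int) + 1


# --------------------------------------------------------------------------- #
# motion feature extraction
# --------------------------------------------------------------------------- #


def _band_filter(x: np.ndarray, fs: float, band: tuple) -> np.ndarray:
    lo, hi = band
    nyq = fs / 2.0
    if lo is None:
        sos = butter(4, min(hi, 0.95 * nyq) / nyq, btype="low", output="sos")
    else:
        sos = butter(4, [lo / nyq, min(hi, 0.95 * nyq) / nyq],
                     btype="band", output="sos")
    if np.iscomplexobj(x):
        return sosfiltfilt(sos, x.real, axis=-1) + 1j * sosfiltfilt(sos, x.imag, axis=-1)
    return sosfiltfilt(sos, x, axis=-1)


def _pcs(x: np.ndarray, k: int) -> np.ndarray:
    """Top-k principal-component scores of an (n_features, n_t) block."""
    xr = np.vstack([x.real, x.imag]) if np.iscomplexobj(x) else x
    xr = xr - xr.mean(axis=1, keepdims=True)
    _, s, vt = np.linalg.svd(xr, full_matrices=False)
    return vt[:k] * s[:k, None]


def _pc1(x: np.ndarray) -> np.ndarray:
    return _pcs(x, 1)[0]


def _dominant_freq(sig: np.ndarray, fs: float, frange: tuple) -> float:
    f, psd = welch(sig, fs=fs, nperseg=min(2048, len(sig)))
    sel = (f >= frange[0]) & (f <= frange[1])
    return float(f[sel][np.argmax(psd[sel])])


def _regularized_phase(sig: np.ndarray, fs: float, frange: tuple,
                       dev_cut: float) -> np.ndarray:
    """Instantaneous phase under a quasi-constant-rate model.

    Hilbert phase is demodulated at the best-fitting constant rate in
    ``frange``; the slowly varying deviation is lowpass-smoothed in the
    complex domain (robust to unwrap errors) and re-added.
    """
    t = np.arange(len(sig)) / fs
    z = np.exp(1j * np.angle(hilbert(sig)))
    freqs = np.linspace(frange[0], frange[1], 241)
    amp = np.abs((z * np.exp(-2j * np.pi * np.outer(freqs, t))).mean(axis=1))
    f0 = freqs[np.argmax(amp)]
    resid = z * np.exp(-2j * np.pi * f0 * t)
    resid_s = _band_filter(resid[None, :], fs, (None, dev_cut))[0]
    return 2.0 * np.pi * f0 * t + np.angle(resid_s)


def _contrast_free_profiles(dataset: KSpaceDataset, tr_idx: np.ndarray,
                            mag_t1_basis: np.ndarray | None):
    """Training-line profile deviations with the T1-recovery contrast removed.

    Profiles are magnitudes of the 1D inverse DFT of each center line,
    normalized per time point; subtracting the per-(scan, tau) ensemble mean
    (contrast is identical across IR blocks at fixed tau) cancels the
    recovery contrast exactly.  Returns ``(feats, feats_detrended)``: the
    second version additionally projects each IR block onto the orthogonal
    complement of the magnitude T1-recovery basis, which suppresses the
    block-periodic residual of the ensemble reference (needed for the slow
    respiratory band; the cardiac band is unaffected by it).
    """
    n = dataset.seq.readouts_per_period
    m = dataset.seq.matrix
    proj = np.fft.ifft(np.fft.ifftshift(dataset.lines[tr_idx], axes=-1),
                       axis=-1, norm="ortho")
    p = np.abs(proj)
    p = p / np.maximum(p.sum(axis=1, keepdims=True), 1e-300)
    scan_tr = dataset.scan[tr_idx]
    tau_tr = dataset.t1_index[tr_idx]
    block_tr = dataset.ir_block_index[tr_idx]
    feats = np.zeros((m, len(tr_idx)))
    for s in (0, 1):
        sel = np.flatnonzero(scan_tr == s)
        if len(sel) == 0:
            continue
        taus = tau_tr[sel] - 1
        mean = np.zeros((n, m))
        cnt = np.bincount(taus, minlength=n)
        np.add.at(mean, taus, p[sel])
        mean /= np.maximum(cnt, 1)[:, None]
        feats[:, sel] = (p[sel] - mean[taus]).T
    detrended = feats.copy()
    if mag_t1_basis is not None:
        for s in (0, 1):
            sel = np.flatnonzero(scan_tr == s)
            for blk in np.unique(block_tr[sel]):
                c = sel[block_tr[sel] == blk]
                rows = tau_tr[c] - 1 + s * n
                if len(rows) <= mag_t1_basis.shape[1] + 1:
                    continue
                b = np.column_stack([mag_t1_basis[rows, :], np.ones(len(rows))])
                q, _ = np.linalg.qr(b)
                seg = detrended[:, c]
                detrended[:, c] = seg - (seg @ q) @ q.T
    return feats, detrended


def magnitude_t1_basis(atoms: np.ndarray, rank: int = 12) -> np.ndarray:
    """SVD basis of the dictionary atom magnitudes (for contrast references)."""
    a = np.abs(atoms)
    evals, evecs = np.linalg.eigh(a @ a.T)
    return evecs[:, ::-1][:, :rank]


# --------------------------------------------------------------------------- #
# modified k-means binning
# --------------------------------------------------------------------------- #

RESP_BAND = (0.45, 2.6)     # Hz; rodent respiration ~1 Hz
RESP_RATE_RANGE = (0.5, 2.2)
CARD_RATE_RANGE = (3.2, 9.0)  # 190-540 bpm


def bin_motion(dataset: KSpaceDataset, u_t1: T1Basis,
               n_resp: int = 5, n_cardiac: int = 10, *,
               seed: int = 0,
               mag_t1_basis: np.ndarray | None = None,
               phi_rt: np.ndarray | None = None,
               u_x_rt: np.ndarray | None = None,
               resp_phase_regularize: bool = True) -> BinAssignment:
    """Assign every readout of both scans a (cardiac, respiratory, T1) triple.

    ``mag_t1_basis`` (from :func:`magnitude_t1_basis`) improves the contrast
    reference; ``phi_rt``/``u_x_rt`` are only used to pick the end-diastole
    bin from bin-averaged real-time frames.  ``resp_phase_regularize``
    exploits quasi-periodic breathing to denoise the respiratory level
    (disable for irregular breathing patterns).
    """
    cols, tr_idx = _training_partner_cols(dataset)
    if mag_t1_basis is None:
        # fall back to the magnitudes of the signed basis columns
        mag_t1_basis = magnitude_t1_basis(u_t1.basis, rank=u_t1.rank)
    feats, feats_dt = _contrast_free_profiles(dataset, tr_idx, mag_t1_basis)
    fs = 1000.0 / (2.0 * dataset.seq.tr)  # training lines every 2 TR
    scan_tr = dataset.scan[tr_idx]

    resp_level = np.zeros(len(tr_idx))
    card_phase = np.zeros(len(tr_idx))
    for s in (0, 1):
        seg = np.flatnonzero(scan_tr == s)
        if len(seg) == 0:
            continue
        low = _band_filter(feats_dt[:, seg], fs, RESP_BAND)
        p1 = _pc1(low)
        # profiles are normalized to unit sum (mean level 1/matrix); motion
        # must move them by more than numerical noise
        if n_resp > 1 and p1.std() < 1e-8 / dataset.seq.matrix:
            raise ValueError(
                "no distinguishable respiratory motion states in the data; "
                "reduce K_resp")
        if resp_phase_regularize and len(seg) > 512:
            f_resp = _dominant_freq(p1, fs, RESP_RATE_RANGE)
            theta = _regularized_phase(p1, fs, (f_resp - 0.3, f_resp + 0.3),
                                       dev_cut=0.25)
            p1 = _phase_conditional_mean(p1, theta)
        # scan-independent convention: the end-expiration dwell is the most
        # populated level -> long tail points toward positive values
        m3 = np.mean((p1 - p1.mean()) ** 3)
        if m3 < 0:
            p1 = -p1
        std = p1.std()
        resp_level[seg] = (p1 - p1.mean()) / (std if std > 0 else 1.0)

        f_card = _dominant_freq(_pc1(_band_filter(feats[:, seg], fs,
                                                  (3.0, 12.0))),
                                fs, CARD_RATE_RANGE)
        cb = _band_filter(feats[:, seg], fs, (f_card - 0.6, f_card + 0.6))
        card_phase[seg] = np.angle(np.exp(1j * _regularized_phase(
            _pc1(cb), fs, (f_card - 0.6, f_card + 0.6), dev_cut=0.4)))

    resp_bin_tr = _cluster_resp(resp_level, n_resp, seed)
    card_bin_tr = _cluster_cardiac(card_phase, n_cardiac, seed)

    end_diastole = _detect_end_diastole(dataset, phi_rt, u_x_rt, card_bin_tr,
                                        n_cardiac)
    return BinAssignment(
        readout_id=np.arange(dataset.n_readouts),
        scan=dataset.scan.copy(),
        cardiac_bin=card_bin_tr[cols],
        resp_bin=resp_bin_tr[cols],
        t1_index=dataset.t1_index.copy(),
        n_cardiac=n_cardiac,
        n_resp=n_resp,
        end_expiration_bin=1,
        end_diastole_bin=end_diastole,
    )


def _phase_conditional_mean(level: np.ndarray, theta: np.ndarray,
                            n_bins: int = 36) -> np.ndarray:
    """Replace a noisy periodic level signal by its phase-conditional mean."""
    wrapped = np.angle(np.exp(1j * theta))
    idx = ((wrapped + np.pi) / (2.0 * np.pi) * n_bins).astype(int) % n_bins
    sums = np.bincount(idx, weights=level, minlength=n_bins)
    cnts = np.bincount(idx, minlength=n_bins)
    means = np.where(cnts > 0, sums / np.maximum(cnts, 1),
                     level.mean())
    return means[idx]


def _check_distinct(values: np.ndarray, k: int) -> None:
    if len(np.unique(np.round(values, 12))) < k:
        raise ValueError(
            f"fewer than {k} distinct motion states in the data; "
            "reduce the number of bins")


def _cluster_resp(level: np.ndarray, n_resp: int, seed: int) -> np.ndarray:
    if n_resp == 1:
        return np.ones(len(level), dtype=int)
    _check_distinct(level, n_resp)
    km = KMeans(n_clusters=n_resp, n_init=10, random_state=seed).fit(
        level.reshape(-1, 1))
    centers = km.cluster_centers_.ravel()
    counts = np.bincount(km.labels_, minlength=n_resp)
    if np.any(counts == 0):
        raise ValueError("empty respiratory cluster; reduce K_resp")
    # end-expiration = largest dwell cluster first, then by level distance
    dwell = int(np.argmax(counts))
    order = np.argsort(np.abs(centers - centers[dwell]))
    rank = np.empty(n_resp, dtype=int)
    rank[order] = np.arange(n_resp)
    return rank[km.labels_] + 1


def _cluster_cardiac(phase: np.ndarray, n_cardiac: int, seed: int) -> np.ndarray:
    if n_cardiac == 1:
        return np.ones(len(phase), dtype=int)
    pts = np.column_stack([np.cos(phase), np.sin(phase)])
    _check_distinct(phase, n_cardiac)
    km = KMeans(n_clusters=n_cardiac, n_init=10, random_state=seed).fit(pts)
    if np.any(np.bincount(km.labels_, minlength=n_cardiac) == 0):
        raise ValueError("empty cardiac cluster; reduce K_card")
    ang = np.arctan2(km.cluster_centers_[:, 1], km.cluster_centers_[:, 0])
    order = np.argsort(ang)
    rank = np.empty(n_cardiac, dtype=int)
    rank[order] = np.arange(n_cardiac)
    return rank[km.labels_] + 1


def _detect_end_diastole(dataset, phi_rt, u_x_rt, card_bin_tr,
                         n_cardiac) -> int:
    """Cardiac bin with the largest blood-pool area in bin-averaged frames."""
    if u_x_rt is None or phi_rt is None or n_cardiac == 1:
        return 1
    m = dataset.seq.matrix
    areas = []
    for c in range(1, n_cardiac + 1):
        sel = card_bin_tr == c
        if not np.any(sel):
            areas.append(0)
            continue
        img = np.abs(u_x_rt @ phi_rt[:, sel].mean(axis=1)).reshape(m, m)
        center = img[m // 4: 3 * m // 4, m // 4: 3 * m // 4]
        areas.append(int(np.sum(center > 0.6 * center.max())))
    return int(np.argmax(areas)) + 1


# --------------------------------------------------------------------------- #
# scoring against simulator ground truth
# --------------------------------------------------------------------------- #


def score_binning(est: np.ndarray, truth: np.ndarray, k: int,
                  circular: bool) -> float:
    """Fraction of readouts in the matched ground-truth bin or an adjacent one.

    Estimated cluster ids are matched to truth bins by Hungarian assignment on
    the confusion matrix (cluster ids are arbitrary up to relabeling).
    """
    est = np.asarray(est) - 1
    truth = np.asarray(truth) - 1
    conf = np.zeros((k, k))
    np.add.at(conf, (est, truth), 1)
    row, col = linear_sum_assignment(-conf)
    mapping = np.empty(k, dtype=int)
    mapping[row] = col
    mapped = mapping[est]
    diff = np.abs(mapped - truth)
    if circular:
        diff = np.minimum(diff, k - diff)
    return float(np.mean(diff <= 1))
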