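"""Digital beating/breathing short-axis rat-heart phantom and k-space simulator.

Geometry is a 2D short-axis left-ventricle slice: background air, a chest-wall
band, a myocardial annulus around the LV blood pool, and a descending-aorta
disk.  Cardiac motion is radial contraction of the annulus (~300 bpm),
respiratory motion a rigid in-plane translation with an end-expiration dwell
(~60 cpm).  Each readout samples one fully-sampled frequency-encode line at a
single integer ky: even-numbered readouts acquire the k-space center line
(training data), odd-numbered readouts a Gaussian-density random ky (imaging
data).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .sequence import SequenceParams, TissueParams, simulate_joint_pair

LABELS = {"background": 0, "chest": 1, "myocardium": 2, "blood": 3, "aorta": 4}
LABEL_NAMES = {v: k for k, v in LABELS.items()}


def default_tissues() -> dict[str, TissueParams]:
    """Pre/post-Gd T1 values typical of rat tissue at high field (ms)."""
    return {
        "chest": TissueParams(t1_pre=900.0, t1_post=550.0, m0=0.8, alpha=5.0, b=-1.0),
        "myocardium": TissueParams(t1_pre=1550.0, t1_post=750.0, m0=1.0, alpha=5.0, b=-1.0),
        "blood": TissueParams(t1_pre=2200.0, t1_post=600.0, m0=1.4, alpha=5.0, b=-1.0),
        "aorta": TissueParams(t1_pre=2200.0, t1_post=600.0, m0=1.4, alpha=5.0, b=-1.0),
    }


@dataclass
class PhantomConfig:
    """Geometry, motion, contrast and noise of the synthetic acquisition."""

    heart_rate: float = 300.0           # bpm
    resp_rate: float = 60.0             # cycles per minute
    contraction_amplitude: float = 0.3  # fraction of blood-pool radius
    resp_translation: float = 2.5       # mm, peak in-plane displacement
    resp_direction: tuple = (0.29, 0.96)  # (y, x) unit direction; mostly along
                                          # frequency encode so the center line
                                          # (a projection along y) can see it
    noise_sigma: float | None = None    # complex k-space noise std per component
    noise_snr: float | None = 30.0      # alternative: peak-signal / sigma
    seed: int = 0
    hct: float = 0.42
    inflow_blood: bool = True           # blood follows the alpha=0 (inflow) model
    tissues: dict = field(default_factory=default_tissues)
    # geometry as fractions of the matrix size
    heart_center: tuple = (0.47, 0.48)  # (y, x)
    blood_radius: float = 0.095
    myo_outer_radius: float = 0.19
    aorta_center: tuple = (0.72, 0.72)
    aorta_radius: float = 0.045
    chest_y0: float = 0.86              # chest band occupies y in [y0, y0+h]
    chest_height: float = 0.10
    # binning ground truth + sampling
    n_cardiac_bins: int = 10
    n_resp_bins: int = 5
    gauss_ky_frac: float = 1.0 / 6.0    # ky sampling std = frac * matrix
    scan_gap_ms: float = 9.0e5          # timestamp gap between pre and post scans

    def __post_init__(self) -> None:
        if self.heart_rate <= 0 or self.resp_rate <= 0:
            raise ValueError("heart_rate and resp_rate must be positive")
        if not 0.0 < self.hct < 1.0:
            raise ValueError(f"hct must be in (0, 1), got {self.hct}")
        if self.noise_sigma is not None and self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")

    @property
    def cardiac_period_ms(self) -> float:
        return 60000.0 / self.heart_rate

    @property
    def resp_period_ms(self) -> float:
        return 60000.0 / self.resp_rate


@dataclass
class GroundTruth:
    """Per-pixel truth at the reference state plus per-readout motion truth."""

    labels: np.ndarray          # (M, M) int, reference (end-diastole, end-exp)
    t1_pre_map: np.ndarray
    t1_post_map: np.ndarray
    m0_map: np.ndarray
    alpha_map: np.ndarray
    b_map: np.ndarray
    septal_mask: np.ndarray     # (M, M) bool, septal sector of the annulus
    cardiac_phase: np.ndarray   # (n_readouts_total,) in [0, 1)
    resp_disp: np.ndarray       # (n_readouts_total,) pixels
    cardiac_bin: np.ndarray     # 1..n_cardiac_bins
    resp_bin: np.ndarray        # 1..n_resp_bins
    hct: float


@dataclass
class KSpaceDataset:
    """Acquired lines with per-readout metadata (both scans concatenated)."""

    lines: np.ndarray           # (n_total, matrix) complex
    timestamp: np.ndarray       # ms
    ky_index: np.ndarray        # centered convention, ky=0 is the center line
    is_training: np.ndarray     # bool
    scan: np.ndarray            # 0 = pre, 1 = post
    ir_block_index: np.ndarray  # 1..n_ir_pulses
    t1_index: np.ndarray        # 1..N
    seq: SequenceParams
    ground_truth: GroundTruth | None = None
    noise_sigma: float = 0.0
    seed: int = 0

    @property
    def n_readouts(self) -> int:
        return self.lines.shape[0]


def in_plane_voxel_size(seq: SequenceParams) -> float:
    """In-plane voxel size = fov / matrix (mm)."""
    if seq.matrix <= 0:
        raise ValueError("matrix must be positive")
    return seq.fov / seq.matrix


# --------------------------------------------------------------------------- #
# geometry and motion
# --------------------------------------------------------------------------- #


def cardiac_waveform(phase: np.ndarray) -> np.ndarray:
    """Contraction weight in [0, 1]; 0 at phase 0 (end-diastole)."""
    return np.sin(np.pi * np.asarray(phase)) ** 2


def resp_waveform(phase: np.ndarray) -> np.ndarray:
    """Displacement weight in [0, 1] with a long end-expiration dwell at 0."""
    return ((1.0 - np.cos(2.0 * np.pi * np.asarray(phase))) / 2.0) ** 3


def render_labels(config: PhantomConfig, seq: SequenceParams,
                  contraction: float = 0.0, disp_pix: float = 0.0) -> np.ndarray:
    """Integer label map for a given contraction weight and respiratory shift."""
    m = seq.matrix
    yy, xx = np.mgrid[0:m, 0:m].astype(float)
    dy, dx = (d * disp_pix for d in config.resp_direction)
    yy -= dy  # rigid translation of all structures
    xx -= dx
    cy, cx = (c * m for c in config.heart_center)
    r_blood = config.blood_radius * m * (1.0 - config.contraction_amplitude * contraction)
    r_outer = config.myo_outer_radius * m * (
        1.0 - 0.4 * config.contraction_amplitude * contraction)
    if r_outer >= min(cy, cx, m - cy, m - cx):
        raise ValueError("heart does not fit inside the matrix")
    labels = np.zeros((m, m), dtype=np.int8)
    # chest wall band
    y0 = config.chest_y0 * m
    labels[(yy >= y0) & (yy < y0 + config.chest_height * m)] = LABELS["chest"]
    # aorta
    ay, ax = (c * m for c in config.aorta_center)
    r_ao = config.aorta_radius * m
    labels[(yy - ay) ** 2 + (xx - ax) ** 2 <= r_ao ** 2] = LABELS["aorta"]
    rr2 = (yy - cy) ** 2 + (xx - cx) ** 2
    myo = (rr2 <= r_outer ** 2)
    if np.any(myo & (labels == LABELS["chest"])):
        raise ValueError("heart overlaps the chest wall")
    labels[myo] = LABELS["myocardium"]
    labels[rr2 <= r_blood ** 2] = LABELS["blood"]
    return labels


def make_phantom(config: PhantomConfig, seq: SequenceParams):
    """Reference (end-diastole, end-expiration) label map and parameter maps."""
    labels = render_labels(config, seq, contraction=0.0, disp_pix=0.0)
    m = seq.matrix
    maps = {k: np.zeros((m, m)) for k in ("t1_pre", "t1_post", "m0", "alpha", "b")}
    for name, lab in LABELS.items():
        if name == "background":
            continue
        tis = config.tissues[name]
        sel = labels == lab
        maps["t1_pre"][sel] = tis.t1_pre
        maps["t1_post"][sel] = tis.t1_post
        maps["m0"][sel] = tis.m0
        maps["alpha"][sel] = tis.alpha
        maps["b"][sel] = tis.b
    if not np.any(labels == LABELS["myocardium"]):
        raise ValueError("empty myocardial annulus")
    maps["septal_mask"] = septal_mask(config, seq, labels)
    return labels, maps


def septal_mask(config: PhantomConfig, seq: SequenceParams,
                labels: np.ndarray) -> np.ndarray:
    """Annulus sector facing the aorta (stand-in for the septum)."""
    m = seq.matrix
    yy, xx = np.mgrid[0:m, 0:m].astype(float)
    cy, cx = (c * m for c in config.heart_center)
    ay, ax = (c * m for c in config.aorta_center)
    sep_dir = np.arctan2(ay - cy, ax - cx)
    ang = np.arctan2(yy - cy, xx - cx)
    dang = np.angle(np.exp(1j * (ang - sep_dir)))
    return (labels == LABELS["myocardium"]) & (np.abs(dang) <= np.pi / 4)


# --------------------------------------------------------------------------- #
# signal tables and frame rendering
# --------------------------------------------------------------------------- #


def tissue_signal_table(config: PhantomConfig, seq: SequenceParams) -> np.ndarray:
    """Signal per (label, scan, t1_index); blocks start from periodic steady state.

    Returns shape (n_labels, 2, N); label 0 (background) is zero.  With
    ``inflow_blood`` the blood/aorta longitudinal magnetization is unperturbed
    by the readout train (pure IR recovery) and only scaled by sin(alpha) at
    readout.
    """
    n = seq.readouts_per_period
    table = np.zeros((len(LABELS), 2, n))
    for name, lab in LABELS.items():
        if name == "background":
            continue
        tis = config.tissues[name]
        inflow = config.inflow_blood and name in ("blood", "aorta")
        js = simulate_joint_pair(tis, seq, look_locker=not inflow)
        scale = np.sin(np.deg2rad(tis.alpha)) if inflow else 1.0
        table[lab, 0] = scale * js.pre_curve
        table[lab, 1] = scale * js.post_curve
    return table


def motion_state(t_ms: np.ndarray, config: PhantomConfig, seq: SequenceParams):
    """(cardiac phase in [0,1), contraction weight, resp shift in pixels) at t."""
    t_ms = np.asarray(t_ms, dtype=float)
    cphase = (t_ms / config.cardiac_period_ms) % 1.0
    rphase = (t_ms / config.resp_period_ms) % 1.0
    disp = (config.resp_translation / in_plane_voxel_size(seq)) * resp_waveform(rphase)
    return cphase, cardiac_waveform(cphase), disp


def render_frame(t_ms: float, scan: int, config: PhantomConfig,
                 seq: SequenceParams) -> np.ndarray:
    """Complex image at absolute scan time ``t_ms`` (scan: 0 = pre, 1 = post)."""
    if t_ms < 0:
        raise ValueError("t must be non-negative")
    table = tissue_signal_table(config, seq)
    idx = int(t_ms / seq.tr) % seq.readouts_per_period
    _, w, disp = motion_state(np.array([t_ms]), config, seq)
    labels = render_labels(config, seq, contraction=float(w[0]), disp_pix=float(disp[0]))
    return table[:, scan, idx][labels].astype(complex)


# --------------------------------------------------------------------------- #
# acquisition
# --------------------------------------------------------------------------- #


def _gaussian_ky(rng: np.random.Generator, n: int, seq: SequenceParams,
                 frac: float) -> np.ndarray:
    """Truncated, rounded Gaussian-density integer ky in [-M/2, M/2-1]."""
    m = seq.matrix
    ky = np.rint(rng.normal(0.0, frac * m, size=n)).astype(int)
    return np.clip(ky, -m // 2, m // 2 - 1)


def sample_line(images: np.ndarray, ky: np.ndarray) -> np.ndarray:
    """One centered-ky k-space line per image (orthonormal 2D DFT convention).

    ``images``: (n, M, M) indexed [y, x]; ``ky``: (n,) integers.  Equivalent to
    ``fftshift(fft2(img, norm='ortho'))[ky + M//2, :]``.
    """
    m = images.shape[-1]
    y = np.arange(m)
    w = np.exp(-2j * np.pi * np.outer(ky, y) / m) / np.sqrt(m)
    proj = np.einsum("ny,nyx->nx", w, images)
    return np.fft.fftshift(np.fft.fft(proj, axis=-1, norm="ortho"), axes=-1)


def acquire(config: PhantomConfig, seq: SequenceParams,
            seed: int | None = None) -> KSpaceDataset:
    """Simulate the full two-scan (pre + post Gd) interleaved acquisition."""
    rng = np.random.default_rng(config.seed if seed is None else seed)
    m = seq.matrix
    n_per_scan = seq.n_readouts
    n_total = 2 * n_per_scan
    table = tissue_signal_table(config, seq)

    ordinal = np.tile(np.arange(n_per_scan), 2)
    scan = np.repeat([0, 1], n_per_scan)
    block = ordinal // seq.readouts_per_period + 1
    t1_idx = ordinal % seq.readouts_per_period + 1
    # readout 1, 3, 5... imaging; readout 2, 4, ... training (ky = 0)
    is_training = (t1_idx % 2) == 0
    t_local = ordinal * seq.tr  # time within scan; inversion at each block start
    timestamp = t_local + scan * (n_per_scan * seq.tr + config.scan_gap_ms)

    ky = np.zeros(n_total, dtype=int)
    ky[~is_training] = _gaussian_ky(rng, int(np.sum(~is_training)), seq,
                                    config.gauss_ky_frac)

    cphase, w, disp = motion_state(t_local, config, seq)
    # quantize motion for label-map caching; coarse enough to share maps,
    # fine enough (<0.5 px radial change) to be invisible at bin resolution
    wq = np.round(w * 192) / 192
    dispq = np.round(disp * 16) / 16

    lines = np.empty((n_total, m), dtype=complex)
    cache: dict[tuple, np.ndarray] = {}
    keys = np.stack([wq, dispq], axis=1)
    uniq, inverse = np.unique(keys, axis=0, return_inverse=True)
    order = np.argsort(inverse, kind="stable")
    bounds = np.searchsorted(inverse[order], np.arange(len(uniq) + 1))
    for g in range(len(uniq)):
        sel = order[bounds[g]:bounds[g + 1]]
        labels = render_labels(config, seq, contraction=uniq[g, 0],
                               disp_pix=uniq[g, 1])
        for start in range(0, len(sel), 512):
            sub = sel[start:start + 512]
            sig = table[:, scan[sub], t1_idx[sub] - 1]   # (n_labels, n_sub)
            imgs = sig.T[:, labels]                      # (n_sub, M, M)
            lines[sub] = sample_line(imgs, ky[sub])

    sigma = config.noise_sigma
    if sigma is None:
        sigma = 0.0
        if config.noise_snr is not None:
            # image-domain SNR: with the orthonormal DFT, per-pixel image
            # noise std equals the per-sample complex k-space noise std, so
            # sigma = (peak tissue signal) / SNR
            sigma = float(np.max(np.abs(table)) / config.noise_snr)
    if sigma > 0:
        lines += sigma * (rng.standard_normal(lines.shape)
                          + 1j * rng.standard_normal(lines.shape))

    labels_ref, maps = make_phantom(config, seq)
    rw = resp_waveform((t_local / config.resp_period_ms) % 1.0)
    gt = GroundTruth(
        labels=labels_ref,
        t1_pre_map=maps["t1_pre"], t1_post_map=maps["t1_post"],
        m0_map=maps["m0"], alpha_map=maps["alpha"], b_map=maps["b"],
        septal_mask=maps["septal_mask"],
        cardiac_phase=cphase,
        resp_disp=disp,
        cardiac_bin=(cphase * config.n_cardiac_bins).astype(int) + 1,
        resp_bin=np.minimum((rw * config.n_resp_bins).astype(int),
                            config.n_resp_bins - 1) + 1,
        hct=config.hct,
    )
    return KSpaceDataset(
        lines=lines, timestamp=timestamp, ky_index=ky, is_training=is_training,
        scan=scan, ir_block_index=block, t1_index=t1_idx, seq=seq,
        ground_truth=gt, noise_sigma=float(sigma),
        seed=int(config.seed if seed is None else seed),
    )
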