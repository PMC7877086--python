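"""File formats and run configuration.

Raw k-space goes to a documented HDF5 layout (``/lines``, ``/meta/*``,
``/ground_truth/*``), parameter maps to NIfTI-1 with the acquisition voxel
size, configuration to YAML, statistics to JSON/CSV.
"""

from __future__ import annotations

import dataclasses
import hashlib
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import nibabel as nib
import numpy as np
import yaml

from .phantom import GroundTruth, KSpaceDataset, PhantomConfig, default_tissues
from .realtime import BinAssignment
from .sequence import GridSpec, SequenceParams, T1Basis, T1Dictionary, TissueParams
from .tensor import FactoredImage, ReconConfig

LAYOUT_VERSION = "1"

_META_KEYS = ("timestamp", "ky_index", "is_training", "scan",
              "ir_block_index", "t1_index")
_GT_MAPS = ("labels", "t1_pre_map", "t1_post_map", "m0_map", "alpha_map",
            "b_map", "septal_mask")
_GT_TRACES = ("cardiac_phase", "resp_disp", "cardiac_bin", "resp_bin")


@dataclass
class RunConfig:
    """Everything needed to reproduce one end-to-end phantom run."""

    seq: SequenceParams = field(default_factory=SequenceParams)
    phantom: PhantomConfig = field(default_factory=PhantomConfig)
    recon: ReconConfig = field(default_factory=ReconConfig)
    n_resp_bins: int = 5
    n_cardiac_bins: int = 10
    l_rt: int = 16
    dict_n_t1: int = 25
    dict_n_flip: int = 5
    dict_n_b: int = 5
    seed: int = 0
    preset: str = "custom"

    def grid_spec(self) -> GridSpec:
        return GridSpec.reduced(self.dict_n_t1, self.dict_n_flip, self.dict_n_b)


def protocol_config(seed: int = 0) -> RunConfig:
    """Printed protocol: 128x128, FOV 40 mm, TR 7 ms, flip 5 deg, 85 IR pulses,
    N = 416, 10 cardiac x 5 respiratory bins, ~300 bpm / ~60 cpm motion."""
    return RunConfig(seed=seed, preset="protocol")


def fast_test_config(seed: int = 0) -> RunConfig:
    """Desk-scale preset: matrix 64, 48 IR blocks, full N = 416 timing."""
    seq = SequenceParams(matrix=64, n_ir_pulses=48)
    return RunConfig(seq=seq, phantom=PhantomConfig(seed=seed),
                     dict_n_t1=21, seed=seed, preset="fast-test")


def tiny_config(seed: int = 0) -> RunConfig:
    """Smoke-test preset: matrix 32, 6 IR blocks, 4x3 bins."""
    seq = SequenceParams(matrix=32, n_ir_pulses=6)
    return RunConfig(seq=seq, phantom=PhantomConfig(seed=seed),
                     recon=ReconConfig(rank_spatial=12, rank_cardiac=3,
                                       rank_resp=2, rank_t1=6),
                     n_resp_bins=3, n_cardiac_bins=4, l_rt=8,
                     dict_n_t1=13, dict_n_flip=3, dict_n_b=3,
                     seed=seed, preset="tiny")


PRESETS = {"protocol": protocol_config, "fast-test": fast_test_config,
           "tiny": tiny_config}


# --------------------------------------------------------------------------- #
# YAML config
# --------------------------------------------------------------------------- #


def config_to_dict(cfg: RunConfig) -> dict:
    d = dataclasses.asdict(cfg)
    d["phantom"]["tissues"] = {
        k: dataclasses.asdict(v) for k, v in cfg.phantom.tissues.items()}
    return d


def config_from_dict(d: dict) -> RunConfig:
    d = dict(d)
    seq = SequenceParams(**d.pop("seq", {}))
    ph = dict(d.pop("phantom", {}))
    tissues = ph.pop("tissues", None)
    if tissues is not None:
        ph["tissues"] = {k: TissueParams(**v) for k, v in tissues.items()}
    else:
        ph["tissues"] = default_tissues()
    for key in ("heart_center", "aorta_center"):
        if key in ph:
            ph[key] = tuple(ph[key])
    phantom = PhantomConfig(**ph)
    recon = ReconConfig(**d.pop("recon", {}))
    return RunConfig(seq=seq, phantom=phantom, recon=recon, **d)


def save_config(cfg: RunConfig, path) -> None:
    Path(path).write_text(yaml.safe_dump(config_to_dict(cfg), sort_keys=True))


def load_config(path) -> RunConfig:
    return config_from_dict(yaml.safe_load(Path(path).read_text()))


def config_hash(cfg: RunConfig) -> str:
    payload = yaml.safe_dump(config_to_dict(cfg), sort_keys=True)
    return hashlib.sha1(payload.encode()).hexdigest()[:12]


# --------------------------------------------------------------------------- #
# raw k-space HDF5
# --------------------------------------------------------------------------- #


def write_kspace_hdf5(path, dataset: KSpaceDataset) -> None:
    with h5py.File(path, "w") as f:
        f.attrs["layout_version"] = LAYOUT_VERSION
        f.attrs["seed"] = dataset.seed
        f.attrs["noise_sigma"] = dataset.noise_sigma
        f.attrs["seq"] = yaml.safe_dump(dataclasses.asdict(dataset.seq))
        f.create_dataset("lines", data=dataset.lines)
        meta = f.create_group("meta")
        for k in _META_KEYS:
            meta.create_dataset(k, data=np.asarray(getattr(dataset, k)))
        if dataset.ground_truth is not None:
            gt = f.create_group("ground_truth")
            g = dataset.ground_truth
            for k in _GT_MAPS + _GT_TRACES:
                gt.create_dataset(k, data=np.asarray(getattr(g, k)))
            gt.attrs["hct"] = g.hct


def read_kspace_hdf5(path) -> KSpaceDataset:
    with h5py.File(path, "r") as f:
        version = f.attrs.get("layout_version")
        if version != LAYOUT_VERSION:
            raise ValueError(
                f"unsupported raw-data layout version {version!r} "
                f"(expected {LAYOUT_VERSION!r})")
        for name in ("lines",) + tuple(f"meta/{k}" for k in _META_KEYS):
            if name not in f:
                raise KeyError(f"raw-data file is missing dataset '/{name}'")
        seq = SequenceParams(**yaml.safe_load(f.attrs["seq"]))
        meta = {k: f["meta"][k][()] for k in _META_KEYS}
        meta["is_training"] = meta["is_training"].astype(bool)
        gt = None
        if "ground_truth" in f:
            g = f["ground_truth"]
            fields = {k: g[k][()] for k in _GT_MAPS + _GT_TRACES}
            fields["septal_mask"] = fields["septal_mask"].astype(bool)
            gt = GroundTruth(hct=float(g.attrs["hct"]), **fields)
        return KSpaceDataset(
            lines=f["lines"][()], seq=seq, ground_truth=gt,
            noise_sigma=float(f.attrs["noise_sigma"]),
            seed=int(f.attrs["seed"]), **meta)


# --------------------------------------------------------------------------- #
# bins, dictionary, factors
# --------------------------------------------------------------------------- #


def write_bins_hdf5(path, bins: BinAssignment) -> None:
    with h5py.File(path, "w") as f:
        f.attrs["layout_version"] = LAYOUT_VERSION
        for k in ("readout_id", "scan", "cardiac_bin", "resp_bin", "t1_index"):
            f.create_dataset(k, data=np.asarray(getattr(bins, k)))
        for k in ("n_cardiac", "n_resp", "end_expiration_bin",
                  "end_diastole_bin"):
            f.attrs[k] = getattr(bins, k)


def read_bins_hdf5(path) -> BinAssignment:
    with h5py.File(path, "r") as f:
        arrays = {k: f[k][()] for k in ("readout_id", "scan", "cardiac_bin",
                                        "resp_bin", "t1_index")}
        attrs = {k: int(f.attrs[k]) for k in
                 ("n_cardiac", "n_resp", "end_expiration_bin",
                  "end_diastole_bin")}
    return BinAssignment(**arrays, **attrs)


def write_dictionary_hdf5(path, dictionary: T1Dictionary,
                          basis: T1Basis | None = None) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("atoms", data=dictionary.atoms)
        f.create_dataset("grid", data=dictionary.grid)
        gs = dictionary.grid_spec
        f.attrs["t1_values"] = np.asarray(gs.t1_values)
        f.attrs["flip_values"] = np.asarray(gs.flip_values)
        f.attrs["b_values"] = np.asarray(gs.b_values)
        if basis is not None:
            f.create_dataset("basis", data=basis.basis)
            f.create_dataset("singular_values", data=basis.singular_values)


def write_factors_hdf5(path, fimg: FactoredImage) -> None:
    with h5py.File(path, "w") as f:
        f.attrs["layout_version"] = LAYOUT_VERSION
        f.attrs["dims"] = fimg.dims
        f.attrs["matrix"] = fimg.matrix
        for k in ("u_c", "u_r", "u_t1", "core", "phi"):
            f.create_dataset(k, data=getattr(fimg, k))
        if fimg.u_x is not None:
            f.create_dataset("u_x", data=fimg.u_x)


def read_factors_hdf5(path) -> FactoredImage:
    with h5py.File(path, "r") as f:
        kw = {k: f[k][()] for k in ("u_c", "u_r", "u_t1", "core", "phi")}
        u_x = f["u_x"][()] if "u_x" in f else None
        return FactoredImage(dims=tuple(f.attrs["dims"]),
                             matrix=int(f.attrs["matrix"]), u_x=u_x, **kw)


# --------------------------------------------------------------------------- #
# NIfTI maps
# --------------------------------------------------------------------------- #


def map_affine(seq: SequenceParams) -> np.ndarray:
    vox = seq.fov / seq.matrix
    return np.diag([vox, vox, seq.slice_thickness, 1.0])


def write_maps_nifti(maps: dict, seq: SequenceParams, outdir) -> dict:
    """Write each 2D map as a single-slice NIfTI-1 file; returns name->path."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    affine = map_affine(seq)
    paths = {}
    for name, data in maps.items():
        data = np.asarray(data, dtype=np.float32)
        if not np.all(np.isfinite(data)):
            warnings.warn(f"map '{name}' contains non-finite values "
                          "(written as NaN)", RuntimeWarning)
        img = nib.Nifti1Image(data[..., None], affine)
        img.header.set_zooms((seq.fov / seq.matrix, seq.fov / seq.matrix,
                              seq.slice_thickness))
        p = outdir / f"{name}.nii"
        nib.save(img, str(p))
        paths[name] = p
    return paths
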