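"""File formats, configuration, and provenance.

NIfTI-1 for volumes and masks (nibabel), HDF5 for V x V matrices and
embeddings (h5py, with object timestamps disabled so outputs are
byte-reproducible), TSV for tables, JSON for manifests and reports, YAML
for configuration. Voxel indices are 0-based and distances are between
voxel centres throughout.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import h5py
import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cohort import Cohort, CohortSpec, LatentLayout, SimulatedSubject


@dataclass
class VolumeImage:
    """A 3D or 4D volume on an isotropic grid (time axis last if 4D)."""

    data: np.ndarray
    voxel_size_mm: float = 3.0
    origin: tuple = (0.0, 0.0, 0.0)

    def __post_init__(self):
        if self.voxel_size_mm <= 0:
            raise ValueError("voxel size must be positive")
        if self.data.ndim not in (3, 4):
            raise ValueError("volume must be 3D or 4D")


def write_volume(img: VolumeImage, path) -> None:
    affine = np.diag([img.voxel_size_mm] * 3 + [1.0])
    affine[:3, 3] = img.origin
    nib.save(nib.Nifti1Image(np.asarray(img.data), affine), str(path))


def read_volume(path) -> VolumeImage:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        nii = nib.load(str(path))
    except Exception as e:  # nibabel raises several format-specific errors
        raise ValueError(f"{path} is not a readable NIfTI file: {e}") from e
    zooms = nii.header.get_zooms()[:3]
    if max(zooms) - min(zooms) > 1e-4:
        raise ValueError(f"{path}: anisotropic voxels not supported")
    return VolumeImage(
        data=np.asarray(nii.dataobj),
        voxel_size_mm=float(zooms[0]),
        origin=tuple(float(v) for v in nii.affine[:3, 3]),
    )


# ---------------------------------------------------------------------------
# configuration

_VALID_ENUMS = {
    "lesion_reference_stat": ("mean", "min"),
    "ccc_convention": ("overall", "mean_pairwise"),
    "anatomical_metric": ("nearest_voxel", "centroid"),
}


@dataclass
class AnalysisConfig:
    """All analysis tunables with their defaults.

    threshold_pct: per-row FC percentile kept (strictly above).
    alpha / diffusion_time / n_components: diffusion-embedding settings.
    lesion_reference_stat: how lesioned voxels are summarised per gradient.
    ccc_convention: multi-session concordance form.
    anatomical_metric: voxel-to-lesion distance definition.
    common_mask_mode: restrict every patient to a cohort-wide common mask.
    n_bins_sweep: bin counts for the delta-concordance sweep.
    n_perm: permutation iterations for the clinical group test.
    """

    threshold_pct: float = 90.0
    alpha: float = 0.5
    diffusion_time: float = 0.0
    n_components: int = 3
    lesion_reference_stat: str = "mean"
    ccc_convention: str = "overall"
    anatomical_metric: str = "nearest_voxel"
    common_mask_mode: bool = False
    n_bins_sweep: tuple = (5, 10, 20, 50, 100)
    n_perm: int = 10000
    min_mask_voxels: int = 50
    seed: int = 0

    def __post_init__(self):
        for name, allowed in _VALID_ENUMS.items():
            if getattr(self, name) not in allowed:
                raise ValueError(f"{name} must be one of {allowed}")
        self.n_bins_sweep = tuple(int(b) for b in self.n_bins_sweep)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["n_bins_sweep"] = list(self.n_bins_sweep)
        return d


def config_from_dict(d: dict | None) -> AnalysisConfig:
    d = dict(d or {})
    known = {f.name for f in fields(AnalysisConfig)}
    unknown = sorted(set(d) - known)
    if unknown:
        raise ValueError(f"unknown config key(s): {unknown}")
    return AnalysisConfig(**d)


def load_config(path) -> AnalysisConfig:
    """Load a YAML config; missing keys take defaults, unknown keys raise."""
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if doc is None:
        doc = {}
    if not isinstance(doc, dict):
        raise ValueError("config document must be a mapping")
    return config_from_dict(doc)


def dump_config(cfg: AnalysisConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg.to_dict(), fh, sort_keys=True)


def config_hash(cfg: AnalysisConfig) -> str:
    blob = json.dumps(cfg.to_dict(), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


# ---------------------------------------------------------------------------
# provenance

def file_checksum(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()[:16]


@dataclass
class Provenance:
    """Traceability record attached to every derived artifact."""

    tool_version: str = __version__
    config_hash: str = ""
    input_checksums: dict = field(default_factory=dict)
    seeds: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return asdict(self)


def write_json(obj, path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, sort_keys=True, indent=2)
        fh.write("\n")


# ---------------------------------------------------------------------------
# HDF5 matrices and embeddings

def write_matrix_h5(path, values: np.ndarray, name: str = "values", attrs: dict | None = None) -> None:
    with h5py.File(path, "w", track_order=False) as fh:
        ds = fh.create_dataset(name, data=values, track_times=False)
        for k, v in (attrs or {}).items():
            ds.attrs[k] = v


def write_embedding_h5(path, emb, cfg_attrs: dict | None = None) -> None:
    with h5py.File(path, "w") as fh:
        fh.create_dataset("values", data=emb.values, track_times=False)
        fh.create_dataset("eigenvalues", data=emb.eigenvalues, track_times=False)
        fh.create_dataset("variance_ratio", data=emb.variance_ratio, track_times=False)
        for k, v in (cfg_attrs or {}).items():
            fh.attrs[k] = v


def read_embedding_h5(path):
    from .gradients import DiffusionEmbedding, EmbeddingConfig

    with h5py.File(path, "r") as fh:
        return DiffusionEmbedding(
            values=fh["values"][()],
            eigenvalues=fh["eigenvalues"][()],
            variance_ratio=fh["variance_ratio"][()],
            config=EmbeddingConfig(
                alpha=float(fh.attrs.get("alpha", 0.5)),
                n_components=int(fh["values"].shape[1]),
                diffusion_time=float(fh.attrs.get("diffusion_time", 0.0)),
            ),
        )


# ---------------------------------------------------------------------------
# cohort directories

def _embed3d(layout: LatentLayout, rows: np.ndarray, fill=0.0) -> np.ndarray:
    out = np.full(layout.grid_dims, fill, dtype=float)
    out[layout.gm_mask] = rows
    return out


def write_cohort(cohort: Cohort, outdir) -> Path:
    """Write a cohort as NIfTI volumes, TSV clinical table, JSON manifest."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    lay = cohort.layout
    vs = lay.voxel_size_mm
    (out / "layout").mkdir(exist_ok=True)
    write_volume(VolumeImage(lay.gm_mask.astype(np.uint8), vs), out / "layout" / "gm_mask.nii")
    for g in range(lay.n_gradients):
        write_volume(
            VolumeImage(_embed3d(lay, lay.latent_coords[:, g]), vs),
            out / "layout" / f"latent_g{g + 1}.nii",
        )

    def write_subject(subj: SimulatedSubject, sub_out: Path):
        sub_out.mkdir(parents=True, exist_ok=True)
        for s, ts in enumerate(subj.sessions):
            vol = np.zeros(lay.grid_dims + (ts.shape[1],), dtype=np.float32)
            vol[lay.gm_mask] = ts.astype(np.float32)
            write_volume(VolumeImage(vol, vs), sub_out / f"ses-{s + 1}_bold.nii")
        if subj.lesion_mask is not None and subj.lesion_mask.any():
            write_volume(VolumeImage(subj.lesion_mask.astype(np.uint8), vs), sub_out / "lesion.nii")
        if subj.truth is not None:
            for key in ("amplitude", "d_latent"):
                write_volume(
                    VolumeImage(_embed3d(lay, subj.truth[key]), vs),
                    sub_out / f"truth_{key}.nii",
                )

    for subj in cohort.controls:
        write_subject(subj, out / "controls" / subj.subject_id)
    for subj in cohort.patients:
        write_subject(subj, out / "patients" / subj.subject_id)

    cohort.clinical.to_csv(out / "clinical.tsv", sep="\t")

    manifest = {
        "grid_dims": list(lay.grid_dims),
        "voxel_size_mm": vs,
        "n_gradients_latent": lay.n_gradients,
        "anchor_points": np.asarray(lay.anchor_points).tolist(),
        "latent_metric": lay.latent_metric,
        "spec": asdict(cohort.spec),
        "controls": [s.subject_id for s in cohort.controls],
        "patients": [s.subject_id for s in cohort.patients],
        "n_sessions_patient": cohort.spec.n_sessions,
        "tool_version": __version__,
    }
    write_json(manifest, out / "manifest.json")
    return out


def read_cohort(indir) -> Cohort:
    """Load a cohort directory written by :func:`write_cohort`."""
    indir = Path(indir)
    manifest_path = indir / "manifest.json"
    if not manifest_path.exists():
        raise FileNotFoundError(f"no manifest.json under {indir}")
    manifest = json.loads(manifest_path.read_text())
    grid_dims = tuple(manifest["grid_dims"])
    gm_img = read_volume(indir / "layout" / "gm_mask.nii")
    gm = gm_img.data.astype(bool)
    if gm.shape != grid_dims:
        raise ValueError("grey-matter mask grid does not match the manifest")
    G = manifest["n_gradients_latent"]
    coords = np.column_stack(
        [read_volume(indir / "layout" / f"latent_g{g + 1}.nii").data[gm] for g in range(G)]
    )
    layout = LatentLayout(
        grid_dims=grid_dims,
        voxel_size_mm=manifest["voxel_size_mm"],
        gm_mask=gm,
        latent_coords=coords,
        anchor_points=np.asarray(manifest["anchor_points"], dtype=float),
        voxel_ijk=np.array(np.nonzero(gm)).T,
        latent_metric=manifest.get("latent_metric", "euclidean"),
    )
    spec_d = dict(manifest["spec"])
    for key in ("lesion_radius_range",):
        if key in spec_d:
            spec_d[key] = tuple(spec_d[key])
    spec = CohortSpec(**spec_d)

    def read_subject(sub_dir: Path, sid: str, n_sessions: int) -> SimulatedSubject:
        sessions = []
        for s in range(n_sessions):
            vol = read_volume(sub_dir / f"ses-{s + 1}_bold.nii").data
            if vol.shape[:3] != grid_dims:
                raise ValueError(f"{sid}: session grid does not match the cohort manifest")
            sessions.append(np.asarray(vol[gm], dtype=float))
        lesion_path = sub_dir / "lesion.nii"
        lesion = read_volume(lesion_path).data.astype(bool) if lesion_path.exists() else None
        truth = None
        if (sub_dir / "truth_amplitude.nii").exists():
            truth = {
                key: read_volume(sub_dir / f"truth_{key}.nii").data[gm]
                for key in ("amplitude", "d_latent")
            }
        return SimulatedSubject(subject_id=sid, sessions=sessions, lesion_mask=lesion, truth=truth)

    controls = [read_subject(indir / "controls" / sid, sid, 1) for sid in manifest["controls"]]
    patients = [
        read_subject(indir / "patients" / sid, sid, manifest["n_sessions_patient"])
        for sid in manifest["patients"]
    ]
    clinical = pd.read_csv(indir / "clinical.tsv", sep="\t", index_col="subject_id")
    return Cohort(layout=layout, spec=spec, controls=controls, patients=patients, clinical=clinical)
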