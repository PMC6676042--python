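"""Synthetic cohort with a known latent gradient structure.

Controls and lesioned patients are simulated on a shared grey-matter voxel
grid. Each voxel carries G latent coordinates in [0, 1] that play the role
of ground-truth connectivity gradients: BOLD-like signal is a mixture of
source time series whose mixing weights fall off smoothly with latent
distance from each source's anchor, so functional connectivity decays
with latent distance and a spectral embedding of the resulting affinity
should recover the latent order. Patients additionally receive a focal
lesion and a longitudinal perturbation whose per-voxel amplitude decays
with distance from the lesion (in latent space, anatomical space, or not
at all), giving every downstream statistic a known truth to recover.

Nothing here models hemodynamics, scanner physics, motion, or
registration error; series are generated clean and co-registered.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .lesion import anatomical_distance


@dataclass
class LatentLayout:
    """Shared voxel grid plus per-voxel latent gradient coordinates.

    ``latent_coords`` has one row per grey-matter voxel (C-order of the
    mask) and G columns, each min-max normalised to [0, 1].
    ``anchor_points`` are the latent positions of the signal sources.
    """

    grid_dims: tuple
    voxel_size_mm: float
    gm_mask: np.ndarray
    latent_coords: np.ndarray
    anchor_points: np.ndarray
    voxel_ijk: np.ndarray = field(repr=False, default=None)
    latent_metric: str = "euclidean"  # euclidean | ring (wrap-around in [0,1])

    @property
    def n_voxels(self) -> int:
        return self.latent_coords.shape[0]

    @property
    def n_gradients(self) -> int:
        return self.latent_coords.shape[1]


@dataclass
class CohortSpec:
    """Generation parameters for one synthetic cohort.

    Defaults are the package's fixture-scale study conditions: 28 controls
    with one session each, 28 patients with three sessions of 120
    timepoints, signal-to-noise ratio 3, and a gradient-graded
    longitudinal perturbation of amplitude ``gamma * exp(-d/tau)`` with
    d the latent distance to the nearest lesioned voxel.
    """

    n_controls: int = 28
    n_patients: int = 28
    n_sessions: int = 3
    n_timepoints: int = 120
    n_sources: int = 10
    snr: float = 3.0
    perturbation_mode: str = "gradient"  # gradient | anatomical | uniform | none
    gamma: float = 0.8
    tau: float = 0.15  # latent units, for mode=gradient
    tau_mm: float = 9.0  # millimetres, for mode=anatomical
    source_width: float = 0.2  # sd of the Gaussian mixing bump, latent units
    lesion_placement: str = "extremes"  # extremes | uniform
    lesion_radius_range: tuple = (1, 2)
    clinical_noise_sd: float = 2.0
    seed: int = 0

    def __post_init__(self):
        if self.snr <= 0:
            raise ValueError("snr must be positive")
        if self.n_sessions < 2:
            raise ValueError("patients need at least 2 sessions")
        if self.gamma < 0:
            raise ValueError("gamma must be >= 0")
        if self.tau <= 0 or self.tau_mm <= 0:
            raise ValueError("decay scales must be positive")
        if self.perturbation_mode not in ("gradient", "anatomical", "uniform", "none"):
            raise ValueError(f"unknown perturbation_mode {self.perturbation_mode!r}")


@dataclass
class SimulatedSubject:
    """One simulated participant: sessions, optional lesion, and truth."""

    subject_id: str
    sessions: list
    lesion_mask: np.ndarray | None = None
    truth: dict | None = None


def _child_seed(seed_seq: np.random.SeedSequence) -> int:
    return int(seed_seq.generate_state(1)[0] % (2**31))


def make_latent_layout(
    grid_dims,
    G: int = 1,
    smoothness: float = 0.95,
    seed: int = 0,
    gm_mask: np.ndarray | None = None,
    field_type: str = "smooth",
    n_anchors: int = 10,
    voxel_size_mm: float = 3.0,
) -> LatentLayout:
    """Generate the latent gradient coordinates over a voxel grid.

    ``smooth`` fields are random low-order polynomials of the normalised
    grid coordinates plus small white noise, min-max scaled to [0, 1]:
    spatially smooth, so latent and anatomical distance are correlated but
    not identical. ``scrambled`` fields randomly permute an evenly spaced
    lattice of coordinates over the voxels, carrying no spatial structure
    at all: latent distance is then independent of anatomical distance by
    construction, which is the layout used for the anatomical-specificity
    control. (Spectral recovery of the latent order is unaffected —
    connectivity depends on latent distances only, never on voxel
    positions.) Scrambled layouts additionally use a wrap-around (ring)
    latent metric with evenly spaced anchors, so every voxel sees the
    identical multiset of latent distances: on a linear latent segment,
    voxels near the ends have systematically higher connectivity-profile
    variance than mid-segment voxels, which couples longitudinal
    concordance to gradient position through noise attenuation; the
    circular metric with lattice coordinates removes those edge effects
    exactly, as a specificity control requires.

    Anchors are placed by farthest-point sampling in latent space, which
    spreads the sources over the occupied latent range (extremes first).
    """
    grid_dims = tuple(int(d) for d in grid_dims)
    if len(grid_dims) != 3 or any(d < 4 for d in grid_dims):
        raise ValueError("grid_dims must be three integers, each >= 4")
    if not 1 <= G <= 3:
        raise ValueError("G must be in 1..3")
    if gm_mask is None:
        gm_mask = np.ones(grid_dims, dtype=bool)
    gm_mask = np.asarray(gm_mask, dtype=bool)
    if gm_mask.shape != grid_dims:
        raise ValueError("gm_mask shape does not match grid_dims")
    ijk = np.array(np.nonzero(gm_mask)).T
    if ijk.shape[0] < 50:
        raise ValueError(f"degenerate grid: only {ijk.shape[0]} masked voxels (need >= 50)")

    rng = np.random.default_rng(seed)
    norm = (ijk / (np.array(grid_dims) - 1)).T  # (3, N) in [0, 1]
    noise_sd = 0.02 + 0.5 * max(0.0, 1.0 - smoothness)
    coords = np.empty((ijk.shape[0], G))
    for g in range(G):
        if field_type == "smooth":
            lin = rng.normal(0, 1, 3)
            quad = rng.normal(0, 0.5, 6)
            x, y, z = norm
            f = (
                lin[0] * x + lin[1] * y + lin[2] * z
                + quad[0] * x * x + quad[1] * y * y + quad[2] * z * z
                + quad[3] * x * y + quad[4] * x * z + quad[5] * y * z
            )
            sd = f.std()
            if sd > 0:
                f = f / sd
        elif field_type == "scrambled":
            # exact uniform lattice, randomly assigned: no noise or rescaling,
            # so ring-stationarity holds exactly (no density dip at the wrap)
            n_vox = ijk.shape[0]
            coords[:, g] = (rng.permutation(n_vox) + 0.5) / n_vox
            continue
        else:
            raise ValueError(f"unknown field_type {field_type!r}")
        f = f + rng.normal(0, noise_sd, f.shape)
        f = f - f.min()
        ptp = f.max()
        coords[:, g] = f / ptp if ptp > 0 else 0.5

    metric = "ring" if field_type == "scrambled" else "euclidean"
    if metric == "ring" and G == 1:
        anchors = ((np.arange(n_anchors) + 0.5) / n_anchors)[:, None]
    else:
        anchors = _farthest_point_anchors(coords, n_anchors, metric)
    return LatentLayout(
        grid_dims=grid_dims,
        voxel_size_mm=float(voxel_size_mm),
        gm_mask=gm_mask,
        latent_coords=coords,
        anchor_points=anchors,
        voxel_ijk=ijk,
        latent_metric=metric,
    )


def latent_distances(a: np.ndarray, b: np.ndarray, metric: str = "euclidean") -> np.ndarray:
    """Pairwise latent-space distances between coordinate sets a and b."""
    diff = np.abs(a[:, None, :] - b[None, :, :])
    if metric == "ring":
        diff = np.minimum(diff, 1.0 - diff)
    elif metric != "euclidean":
        raise ValueError(f"unknown latent metric {metric!r}")
    return np.sqrt((diff**2).sum(axis=2))


def _farthest_point_anchors(coords: np.ndarray, n_anchors: int, metric: str = "euclidean") -> np.ndarray:
    """Deterministic farthest-point sampling of anchor positions."""
    start = int(np.argmin(coords[:, 0]))
    chosen = [start]
    d = latent_distances(coords, coords[[start]], metric)[:, 0]
    for _ in range(1, min(n_anchors, coords.shape[0])):
        nxt = int(np.argmax(d))
        chosen.append(nxt)
        d = np.minimum(d, latent_distances(coords, coords[[nxt]], metric)[:, 0])
    return coords[chosen].copy()


def source_weights(layout: LatentLayout, spec: CohortSpec) -> np.ndarray:
    """Gaussian-bump mixing weights: voxels near an anchor load on its source."""
    anchors = layout.anchor_points[: spec.n_sources]
    if anchors.shape[0] < spec.n_sources:
        raise ValueError("layout has fewer anchors than spec.n_sources")
    d = latent_distances(layout.latent_coords, anchors, layout.latent_metric)
    return np.exp(-(d**2) / (2.0 * spec.source_width**2))


def _bold_from_weights(weights: np.ndarray, spec: CohortSpec, rng: np.random.Generator) -> np.ndarray:
    V = weights.shape[0]
    T = spec.n_timepoints
    sources = rng.standard_normal((weights.shape[1], T))
    noise = rng.standard_normal((V, T))
    sig = weights @ sources
    sd = sig.std(axis=1, keepdims=True)
    np.divide(sig, sd, out=sig, where=sd > 0)
    if np.isfinite(spec.snr):
        y = sig + noise / np.sqrt(spec.snr)
    else:
        y = sig
    sd = y.std(axis=1, keepdims=True)
    if np.any(sd == 0):
        raise ValueError("zero-variance voxel series generated (all-zero weights at infinite snr?)")
    return (y - y.mean(axis=1, keepdims=True)) / sd


def simulate_bold(layout: LatentLayout, spec: CohortSpec, seed: int, weights: np.ndarray | None = None) -> np.ndarray:
    """One session of standardised voxel time series (V x T).

    Signal is a weighted sum of shared source series plus white noise at
    the requested snr (signal variance / noise variance); every voxel row
    is returned with zero mean and unit variance, so Pearson correlation
    is a scaled dot product.
    """
    if spec.n_sources < 1:
        raise ValueError("need at least one source")
    if spec.n_timepoints < 30:
        raise ValueError("need at least 30 timepoints")
    if weights is None:
        weights = source_weights(layout, spec)
    rng = np.random.default_rng(seed)
    return _bold_from_weights(weights, spec, rng)


def make_lesion(layout: LatentLayout, center_voxel, radius_vox: float) -> np.ndarray:
    """Spherical lesion: lattice points within ``radius_vox`` of the centre.

    The ball is intersected with the grey-matter mask. Radius 0 gives the
    single centre voxel.
    """
    center = tuple(int(c) for c in center_voxel)
    dims = layout.grid_dims
    if any(not 0 <= c < d for c, d in zip(center, dims)):
        raise ValueError(f"lesion centre {center} lies outside the grid {dims}")
    if not layout.gm_mask[center]:
        raise ValueError(f"lesion centre {center} is outside grey matter")
    if radius_vox < 0:
        raise ValueError("radius must be >= 0")
    grid = np.indices(dims)
    d2 = sum((grid[a] - center[a]) ** 2 for a in range(3))
    return (d2 <= radius_vox**2) & layout.gm_mask


def latent_distance_to_lesion(layout: LatentLayout, lesion_mask: np.ndarray) -> np.ndarray:
    """Per grey-matter voxel, latent-space distance to the nearest lesioned voxel."""
    lesion_rows = lesion_mask[layout.gm_mask]
    if not lesion_rows.any():
        raise ValueError("lesion does not intersect grey matter")
    les = layout.latent_coords[lesion_rows]
    d = latent_distances(layout.latent_coords, les, layout.latent_metric)
    return d.min(axis=1)


def perturbation_amplitude(layout: LatentLayout, spec: CohortSpec, lesion_mask: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Ground-truth per-voxel perturbation amplitude and latent lesion distance."""
    d_lat = latent_distance_to_lesion(layout, lesion_mask)
    if spec.perturbation_mode == "gradient":
        amp = spec.gamma * np.exp(-d_lat / spec.tau)
    elif spec.perturbation_mode == "anatomical":
        d_mm = anatomical_distance(lesion_mask, layout.voxel_size_mm)[layout.gm_mask]
        amp = spec.gamma * np.exp(-d_mm / spec.tau_mm)
    elif spec.perturbation_mode == "uniform":
        amp = np.full(layout.n_voxels, spec.gamma)
    else:  # none
        amp = np.zeros(layout.n_voxels)
    return amp, d_lat


def apply_perturbation(subject: SimulatedSubject, layout: LatentLayout, spec: CohortSpec, seed: int) -> SimulatedSubject:
    """Fill a lesioned subject's sessions with perturbed time series.

    Each session re-draws source series and noise from the same
    generative parameters; on top of that, the mixing weights of voxel v
    receive session-specific Gaussian jitter with standard deviation
    ``amplitude(v)`` times the voxel's base weight scale, so the
    connectivity profile of strongly perturbed voxels drifts between
    sessions. Lesioned voxels' series are replaced by pure noise in every
    session. The per-voxel amplitude field and latent lesion distance are
    stored in ``subject.truth``.
    """
    if subject.lesion_mask is None or not subject.lesion_mask.any():
        raise ValueError("apply_perturbation requires a subject with a lesion")
    if spec.perturbation_mode == "none":
        warnings.warn("perturbation_mode='none' on a patient: sessions are plain re-draws")
    amp, d_lat = perturbation_amplitude(layout, spec, subject.lesion_mask)
    base = source_weights(layout, spec)
    scale = np.sqrt((base**2).mean(axis=1))  # per-voxel weight rms
    lesion_rows = subject.lesion_mask[layout.gm_mask]
    rng = np.random.default_rng(seed)
    sessions = []
    for _ in range(spec.n_sessions):
        jitter = rng.standard_normal(base.shape)
        w = base + (amp * scale)[:, None] * jitter
        ts = _bold_from_weights(w, spec, rng)
        n_les = int(lesion_rows.sum())
        pure = rng.standard_normal((n_les, spec.n_timepoints))
        pure = (pure - pure.mean(axis=1, keepdims=True)) / pure.std(axis=1, keepdims=True)
        ts[lesion_rows] = pure
        sessions.append(ts)
    subject.sessions = sessions
    subject.truth = {"amplitude": amp, "d_latent": d_lat}
    return subject


def simulate_clinical(patient_truths, noise_sd: float = 2.0, seed: int = 0, ids=None) -> pd.DataFrame:
    """Integer clinical scores from per-patient truth summaries.

    Discharge (day 5) scores are a monotone map of the truth summary
    (min-max scaled perturbation concentration) plus Gaussian noise,
    rounded and clipped to the valid ranges (NIHSS 0-42, mRS 0-5).
    Admission (day 0) scores add a non-negative integer improvement
    margin, so a subset of patients changes between admission and
    discharge.
    """
    t = np.asarray(patient_truths, dtype=float)
    n = t.size
    ptp = np.ptp(t)
    tn = (t - t.min()) / ptp if ptp > 0 else np.zeros(n)
    rng = np.random.default_rng(seed)
    nihss5 = np.clip(np.rint(2 + 25 * tn + rng.normal(0, noise_sd, n)), 0, 42).astype(int)
    nihss0 = np.clip(nihss5 + rng.poisson(0.9, n), 0, 42).astype(int)
    mrs5 = np.clip(np.rint(0.5 + 4 * tn + rng.normal(0, noise_sd * 5 / 42, n)), 0, 5).astype(int)
    mrs0 = np.clip(mrs5 + rng.poisson(0.5, n), 0, 5).astype(int)
    if ids is None:
        ids = [f"pat-{i:02d}" for i in range(n)]
    return pd.DataFrame(
        {
            "nihss_day0": nihss0,
            "nihss_day5": nihss5,
            "mrs_day0": mrs0,
            "mrs_day5": mrs5,
        },
        index=pd.Index(ids, name="subject_id"),
    )


@dataclass
class Cohort:
    """A full simulated study: layout, controls, patients, clinical table."""

    layout: LatentLayout
    spec: CohortSpec
    controls: list
    patients: list
    clinical: pd.DataFrame


def _pick_lesion(layout: LatentLayout, spec: CohortSpec, rng: np.random.Generator) -> np.ndarray:
    """Draw a lesion centre and radius; centres default to latent extremes."""
    coords = layout.latent_coords
    if spec.lesion_placement == "extremes":
        ext = np.abs(coords - 0.5).max(axis=1)
        candidates = np.flatnonzero(ext >= np.quantile(ext, 0.8))
    elif spec.lesion_placement == "uniform":
        candidates = np.arange(layout.n_voxels)
    else:
        raise ValueError(f"unknown lesion_placement {spec.lesion_placement!r}")
    lo, hi = spec.lesion_radius_range
    max_frac = 0.2
    for _ in range(20):
        row = int(rng.choice(candidates))
        center = tuple(layout.voxel_ijk[row])
        radius = int(rng.integers(lo, hi + 1))
        mask = make_lesion(layout, center, radius)
        if 0 < mask.sum() <= max_frac * layout.n_voxels:
            return mask
    raise RuntimeError("could not place a lesion within the size budget")


def simulate_cohort(
    spec: CohortSpec | None = None,
    seed: int | None = None,
    layout: LatentLayout | None = None,
    grid_dims=(10, 10, 8),
    G: int = 1,
    field_type: str = "smooth",
) -> Cohort:
    """Generate a complete cohort: controls, lesioned patients, clinical scores.

    All randomness derives from a single seed via spawned child streams,
    so identical (spec, seed) pairs give byte-identical cohorts. The
    per-patient truth summary feeding the clinical scores is the mean
    perturbation amplitude over intact grey-matter voxels.
    """
    spec = spec or CohortSpec()
    if seed is None:
        seed = spec.seed
    ss = np.random.SeedSequence(seed)
    kids = ss.spawn(2 + spec.n_controls + 2 * spec.n_patients)
    it = iter(kids)
    if layout is None:
        layout = make_latent_layout(grid_dims, G=G, seed=_child_seed(next(it)), field_type=field_type)
    else:
        next(it)

    controls = []
    for i in range(spec.n_controls):
        ts = simulate_bold(layout, spec, seed=_child_seed(next(it)))
        controls.append(SimulatedSubject(subject_id=f"ctrl-{i:02d}", sessions=[ts]))

    patients = []
    for i in range(spec.n_patients):
        lesion_rng = np.random.default_rng(_child_seed(next(it)))
        mask = _pick_lesion(layout, spec, lesion_rng)
        subj = SimulatedSubject(subject_id=f"pat-{i:02d}", sessions=[], lesion_mask=mask)
        apply_perturbation(subj, layout, spec, seed=_child_seed(next(it)))
        patients.append(subj)

    if patients:
        summaries = [
            float(p.truth["amplitude"][~p.lesion_mask[layout.gm_mask]].mean()) for p in patients
        ]
        clinical = simulate_clinical(
            summaries,
            noise_sd=spec.clinical_noise_sd,
            seed=_child_seed(next(it)),
            ids=[p.subject_id for p in patients],
        )
    else:
        clinical = pd.DataFrame(
            columns=["nihss_day0", "nihss_day5", "mrs_day0", "mrs_day5"],
            index=pd.Index([], name="subject_id"),
        )
    return Cohort(layout=layout, spec=spec, controls=controls, patients=patients, clinical=clinical)
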