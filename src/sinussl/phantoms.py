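"""Synthetic sinus phantoms with ground-truth lesion masks.

A phantom is a cube of brighter soft tissue containing a roughly ellipsoidal
dark air cavity wrapped in a thin, slightly brighter mucosal lining.
Anomalous phantoms add one lesion: a bright blob attached to the lining and
protruding into the cavity (polyp/cyst-like), or a locally thickened lining
shell (mucosal thickening). Geometry and noise are pure functions of the
seed, so every downstream stage is reproducible and testable without any
clinical data.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .preprocess import ANOMALOUS, NORMAL, MSVolume, save_manifest, save_volume

LESION_TYPES = ("polyp_like", "cyst_like", "mucosal_thickening")


@dataclass
class PhantomParams:
    """Geometry, contrast and noise settings for one phantom draw.

    Lengths are in voxels; intensities are dimensionless in [0, 1]. Semi-axes
    and the lesion radius scale with ``cube_edge`` in the defaults so the same
    morphology is obtained at 16, 32 or 64 voxels per edge.
    """

    cube_edge: int = 32
    cavity_semi_axes: tuple[float, float, float] | None = None
    lining_thickness: float = 1.5
    tissue_intensity: float = 0.65
    air_intensity: float = 0.05
    lining_intensity: float = 0.45
    lesion_intensity: float = 0.85
    noise_sd: float = 0.03
    lesion_radius_range: tuple[float, float] | None = None
    thickening_extra: float = 2.5
    lesion_type: str = "polyp_like"
    jitter: float = 0.06
    seed: int = 0

    def __post_init__(self):
        e = self.cube_edge
        if self.cavity_semi_axes is None:
            self.cavity_semi_axes = (0.30 * e, 0.26 * e, 0.28 * e)
        if self.lesion_radius_range is None:
            self.lesion_radius_range = (0.12 * e, 0.18 * e)
        for name in ("tissue_intensity", "air_intensity", "lining_intensity",
                     "lesion_intensity"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.lesion_type not in LESION_TYPES:
            raise ValueError(f"lesion_type must be one of {LESION_TYPES}")
        margin = max(self.cavity_semi_axes) + self.lining_thickness + 1.0
        if margin >= e / 2:
            raise ValueError(
                f"cavity (max semi-axis {max(self.cavity_semi_axes):.1f} + lining) "
                f"does not fit strictly inside a {e}-voxel cube")


@dataclass
class PhantomSample:
    volume: MSVolume
    lesion_mask: np.ndarray
    label: str
    params: PhantomParams = field(repr=False, default=None)

    def __post_init__(self):
        has_lesion = bool(np.any(self.lesion_mask))
        if (self.label == ANOMALOUS) != has_lesion:
            raise ValueError("label and lesion mask disagree")


def _grids(edge: int):
    ax = np.arange(edge, dtype=np.float64)
    return np.meshgrid(ax, ax, ax, indexing="ij")


def _geometry(params: PhantomParams, rng: np.random.Generator):
    """Jittered cavity ellipsoid: center, semi-axes and the normalized
    ellipsoidal radius field rho (rho < 1 inside the cavity)."""
    e = params.cube_edge
    center = e / 2 - 0.5 + rng.uniform(-params.jitter * e, params.jitter * e, size=3)
    semi = np.array(params.cavity_semi_axes) * rng.uniform(1 - params.jitter,
                                                           1 + params.jitter, size=3)
    ii, jj, kk = _grids(e)
    rho = np.sqrt(((ii - center[0]) / semi[0]) ** 2 +
                  ((jj - center[1]) / semi[1]) ** 2 +
                  ((kk - center[2]) / semi[2]) ** 2)
    return center, semi, rho


def _lining_outer_rho(params: PhantomParams, semi: np.ndarray) -> float:
    return 1.0 + params.lining_thickness / float(np.mean(semi))


def _compose(params: PhantomParams, rho: np.ndarray, lining_outer: float,
             rng: np.random.Generator) -> np.ndarray:
    vol = np.full(rho.shape, params.tissue_intensity)
    vol[rho < lining_outer] = params.lining_intensity
    vol[rho < 1.0] = params.air_intensity
    if params.noise_sd > 0:
        vol = vol + rng.normal(0.0, params.noise_sd, size=vol.shape)
    return np.clip(vol, 0.0, 1.0)


def generate_normal_volume(params: PhantomParams) -> PhantomSample:
    """A lesion-free phantom; identical seeds give bit-identical volumes."""
    rng = np.random.default_rng(params.seed)
    _, semi, rho = _geometry(params, rng)
    vol = _compose(params, rho, _lining_outer_rho(params, semi), rng)
    ms = MSVolume(data=vol, patient_id=f"phantom{params.seed:06d}", label=NORMAL)
    return PhantomSample(volume=ms, lesion_mask=np.zeros(vol.shape, dtype=np.uint8),
                         label=NORMAL, params=params)


def _place_blob(params: PhantomParams, center, semi, rho, rng):
    """Bright sphere attached to the lining, protruding into the cavity."""
    e = params.cube_edge
    radius = rng.uniform(*params.lesion_radius_range)
    direction = rng.normal(size=3)
    direction /= np.linalg.norm(direction)
    # anchor the blob centre just inside the cavity wall so it stays attached
    wall = center + direction * semi * 0.98
    blob_center = wall - direction * radius * 0.6
    ii, jj, kk = _grids(e)
    dist = np.sqrt((ii - blob_center[0]) ** 2 + (jj - blob_center[1]) ** 2 +
                   (kk - blob_center[2]) ** 2)
    mask = (dist < radius) & (rho < 1.0)
    if not mask.any():
        raise ValueError("lesion could not be placed inside the cavity")
    return mask


def _place_thickening(params: PhantomParams, center, semi, rho, rng):
    """Locally thickened lining: an inward shell on one side of the cavity."""
    e = params.cube_edge
    direction = rng.normal(size=3)
    direction /= np.linalg.norm(direction)
    ii, jj, kk = _grids(e)
    vec = np.stack([(ii - center[0]) / semi[0], (jj - center[1]) / semi[1],
                    (kk - center[2]) / semi[2]])
    norm = np.sqrt((vec ** 2).sum(axis=0)) + 1e-12
    cosang = (vec[0] * direction[0] + vec[1] * direction[1] +
              vec[2] * direction[2]) / norm
    extra = params.thickening_extra / float(np.mean(semi))
    inner = 1.0 - extra
    mask = (rho >= inner) & (rho < 1.0) & (cosang > 0.3)
    if not mask.any():
        raise ValueError("thickening region is empty; increase thickening_extra")
    return mask


def generate_anomalous_volume(params: PhantomParams) -> PhantomSample:
    """Same construction as the normal phantom of this seed plus one lesion.

    The geometry and noise random draws are shared with
    :func:`generate_normal_volume`, so erasing the lesion voxels recovers the
    normal phantom of the same seed up to the noise on those voxels.
    """
    rng = np.random.default_rng(params.seed)
    center, semi, rho = _geometry(params, rng)
    lesion_rng = np.random.default_rng((params.seed, 0xA27))
    if params.lesion_type == "mucosal_thickening":
        mask = _place_thickening(params, center, semi, rho, lesion_rng)
    else:
        mask = _place_blob(params, center, semi, rho, lesion_rng)
    vol = np.full(rho.shape, params.tissue_intensity)
    vol[rho < _lining_outer_rho(params, semi)] = params.lining_intensity
    vol[rho < 1.0] = params.air_intensity
    vol[mask] = params.lesion_intensity
    if params.noise_sd > 0:
        vol = vol + rng.normal(0.0, params.noise_sd, size=vol.shape)
    vol = np.clip(vol, 0.0, 1.0)
    ms = MSVolume(data=vol, patient_id=f"phantom{params.seed:06d}", label=ANOMALOUS)
    return PhantomSample(volume=ms, lesion_mask=mask.astype(np.uint8),
                         label=ANOMALOUS, params=params)


def _draw_sample(seed: int, params: PhantomParams, anomalous: bool,
                 rng: np.random.Generator) -> PhantomSample:
    p = replace(params, seed=seed)
    if anomalous:
        p = replace(p, lesion_type=LESION_TYPES[rng.integers(len(LESION_TYPES))])
        return generate_anomalous_volume(p)
    return generate_normal_volume(p)


def generate_dataset(n_normal: int, n_anomalous: int, n_unlabelled: int,
                     anomaly_rate_unlabelled: float = 0.5, seed: int = 0,
                     params: PhantomParams | None = None,
                     out_dir: Path | str | None = None,
                     ) -> tuple[list[PhantomSample], list[MSVolume], list[np.ndarray]]:
    """Draw a labelled set and an unlabelled pool of phantoms.

    Returns ``(labelled, unlabelled, hidden_masks)``. Hidden masks parallel
    the unlabelled pool and exist for evaluation only; unlabelled volumes
    carry ``label=None``. Each sample gets a unique synthetic patient id.
    When ``out_dir`` is given, volumes/masks are written as NIfTI and
    ``labelled.csv`` / ``unlabelled.csv`` manifests are produced.
    """
    if min(n_normal, n_anomalous, n_unlabelled) < 0:
        raise ValueError("counts must be non-negative")
    if not (0.0 <= anomaly_rate_unlabelled <= 1.0):
        raise ValueError("anomaly_rate_unlabelled must lie in [0, 1]")
    if params is None:
        params = PhantomParams()
    rng = np.random.default_rng(seed)
    base = (seed % 1_000_000) * 1_000 if seed >= 0 else 0

    labelled: list[PhantomSample] = []
    for i in range(n_normal):
        labelled.append(_draw_sample(base + i, params, False, rng))
    for i in range(n_anomalous):
        labelled.append(_draw_sample(base + n_normal + i, params, True, rng))

    unlabelled: list[MSVolume] = []
    hidden_masks: list[np.ndarray] = []
    offset = base + n_normal + n_anomalous
    anomalous_flags = rng.random(n_unlabelled) < anomaly_rate_unlabelled
    for i in range(n_unlabelled):
        sample = _draw_sample(offset + i, params, bool(anomalous_flags[i]), rng)
        unlabelled.append(replace(sample.volume, label=None))
        hidden_masks.append(sample.lesion_mask)

    if out_dir is not None:
        _write_dataset(Path(out_dir), labelled, unlabelled, hidden_masks)
    return labelled, unlabelled, hidden_masks


def _write_dataset(out_dir: Path, labelled, unlabelled, hidden_masks) -> None:
    rows = []
    for s in labelled:
        rel = f"labelled/{s.volume.uid}.nii.gz"
        save_volume(out_dir / rel, s.volume.data)
        save_volume(out_dir / f"labelled/{s.volume.uid}_mask.nii.gz",
                    s.lesion_mask.astype(np.int16))
        rows.append({"path": rel, "patient_id": s.volume.patient_id,
                     "side": s.volume.side, "label": s.label})
    save_manifest(out_dir / "labelled.csv", rows)
    rows = []
    for v, mask in zip(unlabelled, hidden_masks):
        rel = f"unlabelled/{v.uid}.nii.gz"
        save_volume(out_dir / rel, v.data)
        save_volume(out_dir / f"hidden_masks/{v.uid}_mask.nii.gz",
                    mask.astype(np.int16))
        rows.append({"path": rel, "patient_id": v.patient_id,
                     "side": v.side, "label": ""})
    save_manifest(out_dir / "unlabelled.csv", rows)
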