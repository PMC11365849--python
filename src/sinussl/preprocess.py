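"""Volume I/O and preprocessing: centroid crops, laterality, normalization,
patient-grouped cross-validation splits and label-fraction subsets.

The conventions mirror a typical maxillary-sinus (MS) extraction pipeline:
a fixed mean centroid located on a template-aligned cranial scan defines an
axis-aligned cube crop per side; right-side crops are mirrored onto the left
so one model sees a single laterality; intensities are min-max scaled per
volume to [0, 1].
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold

NORMAL = "normal"
ANOMALOUS = "anomalous"

#: Axis of the cube treated as the left-right (horizontal) axis when
#: mirroring right-side volumes. Axis 0 by convention; configurable at the
#: call site for data in other orientations.
LATERAL_AXIS = 0


@dataclass
class MSVolume:
    """A cubic maxillary-sinus volume with intensities in [0, 1]."""

    data: np.ndarray
    patient_id: str
    side: str = "left"
    label: str | None = None

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3 or len(set(self.data.shape)) != 1:
            raise ValueError(f"MSVolume data must be a cube, got shape {self.data.shape}")
        if self.side not in ("left", "right"):
            raise ValueError(f"side must be 'left' or 'right', got {self.side!r}")
        if self.label not in (None, NORMAL, ANOMALOUS):
            raise ValueError(f"label must be normal/anomalous/None, got {self.label!r}")

    @property
    def edge(self) -> int:
        return self.data.shape[0]

    @property
    def uid(self) -> str:
        return f"{self.patient_id}_{self.side}"


@dataclass
class Centroid:
    i: int
    j: int
    k: int

    def as_tuple(self) -> tuple[int, int, int]:
        return (self.i, self.j, self.k)


@dataclass
class DatasetSplit:
    """Patient-grouped train/validation/test partition plus unlabelled pool."""

    train: list[MSVolume]
    validation: list[MSVolume]
    test: list[MSVolume]
    unlabelled: list[MSVolume] = field(default_factory=list)

    @property
    def normal_train_subset(self) -> list[MSVolume]:
        return [v for v in self.train if v.label == NORMAL]

    def check_patient_disjoint(self) -> None:
        groups = [self.train, self.validation, self.test]
        seen: dict[str, int] = {}
        for gi, group in enumerate(groups):
            for v in group:
                if v.patient_id in seen and seen[v.patient_id] != gi:
                    raise ValueError(
                        f"patient {v.patient_id} appears in more than one partition")
                seen[v.patient_id] = gi


# ---------------------------------------------------------------------------
# operations

def _round_half_away(x: float) -> int:
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def mean_centroid(centroids: list[Centroid]) -> Centroid:
    """Component-wise mean, rounded to the nearest voxel (ties away from zero)."""
    if not centroids:
        raise ValueError("mean_centroid requires at least one centroid")
    arr = np.array([c.as_tuple() for c in centroids], dtype=float)
    means = arr.mean(axis=0)
    return Centroid(*(_round_half_away(m) for m in means))


def extract_ms_volume(cranial: np.ndarray, centroid: Centroid, edge: int,
                      side: str, patient_id: str = "") -> MSVolume:
    """Crop the half-open cube [c - edge//2, c + edge - edge//2) around the centroid.

    Raises an out-of-bounds error rather than clamping or padding: a silently
    shifted crop would feed the normal model corrupted anatomy.
    """
    cranial = np.asarray(cranial)
    half = edge // 2
    starts = [c - half for c in centroid.as_tuple()]
    for ax, start in enumerate(starts):
        if start < 0 or start + edge > cranial.shape[ax]:
            raise IndexError(
                f"crop [{start}, {start + edge}) exceeds axis {ax} of size "
                f"{cranial.shape[ax]}")
    i, j, k = starts
    cube = cranial[i:i + edge, j:j + edge, k:k + edge].copy()
    return MSVolume(data=cube, patient_id=patient_id, side=side)


def flip_lateral(volume: MSVolume, axis: int = LATERAL_AXIS) -> MSVolume:
    """Mirror the left-right axis and relabel the side as left."""
    return replace(volume, data=np.flip(volume.data, axis=axis).copy(), side="left")


def normalize_intensity(data: np.ndarray) -> np.ndarray:
    """Per-volume min-max scaling to [0, 1]; a constant volume maps to zeros."""
    data = np.asarray(data, dtype=np.float64)
    if not np.all(np.isfinite(data)):
        raise ValueError("volume contains NaN or Inf")
    lo, hi = data.min(), data.max()
    if hi == lo:
        return np.zeros_like(data)
    return (data - lo) / (hi - lo)


def stratified_fraction(labelled: list[MSVolume], fraction: float,
                        seed: int) -> list[MSVolume]:
    """Class-stratified subsample of round-half-up(fraction * n_class) per class.

    Volumes are grouped by patient within each class and patients are drawn in
    a seeded random order, so subsets are nested across fractions for a fixed
    seed and a patient's same-class volumes stay adjacent in the draw.
    """
    if not (0.0 < fraction <= 1.0):
        raise ValueError(f"fraction must be in (0, 1], got {fraction}")
    if fraction == 1.0:
        return list(labelled)
    by_class: dict[str, list[MSVolume]] = {}
    for v in labelled:
        if v.label is None:
            raise ValueError(f"volume {v.uid} has no label")
        by_class.setdefault(v.label, []).append(v)
    if len(by_class) < 2:
        raise ValueError("both classes must be present when fraction < 1")
    rng = np.random.default_rng(seed)
    out: list[MSVolume] = []
    for cls in sorted(by_class):
        vols = by_class[cls]
        patients = sorted({v.patient_id for v in vols})
        order = rng.permutation(len(patients))
        flat: list[MSVolume] = []
        for idx in order:
            pid = patients[idx]
            flat.extend(v for v in vols if v.patient_id == pid)
        m = _round_half_away(fraction * len(vols))
        out.extend(flat[:m])
    return out


def make_cv_folds(labelled: list[MSVolume], k: int, seed: int) -> list[DatasetSplit]:
    """K patient-grouped splits stratified by patient-level label.

    A patient is stratified as anomalous if any of their MS volumes is
    anomalous. Split ``i`` uses fold ``i`` as test, fold ``i+1 (mod k)`` as
    validation and the rest as train; every patient's volumes land together.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    by_patient: dict[str, list[MSVolume]] = {}
    for v in labelled:
        by_patient.setdefault(v.patient_id, []).append(v)
    patients = sorted(by_patient)
    if len(patients) < k:
        raise ValueError(f"need at least {k} patients, got {len(patients)}")
    patient_label = np.array(
        [int(any(v.label == ANOMALOUS for v in by_patient[p])) for p in patients])
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    folds = [test_idx for _, test_idx in skf.split(np.zeros(len(patients)), patient_label)]
    splits: list[DatasetSplit] = []
    for i in range(k):
        test_p = {patients[t] for t in folds[i]}
        val_p = {patients[t] for t in folds[(i + 1) % k]}
        train_p = set(patients) - test_p - val_p
        def collect(pset):
            return [v for p in sorted(pset) for v in by_patient[p]]
        split = DatasetSplit(train=collect(train_p), validation=collect(val_p),
                             test=collect(test_p))
        split.check_patient_disjoint()
        splits.append(split)
    return splits


# ---------------------------------------------------------------------------
# NIfTI + manifest I/O

def save_volume(path: Path | str, data: np.ndarray) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    nib.save(nib.Nifti1Image(np.asarray(data, dtype=np.float32), affine=np.eye(4)), path)


def load_volume(path: Path | str) -> np.ndarray:
    return np.asarray(nib.load(str(path)).get_fdata(), dtype=np.float64)


def save_manifest(path: Path | str, rows: list[dict]) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(rows).to_csv(path, index=False)


def load_manifest(path: Path | str) -> pd.DataFrame:
    return pd.read_csv(path, dtype={"patient_id": str})


def load_volumes_from_manifest(manifest: pd.DataFrame,
                               root: Path | str | None = None) -> list[MSVolume]:
    root = Path(root) if root is not None else None
    volumes = []
    for row in manifest.itertuples(index=False):
        p = Path(row.path)
        if root is not None and not p.is_absolute():
            p = root / p
        label = getattr(row, "label", None)
        if isinstance(label, float) and math.isnan(label):
            label = None
        volumes.append(MSVolume(data=load_volume(p), patient_id=str(row.patient_id),
                                side=getattr(row, "side", "left"), label=label))
    return volumes
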