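"""Per-structure geometry: volumes, centroids and thalamus-referenced metrics.

Each labelled structure is treated as a cloud of voxel centres in RAS
(right-anterior-superior) millimetre space.  Its centroid is the unweighted
mean of those points and its volume is the voxel count times the voxel
volume.  Every non-reference structure then contributes three features:

* ``normvol`` — structure volume divided by the subject's (bilateral)
  thalamus volume, controlling head-size variability;
* ``euclid`` — Euclidean (Minkowski ``p=2``) distance in mm between the
  structure centroid and the thalamus centroid;
* ``cosine`` — cosine distance between the two centroids taken as position
  vectors from a configurable origin (native RAS origin by default).
  The cosine distance is orientation-only and lies in ``[0, 2]``; it is 0
  for identical directions and 2 for diametrically opposed ones.  Because
  it depends on the origin, translating a whole volume changes the cosine
  features while leaving the Euclidean ones untouched.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Sequence

import numpy as np
import pandas as pd

from .registry import StructureRegistry, default_registry, feature_columns
from .volume import LabeledVolume


class MissingStructureError(ValueError):
    """A registry structure has no voxels in the volume."""


@dataclass(frozen=True)
class Point3:
    """A point (or position vector) in RAS millimetre space."""

    x: float
    y: float
    z: float

    def as_array(self) -> np.ndarray:
        return np.array([self.x, self.y, self.z], dtype=float)

    @staticmethod
    def from_array(a: Sequence[float]) -> "Point3":
        x, y, z = (float(v) for v in a)
        if not (np.isfinite(x) and np.isfinite(y) and np.isfinite(z)):
            raise ValueError("point components must be finite")
        return Point3(x, y, z)


@dataclass(frozen=True)
class StructureGeometry:
    """Measured volume and centroid of one structure."""

    name: str
    n_voxels: int
    volume_mm3: float
    centroid: Point3


@dataclass
class SubjectFeatures:
    """All features of one subject: reference volume, per-structure metrics, demographics."""

    subject_id: str
    group: str
    sex: int  # M=0, F=1
    age: float
    thalamus_volume: float
    norm_volume: Dict[str, float] = field(default_factory=dict)
    euclidean_mm: Dict[str, float] = field(default_factory=dict)
    cosine: Dict[str, float] = field(default_factory=dict)


def voxel_to_ras(volume: LabeledVolume, index: Sequence[int]) -> Point3:
    """Map a voxel index to RAS mm via the volume affine (homogeneous coordinate 1)."""
    idx = np.asarray(index, dtype=float)
    if idx.shape != (3,):
        raise ValueError("index must have three components")
    shape = volume.labels.shape
    if np.any(idx < 0) or np.any(idx >= shape):
        raise IndexError(f"index {tuple(index)} outside grid {shape}")
    hom = np.append(idx, 1.0)
    out = volume.affine @ hom
    return Point3.from_array(out[:3])


def minkowski_distance(a: Point3 | Sequence[float], b: Point3 | Sequence[float], p: float = 2.0) -> float:
    """Minkowski distance of order ``p`` >= 1; ``p=2`` is the Euclidean distance."""
    if p < 1:
        raise ValueError(f"Minkowski order must be >= 1, got {p}")
    av = a.as_array() if isinstance(a, Point3) else np.asarray(a, dtype=float)
    bv = b.as_array() if isinstance(b, Point3) else np.asarray(b, dtype=float)
    return float(np.sum(np.abs(av - bv) ** p) ** (1.0 / p))


def euclidean_distance(a: Point3 | Sequence[float], b: Point3 | Sequence[float]) -> float:
    return minkowski_distance(a, b, p=2.0)


def cosine_distance(a: Point3 | Sequence[float], b: Point3 | Sequence[float]) -> float:
    """1 minus the cosine of the angle between two vectors; range [0, 2].

    Invariant to positive rescaling of either argument.  Raises on a
    zero-norm input (direction undefined).  Results within 1e-12 of the
    exact bounds are snapped to 0 or 2 to absorb floating-point rounding.
    """
    av = a.as_array() if isinstance(a, Point3) else np.asarray(a, dtype=float)
    bv = b.as_array() if isinstance(b, Point3) else np.asarray(b, dtype=float)
    na = float(np.linalg.norm(av))
    nb = float(np.linalg.norm(bv))
    if na == 0.0 or nb == 0.0:
        raise ValueError("cosine distance undefined for a zero-norm vector")
    sim = float(np.dot(av, bv)) / (na * nb)
    dist = 1.0 - min(1.0, max(-1.0, sim))
    if dist < 1e-12:
        return 0.0
    if dist > 2.0 - 1e-12:
        return 2.0
    return dist


def measure_structure(
    volume: LabeledVolume,
    name: str,
    registry: StructureRegistry | None = None,
) -> StructureGeometry:
    """Volume and centroid of one registry structure.

    Voxels carrying any of the structure's label codes are pooled into a
    single cloud (merged labels such as the bilateral thalamus therefore
    yield one centroid near the midline).
    """
    reg = registry if registry is not None else default_registry()
    if name not in reg:
        raise KeyError(f"structure {name!r} not in registry")
    codes = reg.codes(name)
    mask = np.isin(volume.labels, list(codes))
    n = int(mask.sum())
    if n == 0:
        raise MissingStructureError(f"structure {name!r} has no voxels in volume")
    idx = np.argwhere(mask).astype(float)  # (n, 3) voxel-centre indices
    hom = np.hstack([idx, np.ones((n, 1))])
    ras = hom @ volume.affine.T  # (n, 4)
    centroid = Point3.from_array(ras[:, :3].mean(axis=0))
    return StructureGeometry(
        name=name,
        n_voxels=n,
        volume_mm3=n * volume.voxel_volume,
        centroid=centroid,
    )


def extract_subject_features(
    volume: LabeledVolume,
    demographics: Mapping[str, object],
    registry: StructureRegistry | None = None,
    origin: Sequence[float] = (0.0, 0.0, 0.0),
    distance_norm: bool = False,
) -> SubjectFeatures:
    """Measure every registry structure and derive the per-subject features.

    Parameters
    ----------
    demographics :
        Mapping with keys ``subject_id``, ``group``, ``sex`` (M=0/F=1)
        and ``age``.
    origin :
        Origin of the position vectors used for the cosine distance
        (native RAS origin by default; the cosine metric is
        origin-dependent).
    distance_norm :
        If True, Euclidean distances are divided by the cube root of the
        thalamus volume (a head-size rescaling); off by default — raw mm
        are reported.
    """
    reg = registry if registry is not None else default_registry()
    geoms = {name: measure_structure(volume, name, reg) for name in reg.names}
    thal = geoms[reg.reference]
    if thal.volume_mm3 <= 0:
        raise ValueError("reference (thalamus) volume is zero")
    origin_v = np.asarray(origin, dtype=float)
    thal_vec = thal.centroid.as_array() - origin_v
    scale = thal.volume_mm3 ** (1.0 / 3.0) if distance_norm else 1.0

    feats = SubjectFeatures(
        subject_id=str(demographics["subject_id"]),
        group=str(demographics["group"]),
        sex=int(demographics["sex"]),
        age=float(demographics["age"]),
        thalamus_volume=thal.volume_mm3,
    )
    for name in reg.non_reference:
        g = geoms[name]
        feats.norm_volume[name] = g.volume_mm3 / thal.volume_mm3
        feats.euclidean_mm[name] = euclidean_distance(g.centroid, thal.centroid) / scale
        feats.cosine[name] = cosine_distance(g.centroid.as_array() - origin_v, thal_vec)
    return feats


def assemble_feature_table(
    subjects: Iterable[SubjectFeatures],
    registry: StructureRegistry | None = None,
) -> pd.DataFrame:
    """Stack per-subject features into the cohort table.

    The result has a fixed, deterministic column order — the raw thalamus
    volume, three columns per non-reference structure, sex and age (57
    feature columns with the default registry) — plus a ``group`` label
    column, indexed by subject id.
    """
    reg = registry if registry is not None else default_registry()
    cols = feature_columns(reg)
    rows: List[Dict[str, object]] = []
    index: List[str] = []
    for s in subjects:
        missing = set(reg.non_reference) - set(s.norm_volume)
        if missing:
            raise ValueError(f"subject {s.subject_id}: missing features for {sorted(missing)}")
        row: Dict[str, object] = {f"{reg.reference}_vol": s.thalamus_volume}
        for name in reg.non_reference:
            row[f"{name}_normvol"] = s.norm_volume[name]
            row[f"{name}_euclid"] = s.euclidean_mm[name]
            row[f"{name}_cosine"] = s.cosine[name]
        row["Sex"] = s.sex
        row["Age"] = s.age
        row["group"] = s.group
        rows.append(row)
        index.append(s.subject_id)
    if not rows:
        raise ValueError("empty cohort: no subjects to assemble")
    table = pd.DataFrame(rows, index=pd.Index(index, name="subject_id"))
    return table[cols + ["group"]]
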