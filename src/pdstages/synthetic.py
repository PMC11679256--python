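"""Synthetic cohorts with the statistical structure the analysis assumes.

Two generation modes share one anatomical model:

* **Phantom mode** rasterises every structure as a voxelised ellipsoid
  into a labelled 3D grid (one volume per subject), so the whole
  pipeline — reading, QC, centroid extraction, feature assembly — can be
  exercised end to end against known ground truth.
* **Fast mode** skips rasterisation and computes the feature table
  directly from the sampled true volumes and centroids; it is cheap
  enough for calibration studies with thousands of replicates.

The template places ellipsoids for all 19 registry structures at
atlas-plausible offsets from a midline origin, with radii chosen so that
volume ratios (e.g. left amygdala near 0.11 of the bilateral thalamus)
and thalamus-to-structure distances (hippocampus near 33 mm, cerebellum
near 54 mm) sit in the range seen in adult subcortical anatomy.
Inter-subject variability enters as multiplicative log-normal volume
noise (coefficient of variation ``volume_cv``) and isotropic Gaussian
centroid jitter (``jitter_sd`` mm).  Group effects are declarative
:class:`EffectSpec` entries — a volume scale factor applied to a
structure in one group (exact in expectation) and/or a centroid shift in
mm.  With no effects, group labels are exchangeable by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .registry import GROUPS, StructureRegistry, default_registry, feature_columns
from .volume import LabeledVolume, write_labeled_volume

# Ellipsoid axis-length ratios (x, y, z); volumes fix the overall radius.
_SHAPE = np.array([0.9, 1.2, 0.9])
_SHAPE_COEF = 4.0 / 3.0 * np.pi * float(np.prod(_SHAPE))  # V = coef * r^3


@dataclass(frozen=True)
class TemplatePart:
    """One ellipsoid: a single label code within a (possibly merged) structure."""

    structure: str
    label: int
    center: Tuple[float, float, float]  # RAS mm
    volume: float  # mm^3


def default_template() -> List[TemplatePart]:
    """Canonical ellipsoid layout for the 19-structure registry.

    Bilateral structures appear once per side; merged structures
    (thalamus, each cerebellar hemisphere) contribute one part per label
    code so every registry code is present in the phantom.
    """
    parts: List[TemplatePart] = [
        TemplatePart("Thalamus", 10, (-12.0, -19.0, 8.0), 6000.0),
        TemplatePart("Thalamus", 49, (12.0, -19.0, 8.0), 6000.0),
        TemplatePart("Left-Hippocampus", 17, (-26.0, -22.0, -12.0), 3500.0),
        TemplatePart("Right-Hippocampus", 53, (26.0, -22.0, -12.0), 3500.0),
        TemplatePart("Left-Amygdala", 18, (-27.0, 4.0, -22.0), 1350.0),
        TemplatePart("Right-Amygdala", 54, (27.0, 4.0, -22.0), 1350.0),
        TemplatePart("Left-Caudate", 11, (-13.0, 12.0, 12.0), 3000.0),
        TemplatePart("Right-Caudate", 50, (13.0, 12.0, 12.0), 3000.0),
        TemplatePart("Left-Putamen", 12, (-28.0, 2.0, 0.0), 3600.0),
        TemplatePart("Right-Putamen", 51, (28.0, 2.0, 0.0), 3600.0),
        TemplatePart("Left-Pallidum", 13, (-18.0, -28.0, 26.0), 1400.0),
        TemplatePart("Right-Pallidum", 52, (18.0, -28.0, 26.0), 1400.0),
        TemplatePart("Left-Accumbens-area", 26, (-9.0, 12.0, -8.0), 550.0),
        TemplatePart("Right-Accumbens-area", 58, (9.0, 12.0, -8.0), 550.0),
        TemplatePart("Left-VentralDC", 28, (-11.0, -6.0, -16.0), 3000.0),
        TemplatePart("Right-VentralDC", 60, (11.0, -6.0, -16.0), 3000.0),
        TemplatePart("4th-Ventricle", 15, (0.0, -50.0, -34.0), 1400.0),
        TemplatePart("Left-Cerebellum", 7, (-10.0, -42.0, -20.0), 1800.0),
        TemplatePart("Left-Cerebellum", 8, (-26.0, -54.0, -32.0), 6000.0),
        TemplatePart("Right-Cerebellum", 46, (10.0, -42.0, -20.0), 1800.0),
        TemplatePart("Right-Cerebellum", 47, (26.0, -54.0, -32.0), 6000.0),
        TemplatePart("CSF", 24, (0.0, -2.0, 14.0), 900.0),
    ]
    return parts


@dataclass(frozen=True)
class EffectSpec:
    """A group-specific anatomical effect on one structure.

    ``volume_scale`` multiplies the structure's expected volume (applied
    as ``scale^(1/3)`` per ellipsoid axis, so it is exact in
    expectation); ``centroid_shift`` translates its template centre, in
    mm.
    """

    structure: str
    group: str
    volume_scale: float = 1.0
    centroid_shift: Tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        if self.volume_scale <= 0:
            raise ValueError("volume_scale must be > 0")


@dataclass(frozen=True)
class FeatureEffect:
    """Fast-mode-only standardized mean shift on one feature column.

    Adds ``d`` times the column's (pre-shift) standard deviation to the
    subjects of ``group``, yielding a standardized effect size of ``d``
    against the unshifted groups.
    """

    column: str
    group: str
    d: float


def default_effects() -> Tuple[EffectSpec, ...]:
    """Study-condition group effects.

    Encodes the qualitative progression pattern the group comparison is
    expected to recover: volume reductions in the left amygdala, left
    putamen and left accumbens in both the prodromal and Parkinson
    groups; additional left caudate and left ventral-diencephalon
    reductions in the Parkinson group only; and small centroid
    displacements of the left hippocampus (toward the thalamus) and
    right pallidum (away from it) in both affected groups.
    """
    both = ("PRODROMAL", "PARKINSON")
    specs: List[EffectSpec] = []
    for g in both:
        specs += [
            EffectSpec("Left-Amygdala", g, volume_scale=0.88),
            EffectSpec("Left-Putamen", g, volume_scale=0.88),
            EffectSpec("Left-Accumbens-area", g, volume_scale=0.88),
            EffectSpec("Left-Hippocampus", g, centroid_shift=(0.9, 0.1, 0.7)),
            EffectSpec("Right-Pallidum", g, centroid_shift=(0.7, -0.3, 0.7)),
        ]
    specs += [
        EffectSpec("Left-Caudate", "PARKINSON", volume_scale=0.88),
        EffectSpec("Left-VentralDC", "PARKINSON", volume_scale=0.88),
    ]
    return tuple(specs)


_FEMALE_PROP = {"CONTROL": 0.321, "PRODROMAL": 0.250, "PARKINSON": 0.429}
_UPDRS3 = {"CONTROL": (0.79, 1.67), "PRODROMAL": (4.86, 5.91), "PARKINSON": (23.89, 11.47)}


@dataclass(frozen=True)
class CohortConfig:
    """Everything that defines a synthetic cohort.

    ``effects=None`` selects the study-condition defaults
    (:func:`default_effects`); pass an empty tuple for a null cohort.
    ``grid_shape=None`` auto-fits the grid to the template (phantom mode).
    ``template_scale`` uniformly shrinks positions and radii for
    reduced-grid runs.
    """

    n_per_group: int = 56
    groups: Tuple[str, ...] = GROUPS
    voxel_size: float = 1.0
    grid_shape: Optional[Tuple[int, int, int]] = None
    jitter_sd: float = 0.6
    volume_cv: float = 0.08
    effects: Optional[Tuple[EffectSpec, ...]] = None
    feature_effects: Tuple[FeatureEffect, ...] = ()
    template_scale: float = 1.0
    age_mean: float = 62.0
    age_sd: float = 11.0
    age_range: Tuple[float, float] = (40.0, 90.0)
    female_prop: Mapping[str, float] = field(default_factory=lambda: dict(_FEMALE_PROP))
    include_updrs3: bool = True
    seed: int = 0

    def resolved_effects(self) -> Tuple[EffectSpec, ...]:
        return default_effects() if self.effects is None else self.effects

    def validate(self, registry: StructureRegistry) -> None:
        if self.n_per_group < 2:
            raise ValueError("n_per_group must be >= 2")
        if len(set(self.groups)) != len(self.groups) or not self.groups:
            raise ValueError("groups must be non-empty and distinct")
        if self.jitter_sd < 0:
            raise ValueError("jitter_sd must be >= 0")
        if self.volume_cv < 0:
            raise ValueError("volume_cv must be >= 0")
        if self.voxel_size <= 0 or self.template_scale <= 0:
            raise ValueError("voxel_size and template_scale must be > 0")
        for e in self.resolved_effects():
            if e.structure not in registry:
                raise ValueError(f"effect references unknown structure {e.structure!r}")
            if e.group not in self.groups:
                raise ValueError(f"effect references unknown group {e.group!r}")


def null_config(**overrides) -> CohortConfig:
    """A cohort configuration with no group effects (null conditions)."""
    overrides.setdefault("effects", ())
    return CohortConfig(**overrides)


@dataclass
class CohortSample:
    """Sampled true anatomy and demographics for a whole cohort."""

    manifest: pd.DataFrame  # subject_id, group, sex, age [, updrs3]
    part_volumes: np.ndarray  # (n_subjects, n_parts) mm^3
    part_centers: np.ndarray  # (n_subjects, n_parts, 3) RAS mm
    parts: List[TemplatePart]
    registry: StructureRegistry

    def structure_truth(self) -> pd.DataFrame:
        """Long-format ground truth: one row per subject per structure.

        Merged structures pool their parts: volume is the sum, centroid
        the volume-weighted mean of part centres.
        """
        names = self.registry.names
        part_struct = np.array([p.structure for p in self.parts])
        rows = []
        for j, name in enumerate(names):
            cols = np.flatnonzero(part_struct == name)
            v = self.part_volumes[:, cols]  # (n, k)
            c = self.part_centers[:, cols, :]  # (n, k, 3)
            vol = v.sum(axis=1)
            cen = (v[:, :, None] * c).sum(axis=1) / vol[:, None]
            rows.append(
                pd.DataFrame(
                    {
                        "subject_id": self.manifest["subject_id"].to_numpy(),
                        "group": self.manifest["group"].to_numpy(),
                        "structure": name,
                        "vol_mm3": vol,
                        "cx": cen[:, 0],
                        "cy": cen[:, 1],
                        "cz": cen[:, 2],
                    }
                )
            )
        out = pd.concat(rows, ignore_index=True)
        return out.sort_values(["subject_id", "structure"], kind="stable").reset_index(drop=True)


def _truncated_normal(rng: np.random.Generator, mean: float, sd: float, lo: float, hi: float, n: int) -> np.ndarray:
    out = rng.normal(mean, sd, size=n)
    bad = (out < lo) | (out > hi)
    while bad.any():  # resample the out-of-range draws
        out[bad] = rng.normal(mean, sd, size=int(bad.sum()))
        bad = (out < lo) | (out > hi)
    return out


def sample_cohort(config: CohortConfig, registry: Optional[StructureRegistry] = None) -> CohortSample:
    """Draw true anatomy and demographics for every subject, deterministically."""
    reg = registry if registry is not None else default_registry()
    config.validate(reg)
    rng = np.random.default_rng(config.seed)
    parts = default_template()
    # template_scale shrinks the whole geometry uniformly: positions,
    # radii, centroid jitter and effect shifts all scale with it.
    s = config.template_scale
    jitter_sd = config.jitter_sd * s
    if s != 1.0:
        parts = [
            replace(p, center=tuple(np.asarray(p.center) * s), volume=p.volume * s**3)
            for p in parts
        ]
    n_parts = len(parts)
    groups = np.repeat(list(config.groups), config.n_per_group)
    n = len(groups)

    # Demographics
    sex = np.zeros(n, dtype=int)
    age = _truncated_normal(rng, config.age_mean, config.age_sd, *config.age_range, n)
    updrs = np.zeros(n)
    for g in config.groups:
        m = groups == g
        sex[m] = (rng.random(int(m.sum())) < config.female_prop.get(g, 0.5)).astype(int)
        mu, sd = _UPDRS3.get(g, (5.0, 5.0))
        updrs[m] = np.clip(rng.normal(mu, sd, int(m.sum())), 0.0, None)

    # Base anatomy noise (independent of group — exchangeable under the null)
    sigma = np.sqrt(np.log1p(config.volume_cv**2))
    log_noise = rng.normal(-0.5 * sigma**2, sigma, size=(n, n_parts)) if sigma > 0 else np.zeros((n, n_parts))
    jitter = rng.normal(0.0, jitter_sd, size=(n, n_parts, 3)) if jitter_sd > 0 else np.zeros((n, n_parts, 3))

    base_v = np.array([p.volume for p in parts])
    base_c = np.array([p.center for p in parts])
    scale = np.ones((n, n_parts))
    shift = np.zeros((n, n_parts, 3))
    part_struct = np.array([p.structure for p in parts])
    for e in config.resolved_effects():
        rows = groups == e.group
        cols = part_struct == e.structure
        scale[np.ix_(rows, cols)] *= e.volume_scale
        shift[np.ix_(rows, cols)] += np.asarray(e.centroid_shift) * s

    part_volumes = base_v[None, :] * scale * np.exp(log_noise)
    part_centers = base_c[None, :, :] + shift + jitter

    manifest = pd.DataFrame(
        {
            "subject_id": [f"sub-{i:04d}" for i in range(n)],
            "group": groups,
            "sex": sex,
            "age": age,
        }
    )
    if config.include_updrs3:
        manifest["updrs3"] = updrs
    return CohortSample(manifest=manifest, part_volumes=part_volumes, part_centers=part_centers, parts=parts, registry=reg)


# ---------------------------------------------------------------------------
# Phantom rasterisation


def _auto_grid(parts: Sequence[TemplatePart], voxel_size: float, margin: float) -> Tuple[Tuple[int, int, int], np.ndarray]:
    """Grid shape and affine that enclose the template with a margin."""
    lo = np.full(3, np.inf)
    hi = np.full(3, -np.inf)
    for p in parts:
        r = (p.volume / _SHAPE_COEF) ** (1.0 / 3.0)
        semi = _SHAPE * r
        lo = np.minimum(lo, np.asarray(p.center) - semi)
        hi = np.maximum(hi, np.asarray(p.center) + semi)
    lo -= margin
    hi += margin
    shape = tuple(int(np.ceil((hi[i] - lo[i]) / voxel_size)) + 1 for i in range(3))
    affine = np.eye(4)
    affine[:3, :3] *= voxel_size
    affine[:3, 3] = lo
    return shape, affine


class StructureCollisionError(RuntimeError):
    """Two rasterised structures claimed the same voxel."""


def rasterize_subject(
    part_volumes: np.ndarray,
    part_centers: np.ndarray,
    parts: Sequence[TemplatePart],
    grid_shape: Tuple[int, int, int],
    affine: np.ndarray,
) -> LabeledVolume:
    """Voxelise one subject's ellipsoids into a labelled grid.

    A voxel belongs to an ellipsoid when its centre lies inside it.
    Later parts must not overwrite earlier ones: any collision raises
    :class:`StructureCollisionError`.  A part extending outside the grid
    raises ``ValueError`` (grid too small).
    """
    labels = np.zeros(grid_shape, dtype=np.int16)
    inv = np.linalg.inv(affine)
    voxel_size = np.abs(np.diag(affine)[:3])
    for j, part in enumerate(parts):
        r = (part_volumes[j] / _SHAPE_COEF) ** (1.0 / 3.0)
        semi = _SHAPE * r
        center = part_centers[j]
        lo_idx = (inv[:3, :3] @ (center - semi) + inv[:3, 3])
        hi_idx = (inv[:3, :3] @ (center + semi) + inv[:3, 3])
        lo = np.floor(np.minimum(lo_idx, hi_idx)).astype(int) - 1
        hi = np.ceil(np.maximum(lo_idx, hi_idx)).astype(int) + 1
        if np.any(lo < 0) or np.any(hi >= np.asarray(grid_shape)):
            raise ValueError(
                f"grid {grid_shape} too small to contain {part.structure} "
                f"(label {part.label}) at centre {tuple(np.round(center, 1))}"
            )
        ii, jj, kk = np.meshgrid(
            np.arange(lo[0], hi[0] + 1),
            np.arange(lo[1], hi[1] + 1),
            np.arange(lo[2], hi[2] + 1),
            indexing="ij",
        )
        idx = np.stack([ii, jj, kk], axis=-1).astype(float)
        ras = idx @ affine[:3, :3].T + affine[:3, 3]
        inside = np.sum(((ras - center) / semi) ** 2, axis=-1) <= 1.0
        sub = labels[lo[0] : hi[0] + 1, lo[1] : hi[1] + 1, lo[2] : hi[2] + 1]
        clash = inside & (sub != 0)
        if clash.any():
            other = int(sub[clash][0])
            raise StructureCollisionError(
                f"{part.structure} (label {part.label}) collides with label {other} "
                f"at the requested sizes/shifts"
            )
        sub[inside] = part.label
    return LabeledVolume(labels=labels, affine=affine)


@dataclass
class PhantomCohort:
    """Result of phantom-mode generation."""

    manifest: pd.DataFrame
    ground_truth: pd.DataFrame
    volumes: Optional[Dict[str, LabeledVolume]]  # in-memory mode
    paths: Optional[Dict[str, Path]]  # on-disk mode
    affine: np.ndarray


def generate_phantom_cohort(
    config: CohortConfig,
    out_dir: Optional[str | Path] = None,
    registry: Optional[StructureRegistry] = None,
    write_stats: bool = False,
) -> PhantomCohort:
    """Generate one labelled phantom volume per subject.

    With ``out_dir`` set, volumes are written as NIfTI (plus manifest and
    ground-truth CSVs, and optional aseg.stats-format fixtures) and not
    kept in memory; otherwise they are returned in a dict keyed by
    subject id.  Deterministic under a fixed ``config.seed``.
    """
    reg = registry if registry is not None else default_registry()
    sample = sample_cohort(config, reg)
    margin = 4.0 + 4.0 * config.jitter_sd + 2.0 * config.voxel_size
    shape, affine = _auto_grid(sample.parts, config.voxel_size, margin)
    if config.grid_shape is not None:
        shape = tuple(config.grid_shape)

    volumes: Optional[Dict[str, LabeledVolume]] = None if out_dir is not None else {}
    paths: Optional[Dict[str, Path]] = None
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        paths = {}

    for i, sid in enumerate(sample.manifest["subject_id"]):
        vol = rasterize_subject(sample.part_volumes[i], sample.part_centers[i], sample.parts, shape, affine)
        if out_dir is not None:
            assert paths is not None
            paths[sid] = write_labeled_volume(vol, out_dir / f"{sid}_aseg.nii.gz")
            if write_stats:
                _write_stats_fixture(vol, out_dir / f"{sid}_aseg.stats", reg)
        else:
            assert volumes is not None
            volumes[sid] = vol

    truth = sample.structure_truth()
    if out_dir is not None:
        sample.manifest.to_csv(out_dir / "manifest.csv", index=False)
        truth.to_csv(out_dir / "ground_truth.csv", index=False)
    return PhantomCohort(
        manifest=sample.manifest, ground_truth=truth, volumes=volumes, paths=paths, affine=affine
    )


def _write_stats_fixture(vol: LabeledVolume, path: Path, registry: StructureRegistry) -> None:
    """aseg.stats-format fixture: voxel counts and volumes per label code.

    Synthetic stand-in for a FreeSurfer stats file (header is minimal).
    """
    name_by_code = {}
    for name in registry.names:
        for code in registry.codes(name):
            name_by_code[code] = name
    lines = ["# synthetic aseg.stats fixture", "# ColHeaders Index SegId NVoxels Volume_mm3 StructName"]
    codes, counts = np.unique(vol.labels[vol.labels > 0], return_counts=True)
    for i, (code, cnt) in enumerate(zip(codes, counts), start=1):
        name = name_by_code.get(int(code), f"Seg{int(code)}")
        lines.append(f"{i:3d} {int(code):4d} {int(cnt):8d} {cnt * vol.voxel_volume:12.1f} {name}")
    path.write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Fast mode


def generate_feature_cohort(
    config: CohortConfig,
    registry: Optional[StructureRegistry] = None,
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Parametric feature table straight from the sampled true anatomy.

    Returns ``(feature_table, ground_truth)``.  The table has exactly the
    columns of :func:`pdstages.geometry.assemble_feature_table` plus the
    group label; volumes are normalised by the bilateral thalamus volume
    and distances are computed analytically from the true centroids.
    Column-level standardized effects (``config.feature_effects``) are
    applied afterwards; referencing an unknown column is an error.
    """
    reg = registry if registry is not None else default_registry()
    sample = sample_cohort(config, reg)
    names = reg.names
    part_struct = np.array([p.structure for p in sample.parts])
    vol = {}
    cen = {}
    for name in names:
        cols = np.flatnonzero(part_struct == name)
        v = sample.part_volumes[:, cols]
        c = sample.part_centers[:, cols, :]
        vol[name] = v.sum(axis=1)
        cen[name] = (v[:, :, None] * c).sum(axis=1) / vol[name][:, None]

    ref = reg.reference
    thal_v = vol[ref]
    thal_c = cen[ref]
    thal_norm = np.linalg.norm(thal_c, axis=1)
    data: Dict[str, np.ndarray] = {f"{ref}_vol": thal_v}
    for name in reg.non_reference:
        c = cen[name]
        diff = c - thal_c
        data[f"{name}_normvol"] = vol[name] / thal_v
        data[f"{name}_euclid"] = np.linalg.norm(diff, axis=1)
        sim = np.einsum("ij,ij->i", c, thal_c) / (np.linalg.norm(c, axis=1) * thal_norm)
        data[f"{name}_cosine"] = 1.0 - np.clip(sim, -1.0, 1.0)
    data["Sex"] = sample.manifest["sex"].to_numpy(dtype=float)
    data["Age"] = sample.manifest["age"].to_numpy()

    table = pd.DataFrame(data, index=pd.Index(sample.manifest["subject_id"], name="subject_id"))
    table = table[feature_columns(reg)]

    groups = sample.manifest["group"].to_numpy()
    if config.feature_effects:
        sds = {fe.column: float(table[fe.column].std(ddof=1)) for fe in config.feature_effects if fe.column in table.columns}
        for fe in config.feature_effects:
            if fe.column not in table.columns:
                raise ValueError(f"feature effect references unknown column {fe.column!r}")
            if fe.group not in config.groups:
                raise ValueError(f"feature effect references unknown group {fe.group!r}")
            table.loc[groups == fe.group, fe.column] += fe.d * sds[fe.column]

    table["group"] = groups
    return table, sample.structure_truth()
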