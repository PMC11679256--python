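"""Reading and validating segmentation products.

Supports labelled volumes in NIfTI (the interoperable standard; MGZ files
are accepted through the same nibabel-backed reader) and FreeSurfer-style
``aseg.stats`` summary files, plus the cohort-level quality-control pass
that excludes subjects with missing or empty outputs before any feature
is computed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import nibabel as nib
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


class EmptyFileError(ValueError):
    """Zero bytes, a stats table with no rows, or a volume with no foreground."""


@dataclass(frozen=True)
class LabeledVolume:
    """A 3D integer label grid with a voxel-index -> RAS mm affine.

    ``voxel_volume`` is the absolute determinant of the affine's 3x3
    block, i.e. the volume of one voxel in mm^3.  Label 0 is background.
    """

    labels: np.ndarray
    affine: np.ndarray

    def __post_init__(self) -> None:
        labels = np.asarray(self.labels)
        affine = np.asarray(self.affine, dtype=float)
        if labels.ndim != 3:
            raise ValueError("labels must be a 3D array")
        if not np.issubdtype(labels.dtype, np.integer):
            raise ValueError("labels must be integer-valued")
        if np.any(labels < 0):
            raise ValueError("label codes must be non-negative")
        if affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        if abs(np.linalg.det(affine[:3, :3])) < 1e-12:
            raise ValueError("affine is singular")
        object.__setattr__(self, "labels", labels)
        object.__setattr__(self, "affine", affine)

    @property
    def voxel_volume(self) -> float:
        return float(abs(np.linalg.det(self.affine[:3, :3])))

    @property
    def foreground_codes(self) -> frozenset:
        codes = np.unique(self.labels)
        return frozenset(int(c) for c in codes if c != 0)


def read_labeled_volume(path: str | Path, int_tolerance: float = 1e-6) -> LabeledVolume:
    """Load a labelled volume from NIfTI (.nii/.nii.gz) or MGZ.

    Voxel values must be integers (floating-point storage is accepted
    when every value is within ``int_tolerance`` of an integer).  Labels
    and affine are preserved exactly, so the reader round-trips with
    :func:`write_labeled_volume`.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"volume not found: {path}")
    img = nib.load(str(path))
    data = np.asarray(img.dataobj)
    if not np.issubdtype(data.dtype, np.integer):
        rounded = np.rint(data)
        if np.max(np.abs(data - rounded)) > int_tolerance:
            raise ValueError(f"{path}: voxel values are not integer labels")
        data = rounded.astype(np.int32)
    return LabeledVolume(labels=data.astype(np.int32, copy=False), affine=np.asarray(img.affine))


def write_labeled_volume(volume: LabeledVolume, path: str | Path) -> Path:
    """Write a labelled volume as NIfTI with int16/int32 storage."""
    path = Path(path)
    dtype = np.int16 if volume.labels.max(initial=0) < np.iinfo(np.int16).max else np.int32
    img = nib.Nifti1Image(volume.labels.astype(dtype), volume.affine)
    path.parent.mkdir(parents=True, exist_ok=True)
    nib.save(img, str(path))
    return path


@dataclass(frozen=True)
class SegStatsRecord:
    """One row of an aseg.stats table."""

    seg_id: int
    n_voxels: int
    volume_mm3: float
    struct_name: str

    def __post_init__(self) -> None:
        if self.n_voxels < 0 or self.volume_mm3 < 0:
            raise ValueError("voxel count and volume must be non-negative")


def parse_aseg_stats(path: str | Path) -> List[SegStatsRecord]:
    """Parse a FreeSurfer ``aseg.stats`` file.

    Header lines start with ``#`` and are ignored.  Table rows are
    whitespace-delimited with columns Index, SegId, NVoxels, Volume_mm3,
    StructName (any further columns are ignored).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"stats file not found: {path}")
    text = path.read_text()
    if len(text.strip()) == 0:
        raise EmptyFileError(f"{path}: empty stats file")
    records: List[SegStatsRecord] = []
    for lineno, line in enumerate(text.splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) < 5:
            raise ValueError(f"{path}:{lineno}: malformed row (expected >=5 columns): {line!r}")
        try:
            seg_id = int(parts[1])
            n_voxels = int(parts[2])
            volume = float(parts[3])
        except ValueError as exc:
            raise ValueError(f"{path}:{lineno}: non-numeric SegId/NVoxels/Volume: {line!r}") from exc
        records.append(SegStatsRecord(seg_id=seg_id, n_voxels=n_voxels, volume_mm3=volume, struct_name=parts[4]))
    if not records:
        raise EmptyFileError(f"{path}: stats file has no table rows")
    return records


@dataclass(frozen=True)
class QCReport:
    """Quality-control verdict for one subject."""

    subject_id: str
    status: str  # "pass" | "excluded"
    reasons: Tuple[str, ...] = ()

    def __post_init__(self) -> None:
        excluded = self.status == "excluded"
        if excluded != bool(self.reasons):
            raise ValueError("excluded iff reasons non-empty")


def qc_subject(
    subject_id: str,
    volume_path: Optional[Path] = None,
    stats_path: Optional[Path] = None,
    required_codes: Optional[Iterable[int]] = None,
) -> QCReport:
    """QC one subject from whichever artifacts it is expected to provide.

    Flags a missing file, an empty file (zero bytes, a row-less stats
    table, or a label volume with no foreground voxels), and — when
    ``required_codes`` is given — any registry label code absent from the
    artifacts.
    """
    reasons: List[str] = []
    present_codes: set[int] = set()
    any_artifact_checked = False

    if volume_path is not None:
        any_artifact_checked = True
        volume_path = Path(volume_path)
        if not volume_path.exists():
            reasons.append(f"missing file: {volume_path.name}")
        else:
            try:
                vol = read_labeled_volume(volume_path)
            except ValueError:
                reasons.append(f"unreadable volume: {volume_path.name}")
            else:
                if not vol.foreground_codes:
                    reasons.append(f"empty file: {volume_path.name} (no foreground voxels)")
                present_codes |= set(vol.foreground_codes)

    if stats_path is not None:
        any_artifact_checked = True
        stats_path = Path(stats_path)
        if not stats_path.exists():
            reasons.append(f"missing file: {stats_path.name}")
        else:
            try:
                records = parse_aseg_stats(stats_path)
            except EmptyFileError:
                reasons.append(f"empty file: {stats_path.name}")
            else:
                present_codes |= {r.seg_id for r in records if r.n_voxels > 0}

    if not any_artifact_checked:
        reasons.append("missing file: no artifact provided")

    if required_codes is not None and not reasons:
        missing = sorted(set(required_codes) - present_codes)
        if missing:
            reasons.append(f"missing structure: label codes {missing}")

    status = "excluded" if reasons else "pass"
    return QCReport(subject_id=str(subject_id), status=status, reasons=tuple(reasons))


def qc_cohort(
    manifest: pd.DataFrame,
    artifacts: Mapping[str, Mapping[str, Optional[Path]]],
    required_codes: Optional[Iterable[int]] = None,
) -> Tuple[List[QCReport], pd.DataFrame]:
    """Apply the exclusion logic across a cohort manifest.

    Parameters
    ----------
    manifest :
        DataFrame with a ``subject_id`` column (unique) plus any metadata.
    artifacts :
        ``subject_id -> {"volume": path-or-None, "stats": path-or-None}``.
        A subject absent from the mapping is flagged as missing.
    required_codes :
        Label codes every subject must provide (usually the registry's
        ``all_codes``).

    Returns the per-subject reports (manifest order preserved) and the
    retained manifest containing only passing subjects.
    """
    if manifest["subject_id"].duplicated().any():
        raise ValueError("manifest subject_id values must be unique")
    required = list(required_codes) if required_codes is not None else None
    reports: List[QCReport] = []
    for sid in manifest["subject_id"].astype(str):
        entry = artifacts.get(sid)
        if entry is None:
            reports.append(QCReport(sid, "excluded", ("missing file: no artifact provided",)))
            continue
        reports.append(
            qc_subject(
                sid,
                volume_path=entry.get("volume"),
                stats_path=entry.get("stats"),
                required_codes=required,
            )
        )
    passing = {r.subject_id for r in reports if r.status == "pass"}
    retained = manifest[manifest["subject_id"].astype(str).isin(passing)].copy()
    logger.info("QC: %d/%d subjects retained", len(retained), len(manifest))
    return reports, retained


def qc_reports_frame(reports: Sequence[QCReport]) -> pd.DataFrame:
    """Tabular view of QC reports for CSV export."""
    return pd.DataFrame(
        {
            "subject_id": [r.subject_id for r in reports],
            "status": [r.status for r in reports],
            "reasons": ["; ".join(r.reasons) for r in reports],
        }
    )
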