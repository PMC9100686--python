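"""File formats: time-series tables, connectivity tables, NIfTI volumes,
cohort manifests and the run configuration schema.

Conventions: time-series files are TSV/CSV with rows = time points,
columns = ROIs, first row = ROI names (a transposed dialect is accepted only
when the manifest flags it); connectivity matrices are square TSV with ROI
names as header row and first column; volumes are NIfTI (.nii / .nii.gz).
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Literal

import nibabel as nib
import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field

from .connectome import ConnectivityMatrix, TimeSeriesMatrix
from .errors import ConfigError, DataError, FormatError
from .types import MultimodalSubject, VolumeImage

__all__ = [
    "read_timeseries",
    "write_timeseries",
    "read_connectivity",
    "write_connectivity",
    "read_volume",
    "write_volume",
    "read_manifest",
    "load_cohort",
    "write_cohort",
    "RunConfig",
    "load_run_config",
    "config_hash",
]


def _sep_for(path: Path) -> str:
    return "," if path.suffix.lower() == ".csv" else "\t"


def read_timeseries(path, transposed: bool = False) -> TimeSeriesMatrix:
    """Parse a time-series table; errors name the offending cell."""
    path = Path(path)
    if not path.exists():
        raise DataError(f"time-series file not found: {path}")
    sep = _sep_for(path)
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split(sep)
    names = [h.strip() for h in header]
    dupes = [n for n in dict.fromkeys(names) if names.count(n) > 1]
    if dupes:
        raise FormatError(f"duplicate ROI names in {path}: {dupes}")
    try:
        frame = pd.read_csv(path, sep=sep, header=0, float_precision="round_trip")
    except Exception as exc:  # noqa: BLE001 - surface as format error
        raise FormatError(f"cannot parse {path}: {exc}") from exc
    numeric = frame.apply(pd.to_numeric, errors="coerce")
    bad = np.argwhere(numeric.isna().values)
    if bad.size:
        row, col = bad[0]
        raise FormatError(
            f"non-numeric or missing value in {path} at data row {row + 1}, "
            f"column {frame.columns[col]!r}"
        )
    values = numeric.values.astype(float)
    names = tuple(str(c) for c in frame.columns)
    if transposed:
        values = values.T
        names = tuple(f"ROI{i + 1}" for i in range(values.shape[1]))
    return TimeSeriesMatrix(subject_id=path.stem, values=values, roi_names=names)


def write_timeseries(ts: TimeSeriesMatrix, path) -> None:
    path = Path(path)
    pd.DataFrame(ts.values, columns=list(ts.roi_names)).to_csv(
        path, sep=_sep_for(path), index=False, float_format="%.17g"
    )


def read_connectivity(path) -> ConnectivityMatrix:
    """Square TSV with ROI names as header row and first column."""
    path = Path(path)
    if not path.exists():
        raise DataError(f"connectivity file not found: {path}")
    frame = pd.read_csv(path, sep=_sep_for(path), header=0, index_col=0)
    if frame.shape[0] != frame.shape[1]:
        raise FormatError(f"connectivity table in {path} is not square: {frame.shape}")
    values = frame.apply(pd.to_numeric, errors="coerce").values
    if np.isnan(values).any():
        raise FormatError(f"non-numeric entries in connectivity table {path}")
    return ConnectivityMatrix(
        values=values, kind="pearson", roi_names=tuple(str(c) for c in frame.columns)
    )


def write_connectivity(b: ConnectivityMatrix, path) -> None:
    path = Path(path)
    pd.DataFrame(
        b.values, columns=list(b.roi_names), index=list(b.roi_names)
    ).to_csv(path, sep=_sep_for(path), float_format="%.17g")


def read_volume(path) -> VolumeImage:
    """Load a 3-D NIfTI volume; 4-D files are rejected.

    The image is taken in stored orientation; the affine is not applied
    (resampling belongs to upstream preprocessing).
    """
    path = Path(path)
    if not path.exists():
        raise DataError(f"volume file not found: {path}")
    try:
        img = nib.load(str(path))
        data = np.asarray(img.get_fdata(), dtype=float)
    except Exception as exc:  # noqa: BLE001
        raise FormatError(f"cannot read NIfTI {path}: {exc}") from exc
    data = np.squeeze(data) if data.ndim == 4 and data.shape[-1] == 1 else data
    if data.ndim != 3:
        raise FormatError(
            f"{path} is {data.ndim}-D; expected a single 3-D volume"
        )
    zooms = tuple(float(z) for z in img.header.get_zooms()[:3])
    return VolumeImage(subject_id=path.name.split(".")[0], values=data, voxel_size=zooms)


def write_volume(vol: VolumeImage, path) -> None:
    affine = np.diag(list(vol.voxel_size) + [1.0])
    img = nib.Nifti1Image(vol.values.astype(np.float32), affine)
    img.header.set_zooms(vol.voxel_size)
    nib.save(img, str(path))


# -- cohort manifest --------------------------------------------------------

_MANIFEST_COLUMNS = {"subject_id", "label"}


def read_manifest(path) -> pd.DataFrame:
    """Manifest TSV: subject_id, label, timeseries_path and/or volume_path,
    optional boolean timeseries_transposed.  Validation is exhaustive before
    any training begins."""
    path = Path(path)
    if not path.exists():
        raise DataError(f"manifest not found: {path}")
    frame = pd.read_csv(path, sep="\t")
    missing = _MANIFEST_COLUMNS - set(frame.columns)
    if missing:
        raise FormatError(f"manifest {path} lacks columns: {sorted(missing)}")
    if frame["subject_id"].duplicated().any():
        dupes = frame.loc[frame["subject_id"].duplicated(), "subject_id"].tolist()
        raise DataError(f"duplicate subject ids in manifest: {dupes}")
    if not frame["label"].isin([0, 1]).all():
        raise DataError("manifest labels must be 0 or 1")
    if "timeseries_path" not in frame.columns and "volume_path" not in frame.columns:
        raise FormatError("manifest needs timeseries_path and/or volume_path columns")
    root = path.parent
    for col in ("timeseries_path", "volume_path"):
        if col in frame.columns:
            for value in frame[col].dropna():
                target = root / value
                if not target.exists():
                    raise DataError(f"manifest references missing file: {target}")
    return frame


def load_cohort(manifest_path) -> list[MultimodalSubject]:
    """Load every subject referenced by a manifest."""
    path = Path(manifest_path)
    frame = read_manifest(path)
    root = path.parent
    subjects = []
    for _, row in frame.iterrows():
        ts = None
        vol = None
        if "timeseries_path" in frame.columns and pd.notna(row.get("timeseries_path")):
            transposed = bool(row.get("timeseries_transposed", False))
            ts = read_timeseries(root / row["timeseries_path"], transposed=transposed)
            ts = TimeSeriesMatrix(
                subject_id=str(row["subject_id"]),
                values=ts.values,
                roi_names=ts.roi_names,
            )
        if "volume_path" in frame.columns and pd.notna(row.get("volume_path")):
            vol = read_volume(root / row["volume_path"])
            vol = VolumeImage(
                subject_id=str(row["subject_id"]),
                values=vol.values,
                voxel_size=vol.voxel_size,
            )
        subjects.append(
            MultimodalSubject(
                subject_id=str(row["subject_id"]),
                label=int(row["label"]),
                time_series=ts,
                volume=vol,
            )
        )
    return subjects


def write_cohort(subjects: list[MultimodalSubject], out_dir) -> Path:
    """Write per-subject time-series TSV + NIfTI volume + a manifest TSV."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for s in subjects:
        row: dict = {"subject_id": s.subject_id, "label": s.label}
        if s.time_series is not None:
            ts_path = out_dir / f"{s.subject_id}_timeseries.tsv"
            write_timeseries(s.time_series, ts_path)
            row["timeseries_path"] = ts_path.name
        if s.volume is not None:
            vol_path = out_dir / f"{s.subject_id}_volume.nii.gz"
            write_volume(s.volume, vol_path)
            row["volume_path"] = vol_path.name
        rows.append(row)
    manifest = out_dir / "manifest.tsv"
    pd.DataFrame(rows).to_csv(manifest, sep="\t", index=False)
    return manifest


# -- run configuration ------------------------------------------------------


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class ConnectomeSection(_Strict):
    strategy: Literal["knn", "threshold", "full"] = "knn"
    k: int = 10
    q: float = 0.2
    absolute: bool = True


class GCNSection(_Strict):
    layer_widths: list[int] = Field(default_factory=lambda: [64, 64])
    head_width: int = 64
    dropout_rate: float = 0.0


class CNNSection(_Strict):
    conv_channels: list[int] = Field(default_factory=lambda: [16, 32, 64, 128])
    kernel_size: int = 3
    fc_widths: list[int] = Field(default_factory=lambda: [128, 64])
    dropout_rate: float = 0.5
    batch_norm: bool = True
    zscore_input: bool = True


class LossSection(_Strict):
    lambda_: float = Field(default=0.01, alias="lambda")
    mmd_kernel: Literal["linear", "rbf"] = "linear"
    mmd_squared: bool = False
    model_config = ConfigDict(extra="forbid", populate_by_name=True)


class TrainSection(_Strict):
    learning_rate: float = 1e-4
    weight_decay: float = 0.0015
    epochs: int = 100
    batch_size: int = 16
    seed: int = 0
    variant: Literal["amni", "amni_s", "amni_f", "amni_womdd", "amni_lf"] = "amni"
    lf_weight: float = 0.5
    dtype: Literal["float32", "float64"] = "float32"


class EvalSection(_Strict):
    n_repeats: int = 10
    test_fraction: float = 0.2
    stratify: bool = True
    base_seed: int = 0


class RunConfig(_Strict):
    """Schema-validated run configuration; unknown keys are rejected."""

    manifest: str
    output_dir: str = "runs"
    connectome: ConnectomeSection = Field(default_factory=ConnectomeSection)
    gcn: GCNSection = Field(default_factory=GCNSection)
    cnn: CNNSection = Field(default_factory=CNNSection)
    loss: LossSection = Field(default_factory=LossSection)
    train: TrainSection = Field(default_factory=TrainSection)
    eval: EvalSection = Field(default_factory=EvalSection)


def load_run_config(path) -> RunConfig:
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"run config not found: {path}")
    try:
        payload = yaml.safe_load(path.read_text()) or {}
        return RunConfig.model_validate(payload)
    except ConfigError:
        raise
    except Exception as exc:  # noqa: BLE001 - pydantic/yaml errors
        raise ConfigError(f"invalid run config {path}: {exc}") from exc


def config_hash(cfg: RunConfig) -> str:
    """Stable short hash naming every output of a run."""
    canonical = json.dumps(cfg.model_dump(by_alias=True), sort_keys=True)
    return hashlib.sha256(canonical.encode()).hexdigest()[:12]
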