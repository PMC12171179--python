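"""Cohort data model and file IO.

A cohort lives in one directory: a manifest CSV linking each patient to a
tongue image, a face image and a pulse recording, plus a single clinical
table. The manifest schema is::

    patient_id,tongue_path,face_path,pulse_path,label,split

Paths are stored relative to the manifest's directory. Pulse recordings are
two-column CSVs (``time_s,pressure``), sampled every 1/50 s; the clinical
table has ``patient_id`` first and named numeric/binary features after.
"""

from __future__ import annotations

import dataclasses
import os
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

MANIFEST_COLUMNS = ["patient_id", "tongue_path", "face_path", "pulse_path",
                    "label", "split"]
SPLITS = ("train", "internal", "external")
DEFAULT_SAMPLING_INTERVAL = 1.0 / 50.0  # s


@dataclasses.dataclass
class PulseRecording:
    """A radial pulse pressure series sampled at a fixed interval."""

    pressure: np.ndarray
    sampling_interval: float = DEFAULT_SAMPLING_INTERVAL

    @property
    def duration(self) -> float:
        return len(self.pressure) * self.sampling_interval

    def __post_init__(self):
        self.pressure = np.asarray(self.pressure, dtype=float)
        if self.pressure.ndim != 1:
            raise ValueError("pulse pressure must be a 1-D series")
        if self.sampling_interval <= 0:
            raise ValueError("sampling_interval must be positive")


@dataclasses.dataclass
class SampleRecord:
    """One patient's four modality inputs plus endpoint label and split."""

    patient_id: str
    tongue_image: np.ndarray  # (H, W, 3) uint8 RGB
    face_image: np.ndarray
    pulse: PulseRecording
    clinical: pd.Series  # named numeric vector
    label: int  # 1 = stenosis >= 75%
    split: str


@dataclasses.dataclass
class CohortManifest:
    """Validated view of a cohort directory."""

    rows: pd.DataFrame          # MANIFEST_COLUMNS, paths relative to root
    clinical: pd.DataFrame      # indexed by patient_id
    root: Path

    @property
    def patient_ids(self) -> list[str]:
        return list(self.rows["patient_id"])

    @property
    def feature_names(self) -> list[str]:
        return list(self.clinical.columns)

    def labels(self, split: str | None = None) -> np.ndarray:
        rows = self.rows if split is None else self.rows[self.rows["split"] == split]
        return rows["label"].to_numpy(dtype=int)

    def ids_for_split(self, split: str) -> list[str]:
        return list(self.rows.loc[self.rows["split"] == split, "patient_id"])


def _validate_manifest(rows: pd.DataFrame, clinical: pd.DataFrame, root: Path) -> None:
    missing = [c for c in MANIFEST_COLUMNS if c not in rows.columns]
    if missing:
        raise ValueError(f"manifest is missing columns: {missing}")
    dup = rows["patient_id"][rows["patient_id"].duplicated()].tolist()
    if dup:
        raise ValueError(f"duplicate patient_id in manifest: {sorted(set(dup))}")
    bad_labels = sorted(set(rows["label"]) - {0, 1})
    if bad_labels:
        raise ValueError(f"labels must be 0/1, found {bad_labels}")
    bad_splits = sorted(set(rows["split"]) - set(SPLITS))
    if bad_splits:
        raise ValueError(f"unknown split tags {bad_splits}; expected {SPLITS}")
    dangling = []
    for _, r in rows.iterrows():
        for col in ("tongue_path", "face_path", "pulse_path"):
            if not (root / r[col]).exists():
                dangling.append(str(r[col]))
    if dangling:
        raise ValueError(f"manifest references missing files: {dangling}")
    absent = [p for p in rows["patient_id"] if p not in clinical.index]
    if absent:
        raise ValueError(f"patients missing from clinical table: {absent}")


def read_manifest(path: str | os.PathLike) -> CohortManifest:
    """Read and validate a cohort manifest CSV.

    The clinical table is expected at ``clinical.csv`` next to the manifest
    unless a ``# clinical_table:`` comment header names another file.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"manifest not found: {path}")
    root = path.parent
    clinical_name = "clinical.csv"
    with open(path) as fh:
        first = fh.readline()
    if first.startswith("# clinical_table:"):
        clinical_name = first.split(":", 1)[1].strip()
    rows = pd.read_csv(path, comment="#", dtype={"patient_id": str})
    clin_path = root / clinical_name
    if not clin_path.exists():
        raise FileNotFoundError(f"clinical table not found: {clin_path}")
    clinical = pd.read_csv(clin_path, dtype={"patient_id": str}).set_index("patient_id")
    _validate_manifest(rows, clinical, root)
    return CohortManifest(rows=rows.reset_index(drop=True), clinical=clinical, root=root)


def write_manifest(manifest: CohortManifest, path: str | os.PathLike) -> None:
    """Serialize a manifest so that ``read_manifest`` round-trips it."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    manifest.rows[MANIFEST_COLUMNS].to_csv(path, index=False)
    manifest.clinical.reset_index().to_csv(path.parent / "clinical.csv", index=False)


def read_pulse_csv(path: str | os.PathLike) -> PulseRecording:
    """Parse a two-column ``time_s,pressure`` CSV into a PulseRecording."""
    df = pd.read_csv(path)
    if not {"time_s", "pressure"}.issubset(df.columns):
        raise ValueError(f"pulse CSV {path} must have columns time_s,pressure")
    t = df["time_s"].to_numpy(dtype=float)
    if len(t) < 2:
        raise ValueError(f"pulse CSV {path} too short")
    dt = np.diff(t)
    if np.any(dt <= 0):
        raise ValueError(f"non-monotone time column in {path}")
    return PulseRecording(pressure=df["pressure"].to_numpy(dtype=float),
                          sampling_interval=float(np.median(dt)))


def write_pulse_csv(rec: PulseRecording, path: str | os.PathLike) -> None:
    t = np.arange(len(rec.pressure)) * rec.sampling_interval
    pd.DataFrame({"time_s": np.round(t, 6),
                  "pressure": rec.pressure}).to_csv(path, index=False)


def load_image(path: str | os.PathLike, image_size: tuple[int, int]) -> np.ndarray:
    """Decode to RGB and bilinear-resize to (H, W); returns uint8 (H, W, 3)."""
    h, w = image_size
    if h % 2 or w % 2:
        raise ValueError("image_size must have even H and W (2x2 max-pool)")
    try:
        img = Image.open(path).convert("RGB")
    except Exception as exc:  # noqa: BLE001 - re-raise with path context
        raise ValueError(f"cannot decode image {path}: {exc}") from exc
    img = img.resize((w, h), Image.BILINEAR)
    return np.asarray(img, dtype=np.uint8)


def load_sample(manifest: CohortManifest, patient_id: str,
                image_size: tuple[int, int] = (64, 64)) -> SampleRecord:
    """Load one patient's four modality inputs. Deterministic."""
    rows = manifest.rows
    match = rows[rows["patient_id"] == patient_id]
    if match.empty:
        raise KeyError(f"patient_id {patient_id!r} not in manifest")
    r = match.iloc[0]
    clinical = manifest.clinical.loc[patient_id]
    if clinical.isna().any():
        bad = list(clinical.index[clinical.isna()])
        raise ValueError(f"missing clinical values for {patient_id}: {bad}")
    return SampleRecord(
        patient_id=patient_id,
        tongue_image=load_image(manifest.root / r["tongue_path"], image_size),
        face_image=load_image(manifest.root / r["face_path"], image_size),
        pulse=read_pulse_csv(manifest.root / r["pulse_path"]),
        clinical=clinical.astype(float),
        label=int(r["label"]),
        split=str(r["split"]),
    )


class MinMaxScaler:
    """Per-feature min-max scaling to [0, 1] using training-split statistics.

    Out-of-range values on held-out splits are clipped so every model sees
    bounded inputs.
    """

    def __init__(self):
        self.min_ = None
        self.range_ = None

    def fit(self, x: np.ndarray) -> "MinMaxScaler":
        x = np.asarray(x, dtype=float)
        self.min_ = x.min(axis=0)
        rng = x.max(axis=0) - self.min_
        self.range_ = np.where(rng > 0, rng, 1.0)
        return self

    def transform(self, x: np.ndarray) -> np.ndarray:
        return np.clip((np.asarray(x, dtype=float) - self.min_) / self.range_, 0.0, 1.0)

    def fit_transform(self, x: np.ndarray) -> np.ndarray:
        return self.fit(x).transform(x)
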