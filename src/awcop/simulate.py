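"""Class-conditional synthetic multimodal cohorts with known ground truth.

The generator emulates the four data sources of the clinical study at desk
scale so every downstream stage (pulse fiducial extraction, branch encoders,
fusion, screening, saliency) can be tested against planted structure:

* **Tongue images** — an elliptical tongue on a dark background with a
  central coating patch; the positive class shifts the coating hue.
* **Face images** — an elliptical face; the positive class brightens the
  forehead, nose and cheek regions (where the trained model's class
  activation maps are expected to concentrate).
* **Pulse waveforms** — 30 s at 50 Hz, concatenated cardiac cycles built
  from three Gaussian bumps (percussion h1, tidal h3, dicrotic h5 after an
  emergent notch h4) on a raised-cosine diastolic base, plus optional
  baseline drift and white noise. The positive class shifts the mean h3/h1
  ratio. Cycle onsets fall exactly on samples, and realized landmark values
  (evaluated on a dense grid of the noiseless model) are recorded as ground
  truth.
* **Clinical table** — 50 named columns; a stated subset (fibrinogen-like,
  D-dimer-like, FDP-like, myoglobin-like markers plus two binary risk
  factors) differs between classes, the rest are standard-normal noise.

Gaussian-bump synthesis is chosen over physiological transmission-line
models deliberately: landmarks are analytically known, so the feature
extractor can be tested for exact recovery.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image
from skimage import color as skcolor

from .io import (CohortManifest, PulseRecording, DEFAULT_SAMPLING_INTERVAL,
                 write_pulse_csv)

INFORMATIVE_NUMERIC = ["fibrinogen_like", "d_dimer_like", "fdp_like", "myoglobin_like"]
BINARY_FACTORS = ["hypertension_like", "diabetes_like"]


@dataclasses.dataclass
class CohortSpec:
    """Knobs of the synthetic cohort; defaults are the study conditions."""

    n_patients: int = 100
    prevalence: float = 0.5
    seed: int = 0
    image_size: tuple[int, int] = (64, 64)
    tongue_effect: float = 40.0      # coating hue shift for class 1, degrees
    face_effect: float = 30.0        # region brightness shift for class 1, 0-255
    pulse_effect: float = 0.15       # additive shift of mean h3/h1 for class 1
    pulse_alternans: float = 0.0     # beat-to-beat amplitude alternation, class 1
    clinical_effects: dict | None = None  # feature -> standardized mean difference
    n_clinical: int = 50
    image_noise: float = 8.0         # pixel noise SD, 0-255 units
    pulse_noise: float = 0.02        # white noise SD, units of h1~1
    drift_amp: float = 0.10          # baseline drift amplitude
    drift_freq: float = 0.15         # Hz
    duration: float = 30.0           # s per recording
    split_fractions: tuple[float, float, float] = (0.70, 0.15, 0.15)
    hypertension_probs: tuple[float, float] = (0.45, 0.60)
    diabetes_probs: tuple[float, float] = (0.30, 0.45)

    def __post_init__(self):
        if not (0.0 < self.prevalence < 1.0):
            raise ValueError("prevalence must be strictly between 0 and 1")
        h, w = self.image_size
        if h % 2 or w % 2:
            raise ValueError("image_size must be even in both dimensions")
        if self.clinical_effects is None:
            self.clinical_effects = {"fibrinogen_like": 0.8, "d_dimer_like": 0.6,
                                     "fdp_like": 0.5, "myoglobin_like": 0.8}
        if self.n_clinical < len(self.clinical_effects) + len(BINARY_FACTORS):
            raise ValueError("n_clinical smaller than the informative feature set")

    def feature_names(self) -> list[str]:
        named = INFORMATIVE_NUMERIC + BINARY_FACTORS
        extra = [f"lab_{i:02d}" for i in range(len(named) + 1, self.n_clinical + 1)]
        return named + extra


@dataclasses.dataclass
class GroundTruth:
    """Planted structure: latent classes, pulse landmarks, informative labs."""

    labels: dict            # patient_id -> 0/1
    pulse: dict             # patient_id -> {period_s, r3, cycles: [...]}
    informative_features: list[str]

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=1)


# --------------------------------------------------------------------------
# region masks

def _ellipse_mask(h, w, cy, cx, ry, rx):
    yy, xx = np.mgrid[0:h, 0:w]
    return ((yy - cy) / ry) ** 2 + ((xx - cx) / rx) ** 2 <= 1.0


def tongue_mask(h: int, w: int) -> np.ndarray:
    return _ellipse_mask(h, w, 0.55 * h, 0.5 * w, 0.38 * h, 0.30 * w)


def tongue_coating_mask(h: int, w: int) -> np.ndarray:
    """Central coating patch; where the class signal is planted."""
    return _ellipse_mask(h, w, 0.50 * h, 0.5 * w, 0.20 * h, 0.16 * w)


def face_mask(h: int, w: int) -> np.ndarray:
    return _ellipse_mask(h, w, 0.52 * h, 0.5 * w, 0.42 * h, 0.32 * w)


def face_region_masks(h: int, w: int) -> dict[str, np.ndarray]:
    """Forehead, nose and (joint) cheek masks carrying the class signal."""
    forehead = _ellipse_mask(h, w, 0.24 * h, 0.5 * w, 0.10 * h, 0.20 * w)
    nose = _ellipse_mask(h, w, 0.55 * h, 0.5 * w, 0.14 * h, 0.06 * w)
    cheeks = (_ellipse_mask(h, w, 0.60 * h, 0.30 * w, 0.09 * h, 0.08 * w)
              | _ellipse_mask(h, w, 0.60 * h, 0.70 * w, 0.09 * h, 0.08 * w))
    face = face_mask(h, w)
    return {"forehead": forehead & face, "nose": nose & face,
            "cheeks": cheeks & face}


# --------------------------------------------------------------------------
# image synthesis

def _shift_hue(rgb01: np.ndarray, degrees: float) -> np.ndarray:
    hsv = skcolor.rgb2hsv(rgb01[None, None, :])
    hsv[..., 0] = (hsv[..., 0] + degrees / 360.0) % 1.0
    return skcolor.hsv2rgb(hsv)[0, 0]


def synth_tongue_image(cls: int, spec: CohortSpec, rng: np.random.Generator) -> np.ndarray:
    h, w = spec.image_size
    img = np.empty((h, w, 3))
    img[:] = (40.0, 40.0, 45.0)
    body = tongue_mask(h, w)
    coating = tongue_coating_mask(h, w)
    img[body] = (185.0, 95.0, 95.0)
    base_coating = np.array([200.0, 170.0, 120.0]) / 255.0
    jitter = rng.normal(0.0, 3.0)  # per-patient hue variation, both classes
    shift = jitter + (spec.tongue_effect if cls == 1 else 0.0)
    img[coating] = _shift_hue(base_coating, shift) * 255.0
    img += rng.normal(0.0, spec.image_noise, img.shape)
    return np.clip(img, 0, 255).astype(np.uint8)


def synth_face_image(cls: int, spec: CohortSpec, rng: np.random.Generator) -> np.ndarray:
    h, w = spec.image_size
    img = np.empty((h, w, 3))
    img[:] = (35.0, 35.0, 40.0)
    img[face_mask(h, w)] = (190.0, 155.0, 130.0)
    img += rng.normal(0.0, 4.0)  # per-patient global exposure jitter
    if cls == 1:
        regions = face_region_masks(h, w)
        lit = regions["forehead"] | regions["nose"] | regions["cheeks"]
        img[lit] += spec.face_effect
    img += rng.normal(0.0, spec.image_noise, img.shape)
    return np.clip(img, 0, 255).astype(np.uint8)


# --------------------------------------------------------------------------
# pulse synthesis

def _cycle_model(t: np.ndarray, period: float, h1: float, r3: float) -> np.ndarray:
    """Noiseless single-cycle waveform on times ``t`` in [0, period)."""
    # bump placement keeps the cycle-onset sample the strict minimum for
    # every period in [0.7, 1.1] s: the percussion tail at t=0 must stay
    # below the raised-cosine base at the last sample
    t1 = 0.18 * period
    t3 = 0.34 * period
    t5 = 0.58 * period
    s1, s3, s5 = 0.030, 0.045, 0.040
    base = 0.08 * h1 * (1.0 - np.cos(2 * np.pi * t / period)) / 2.0
    wave = (h1 * np.exp(-0.5 * ((t - t1) / s1) ** 2)
            + r3 * h1 * np.exp(-0.5 * ((t - t3) / s3) ** 2)
            + 0.25 * h1 * np.exp(-0.5 * ((t - t5) / s5) ** 2))
    return base + wave


def _realized_landmarks(period: float, h1: float, r3: float) -> dict:
    """Landmarks of the continuous noiseless cycle, via a dense grid."""
    t = np.linspace(0.0, period, 4000, endpoint=False)
    y = _cycle_model(t, period, h1, r3)
    onset_val = y[0]
    main = slice(0, np.searchsorted(t, 0.27 * period))
    i1 = int(np.argmax(y[main]))
    tidal = slice(np.searchsorted(t, 0.26 * period), np.searchsorted(t, 0.46 * period))
    i3 = tidal.start + int(np.argmax(y[tidal]))
    return {"h1": float(y[i1] - onset_val), "t1": float(t[i1]),
            "h3": float(y[i3] - onset_val), "t3": float(t[i3])}


def synth_pulse(cls: int, spec: CohortSpec,
                rng: np.random.Generator) -> tuple[PulseRecording, dict]:
    """One 30-s recording plus its per-cycle landmark ground truth."""
    dt = DEFAULT_SAMPLING_INTERVAL
    n_total = int(round(spec.duration / dt))
    period = float(np.clip(rng.normal(0.85, 0.06), 0.70, 1.10))
    n_cyc = int(round(period / dt))
    period = n_cyc * dt  # onsets land exactly on samples
    if period > 3.0:
        raise ValueError("cycle period incompatible with a 6-s stable window")
    h1_pat = rng.normal(1.0, 0.05)
    r3_pat = float(np.clip(
        rng.normal(0.45 + spec.pulse_effect * cls, 0.05), 0.05, 0.90))
    t_cycle = np.arange(n_cyc) * dt
    pieces, cycles = [], []
    onset = 0
    beat = 0
    alt = spec.pulse_alternans * cls  # pulsus-alternans channel: the cycle
    # -averaged parameter table is blind to it, the waveform encoder is not
    while onset < n_total:  # last cycle may be trimmed
        h1_c = h1_pat * (1.0 + rng.normal(0.0, 0.02))
        h1_c *= 1.0 + alt * (1 if beat % 2 == 0 else -1)
        beat += 1
        r3_c = float(np.clip(r3_pat + rng.normal(0.0, 0.02), 0.05, 0.95))
        pieces.append(_cycle_model(t_cycle, period, h1_c, r3_c))
        lm = _realized_landmarks(period, h1_c, r3_c)
        lm.update({"onset": onset, "period": period, "r3_param": r3_c})
        cycles.append(lm)
        onset += n_cyc
    pressure = np.concatenate(pieces)[:n_total]
    tt = np.arange(n_total) * dt
    if spec.drift_amp > 0:
        pressure = pressure + spec.drift_amp * np.sin(
            2 * np.pi * spec.drift_freq * tt + rng.uniform(0, 2 * np.pi))
    if spec.pulse_noise > 0:
        pressure = pressure + rng.normal(0.0, spec.pulse_noise, n_total)
    truth = {"period_s": period, "h1_patient": h1_pat, "r3_patient": r3_pat,
             "cycles": [c for c in cycles if c["onset"] + n_cyc <= n_total]}
    return PulseRecording(pressure=pressure, sampling_interval=dt), truth


# --------------------------------------------------------------------------
# clinical table

def synth_clinical(cls: int, spec: CohortSpec, rng: np.random.Generator) -> pd.Series:
    names = spec.feature_names()
    values = {}
    for name in names:
        if name == "hypertension_like":
            values[name] = float(rng.random() < spec.hypertension_probs[cls])
        elif name == "diabetes_like":
            values[name] = float(rng.random() < spec.diabetes_probs[cls])
        else:
            shift = spec.clinical_effects.get(name, 0.0) * cls
            values[name] = float(rng.normal(shift, 1.0))
    return pd.Series(values, name="clinical")


# --------------------------------------------------------------------------
# cohort assembly

def _assign_splits(labels: np.ndarray, fractions, rng) -> np.ndarray:
    """Stratified train/internal/external assignment with stated fractions."""
    splits = np.empty(len(labels), dtype=object)
    for cls in (0, 1):
        idx = np.flatnonzero(labels == cls)
        idx = idx[rng.permutation(len(idx))]
        n = len(idx)
        n_tr = int(round(fractions[0] * n))
        n_int = int(round(fractions[1] * n))
        splits[idx[:n_tr]] = "train"
        splits[idx[n_tr:n_tr + n_int]] = "internal"
        splits[idx[n_tr + n_int:]] = "external"
    return splits


def generate_cohort(spec: CohortSpec, out_dir) -> tuple[CohortManifest, GroundTruth]:
    """Write a complete cohort directory; identical spec+seed => identical bytes."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(spec.seed)
    n = spec.n_patients
    n_pos = int(round(spec.prevalence * n))
    labels = np.zeros(n, dtype=int)
    labels[rng.choice(n, size=n_pos, replace=False)] = 1
    splits = _assign_splits(labels, spec.split_fractions, rng)

    rows, clin_rows, gt_pulse = [], [], {}
    for i in range(n):
        pid = f"P{i + 1:04d}"
        cls = int(labels[i])
        tongue = synth_tongue_image(cls, spec, rng)
        face = synth_face_image(cls, spec, rng)
        pulse, truth = synth_pulse(cls, spec, rng)
        clinical = synth_clinical(cls, spec, rng)
        Image.fromarray(tongue).save(out / f"tongue_{pid}.png")
        Image.fromarray(face).save(out / f"face_{pid}.png")
        write_pulse_csv(pulse, out / f"pulse_{pid}.csv")
        rows.append({"patient_id": pid, "tongue_path": f"tongue_{pid}.png",
                     "face_path": f"face_{pid}.png",
                     "pulse_path": f"pulse_{pid}.csv",
                     "label": cls, "split": splits[i]})
        clin_rows.append(clinical.rename(pid))
        gt_pulse[pid] = truth

    rows_df = pd.DataFrame(rows, columns=["patient_id", "tongue_path", "face_path",
                                          "pulse_path", "label", "split"])
    clinical_df = pd.DataFrame(clin_rows)
    clinical_df.index.name = "patient_id"
    rows_df.to_csv(out / "manifest.csv", index=False)
    clinical_df.reset_index().to_csv(out / "clinical.csv", index=False)

    informative = (list(spec.clinical_effects.keys()) + BINARY_FACTORS)
    truth = GroundTruth(labels={f"P{i + 1:04d}": int(labels[i]) for i in range(n)},
                        pulse=gt_pulse, informative_features=informative)
    truth.to_json(out / "ground_truth.json")
    manifest = CohortManifest(rows=rows_df, clinical=clinical_df, root=out)
    return manifest, truth
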