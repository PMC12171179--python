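"""Training loop, evaluation and the ablation harness.

The entry point for a cohort directory is :func:`assemble_dataset`, which
turns a manifest into the per-modality arrays the network consumes: images
scaled to [0, 1] in channel-first layout, the preprocessed 6-s pulse segment
z-scored per sequence, the 15 extracted pulse parameters and the 15 screened
clinical features min-max scaled with training-split statistics.

Ablations mirror the study protocol: seven module variants (LSTM / residual
blocks / attention toggled; when the LSTM is removed the pulse modality
enters through a dense encoder on its 15 extracted parameters), seven
modality subsets (labs always included), the six decision-layer fusion
strategies, and a learning-rate sweep over {0.001, 0.005, 0.01, 0.05}.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .io import CohortManifest, MinMaxScaler, load_image, read_pulse_csv
from .metrics import EvalReport, classification_report
from .model import ALL_MODALITIES, AWCOPClassifier
from .pulse import (FEATURE_COLUMNS, extract_stable_segment, features_table,
                    preprocess)
from .stats import select_top_features

MODULE_VARIANTS = {
    "lstm+resnet+attention": (True, True, True),
    "resnet+attention": (False, True, True),
    "lstm+attention": (True, False, True),
    "lstm+resnet": (True, True, False),
    "attention": (False, False, True),
    "resnet": (False, True, False),
    "lstm": (True, False, False),
}

DATA_ABLATION_COMBOS = [
    ("clinical", "tongue"),
    ("clinical", "face"),
    ("clinical", "pulse"),
    ("clinical", "tongue", "face"),
    ("clinical", "tongue", "pulse"),
    ("clinical", "face", "pulse"),
    ("clinical", "tongue", "face", "pulse"),
]

LR_GRID = (0.001, 0.005, 0.01, 0.05)


@dataclasses.dataclass
class TrainSpec:
    epochs: int = 30
    batch_size: int = 16
    learning_rate: float = 0.001
    early_stop_patience: int = 8
    seed: int = 0

    def __post_init__(self):
        if self.learning_rate < 0:
            raise ValueError("learning_rate must be non-negative")


def assemble_dataset(manifest: CohortManifest, image_size=(64, 64),
                     k_clinical: int = 15, seed: int = 0) -> dict:
    """Build the model-ready array bundle from a cohort directory.

    Feature screening and all scaling statistics use the training split
    only. Returns a dict with keys ``tongue``, ``face``, ``pulse``,
    ``pulse_feats``, ``clinical``, ``y``, ``splits``, ``patient_ids``,
    ``selected_clinical`` and ``pulse_feature_names``.
    """
    ids = manifest.patient_ids
    splits = manifest.rows["split"].to_numpy()
    y = manifest.labels()
    tr = splits == "train"

    tongue = np.stack([
        load_image(manifest.root / p, image_size).transpose(2, 0, 1) / 255.0
        for p in manifest.rows["tongue_path"]])
    face = np.stack([
        load_image(manifest.root / p, image_size).transpose(2, 0, 1) / 255.0
        for p in manifest.rows["face_path"]])

    segments = []
    for p in manifest.rows["pulse_path"]:
        seg = extract_stable_segment(preprocess(read_pulse_csv(manifest.root / p)))
        x = seg.pressure
        sd = x.std()
        segments.append((x - x.mean()) / (sd if sd > 0 else 1.0))
    pulse = np.stack(segments)[..., None]  # (n, 300, 1)

    feats = features_table(manifest)
    fill = feats.iloc[tr.nonzero()[0]].mean(axis=0, skipna=True)
    feats = feats.fillna(fill)
    pf_scaler = MinMaxScaler().fit(feats.to_numpy()[tr])
    pulse_feats = pf_scaler.transform(feats.to_numpy())

    ranking = select_top_features(manifest.clinical.loc[np.array(ids)[tr]],
                                  y[tr], k=k_clinical, seed=seed)
    clin = manifest.clinical.loc[ids, ranking.selected].to_numpy(dtype=float)
    cl_scaler = MinMaxScaler().fit(clin[tr])
    clinical = cl_scaler.transform(clin)

    return {"tongue": tongue, "face": face, "pulse": pulse,
            "pulse_feats": pulse_feats, "clinical": clinical,
            "y": y, "splits": splits, "patient_ids": ids,
            "selected_clinical": ranking.selected,
            "pulse_feature_names": list(FEATURE_COLUMNS),
            "image_size": tuple(image_size)}


def _split_bundle(dataset: dict, mask: np.ndarray) -> dict:
    keys = ("tongue", "face", "pulse", "pulse_feats", "clinical")
    return {k: dataset[k][mask] for k in keys if k in dataset}


def make_classifier(dataset: dict, train_spec: TrainSpec | None = None,
                    **model_kwargs) -> AWCOPClassifier:
    spec = train_spec or TrainSpec()
    model_kwargs.setdefault("image_size", dataset["image_size"])
    model_kwargs.setdefault("seed", spec.seed)
    return AWCOPClassifier(learning_rate=spec.learning_rate, epochs=spec.epochs,
                           batch_size=spec.batch_size,
                           early_stop_patience=spec.early_stop_patience,
                           **model_kwargs)


def train(dataset: dict, train_spec: TrainSpec | None = None,
          validate: bool = True, **model_kwargs) -> AWCOPClassifier:
    """Fit a classifier on the train split (internal split for early stop)."""
    splits, y = dataset["splits"], dataset["y"]
    tr = splits == "train"
    if tr.sum() == 0 or len(np.unique(y[tr])) < 2:
        raise ValueError("training split must be non-empty with both classes")
    clf = make_classifier(dataset, train_spec, **model_kwargs)
    val = None
    internal = splits == "internal"
    if validate and internal.sum() > 0 and len(np.unique(y[internal])) == 2:
        val = (_split_bundle(dataset, internal), y[internal])
    clf.fit(_split_bundle(dataset, tr), y[tr], validation=val)
    return clf


def evaluate(clf: AWCOPClassifier, dataset: dict, split: str) -> EvalReport:
    mask = dataset["splits"] == split
    if mask.sum() == 0:
        raise ValueError(f"split {split!r} is empty")
    y = dataset["y"][mask]
    if len(np.unique(y)) < 2:
        raise ValueError(f"AUC undefined: split {split!r} has one class")
    prob = clf.predict_proba(_split_bundle(dataset, mask))[:, 1]
    return classification_report(y, prob, split=split)


def _report_rows(name: str, clf: AWCOPClassifier, dataset: dict) -> list[dict]:
    rows = []
    for split in ("internal", "external"):
        rep = evaluate(clf, dataset, split)
        rows.append({"variant": name, "split": split, **rep.as_dict()})
    return rows


def module_ablation(dataset: dict, train_spec: TrainSpec | None = None,
                    variants: list[str] | None = None,
                    **model_kwargs) -> pd.DataFrame:
    """Train the seven module variants with a shared seed and data."""
    rows = []
    for name in (variants or list(MODULE_VARIANTS)):
        use_lstm, use_resnet, use_attention = MODULE_VARIANTS[name]
        clf = train(dataset, train_spec, use_lstm=use_lstm,
                    use_resnet=use_resnet, use_attention=use_attention,
                    **model_kwargs)
        rows.extend(_report_rows(name, clf, dataset))
    return pd.DataFrame(rows)


def data_ablation(dataset: dict, train_spec: TrainSpec | None = None,
                  combos: list[tuple] | None = None,
                  **model_kwargs) -> pd.DataFrame:
    """Train the stated modality subsets; labs are always included."""
    rows = []
    for combo in (combos or DATA_ABLATION_COMBOS):
        mods = tuple(m for m in ALL_MODALITIES if m in combo)
        clf = train(dataset, train_spec, modalities=mods, **model_kwargs)
        rows.extend(_report_rows("+".join(combo), clf, dataset))
    return pd.DataFrame(rows)


def fusion_ablation(dataset: dict, train_spec: TrainSpec | None = None,
                    **model_kwargs) -> pd.DataFrame:
    """Same branches and seed; decision-layer strategy varied over six."""
    from .model import FUSION_STRATEGIES
    rows = []
    for strategy in FUSION_STRATEGIES:
        clf = train(dataset, train_spec, fusion=strategy, **model_kwargs)
        rows.extend(_report_rows(strategy, clf, dataset))
    return pd.DataFrame(rows)


def lr_sweep(dataset: dict, train_spec: TrainSpec | None = None,
             rates: tuple = LR_GRID, **model_kwargs) -> dict[float, dict]:
    """Per-rate training curves (loss per epoch, fusion-weight trajectory)."""
    spec = train_spec or TrainSpec()
    curves = {}
    for lr in rates:
        run_spec = dataclasses.replace(spec, learning_rate=lr)
        clf = train(dataset, run_spec, validate=False, **model_kwargs)
        curves[lr] = {"loss": clf.history_["loss"],
                      "fusion_weights": clf.history_["fusion_weights"]}
    return curves
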