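"""Model interpretability: Grad-CAM for the image branches and input-gradient
saliency with top-20% marking for the pulse branch.

Grad-CAM uses the output of the last residual block (the final convolutional
feature map): channel weights are the spatially averaged gradients of the
target-class logit, the map is the rectified weighted sum of feature maps,
bilinearly upsampled to the input size and min-max normalized. A flat or
negative map normalizes to all zeros rather than erroring.

Plain Grad-CAM is ill-defined for the recurrent pulse branch, so waveform
importance is the per-timestep magnitude of the logit gradient with respect
to the input segment (``gradient``; ``gradient_x_input`` optional), and the
top 20% of timesteps by importance are marked (ceil count, ties broken by
the earlier index) — 60 points of a 300-sample segment.

Saliency never mutates model state: gradients are cleared afterwards and
parameters are untouched.
"""

from __future__ import annotations

import dataclasses
import json
import math
from pathlib import Path

import numpy as np
from scipy import ndimage

from .model import AWCOPClassifier, _as_tensors

MARK_FRACTION = 0.20


@dataclasses.dataclass
class SaliencyMap2D:
    heat: np.ndarray          # (H, W) in [0, 1]
    target_class: int
    source_layer: str


@dataclasses.dataclass
class PulseSaliency:
    importance: np.ndarray    # per-timestep importance, length = segment
    marked_indices: np.ndarray
    target_class: int


def _single(batch: dict, keys: list[str]) -> dict:
    out = {}
    for k in keys:
        arr = np.asarray(batch[k])
        out[k] = arr[None] if arr.ndim == (2 if k == "pulse" else
                                           3 if k in ("tongue", "face") else 1) else arr
    return out


def _forward_backward(clf: AWCOPClassifier, tensors: dict,
                      target_class: int | None, contrast: bool) -> int:
    clf.net_.eval()
    clf.net_.zero_grad()
    logits, _ = clf.net_(tensors)
    target = (int(np.argmax(logits.data[0])) if target_class is None
              else int(target_class))
    seed = np.zeros_like(logits.data)
    seed[0, target] = 1.0
    if contrast:
        # two-logit head: evidence shared by both classes cancels only in
        # the margin, so the discriminative map differentiates the logit
        # difference rather than the raw class score
        seed[0, 1 - target] = -1.0
    logits.backward(seed)
    return target


def cam_from_gradients(activations: np.ndarray, gradients: np.ndarray,
                       out_size: tuple[int, int]) -> np.ndarray:
    """Grad-CAM arithmetic: channel weights = spatially averaged gradients;
    map = ReLU of the weighted feature-map sum, bilinearly upsampled to
    ``out_size`` and min-max normalized (flat maps normalize to zeros)."""
    alpha = gradients.mean(axis=(1, 2))           # GAP of gradients
    cam = np.maximum((alpha[:, None, None] * activations).sum(axis=0), 0.0)
    h, w = out_size
    cam = ndimage.zoom(cam, (h / cam.shape[0], w / cam.shape[1]), order=1)
    span = cam.max() - cam.min()
    if span <= 1e-12 * max(abs(cam.max()), 1.0):  # flat map -> all zeros
        return np.zeros_like(cam)
    return (cam - cam.min()) / span


def gradcam_image(clf: AWCOPClassifier, sample: dict, modality: str,
                  target_class: int | None = None,
                  contrast: bool = True) -> SaliencyMap2D:
    """Class activation map for one sample's tongue or face image.

    ``sample`` holds the same keys as a dataset bundle, single sample or
    batch of one. Defaults to explaining the predicted class via the logit
    margin (``contrast=False`` differentiates the raw class logit instead).
    """
    if modality not in ("tongue", "face"):
        raise ValueError("Grad-CAM applies to the image modalities only")
    if modality not in clf.modalities:
        raise ValueError(f"model was built without the {modality!r} branch")
    tensors = _as_tensors(_single(sample, clf._batch_keys()))
    target = _forward_backward(clf, tensors, target_class, contrast)
    fm = clf.net_.branches[modality].last_feature_map
    cam = cam_from_gradients(fm.data[0], fm.grad[0],
                             tuple(tensors[modality].shape[2:]))
    clf.net_.zero_grad()
    layer = "residual_block_4" if clf.use_resnet else "conv_stem"
    return SaliencyMap2D(heat=cam, target_class=target, source_layer=layer)


def mark_top_fraction(importance: np.ndarray,
                      fraction: float = MARK_FRACTION) -> np.ndarray:
    """Indices of the ceil(fraction * n) largest values, earlier index first
    on ties (stable sort on descending importance)."""
    n = len(importance)
    k = math.ceil(fraction * n)
    order = np.argsort(-np.asarray(importance), kind="stable")
    return np.sort(order[:k])


def pulse_saliency(clf: AWCOPClassifier, sample: dict,
                   target_class: int | None = None,
                   mode: str = "gradient",
                   contrast: bool = True) -> PulseSaliency:
    """Per-timestep importance of the pulse segment for the target logit."""
    if "pulse" not in clf.modalities or not clf.use_lstm:
        raise ValueError("pulse saliency needs the LSTM pulse branch")
    if mode not in ("gradient", "gradient_x_input"):
        raise ValueError("mode must be 'gradient' or 'gradient_x_input'")
    single = _single(sample, clf._batch_keys())
    tensors = _as_tensors(single)
    tensors["pulse"].requires_grad = True
    target = _forward_backward(clf, tensors, target_class, contrast)
    grad = tensors["pulse"].grad[0, :, 0]
    imp = np.abs(grad * single["pulse"][0, :, 0]) if mode == "gradient_x_input" \
        else np.abs(grad)
    clf.net_.zero_grad()
    return PulseSaliency(importance=imp,
                         marked_indices=mark_top_fraction(imp),
                         target_class=target)


def render_overlays(sample: dict, maps: dict, out_dir,
                    dpi: int = 100) -> dict[str, Path]:
    """Write PNG overlays (heat on image; pulse curve with black dots) and a
    JSON of marked indices and normalized maps. Pure visualization."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}
    meta: dict = {}
    for modality in ("tongue", "face"):
        if modality not in maps:
            continue
        sal: SaliencyMap2D = maps[modality]
        img = np.asarray(sample[modality])
        if img.ndim == 4:
            img = img[0]
        img = img.transpose(1, 2, 0)  # (H, W, 3), [0, 1]
        h, w = img.shape[:2]
        fig = plt.figure(figsize=(w / dpi, h / dpi), dpi=dpi, frameon=False)
        ax = fig.add_axes([0, 0, 1, 1])
        ax.axis("off")
        ax.imshow(img)
        ax.imshow(sal.heat, cmap="jet", alpha=0.45, vmin=0, vmax=1)
        path = out / f"{modality}_cam.png"
        fig.savefig(path, dpi=dpi)
        plt.close(fig)
        written[modality] = path
        meta[f"{modality}_cam"] = {"target_class": sal.target_class,
                                   "heat": np.round(sal.heat, 4).tolist()}
    if "pulse" in maps:
        sal: PulseSaliency = maps["pulse"]
        seg = np.asarray(sample["pulse"])
        if seg.ndim == 3:
            seg = seg[0]
        seg = seg[:, 0]
        fig, ax = plt.subplots(figsize=(8, 3))
        ax.plot(seg, lw=1.0, color="tab:red")
        ax.plot(sal.marked_indices, seg[sal.marked_indices], "k.", ms=4)
        ax.set_xlabel("sample (50 Hz)")
        ax.set_ylabel("pressure (z-scored)")
        fig.tight_layout()
        path = out / "pulse_saliency.png"
        fig.savefig(path, dpi=dpi)
        plt.close(fig)
        written["pulse"] = path
        meta["pulse_saliency"] = {
            "target_class": sal.target_class,
            "marked_indices": sal.marked_indices.tolist(),
            "n_marked": int(len(sal.marked_indices)),
        }
    (out / "saliency.json").write_text(json.dumps(meta))
    written["json"] = out / "saliency.json"
    return written
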