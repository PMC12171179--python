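"""Group-difference screening, random-forest feature selection and the five
classical baselines (logistic regression, random forest, SVM, KNN, XGBoost).

Numeric features are compared with a two-sided Mann-Whitney U test (normal
approximation with tie correction) and summarized as median (Q1, Q3); binary
features with a 2x2 chi-square without continuity correction and summarized
as counts. Raw p-values are reported, with an optional Benjamini-Hochberg
column as a clearly labelled extension.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC
from skimage import color as skcolor
from xgboost import XGBClassifier

from .io import CohortManifest, load_image
from .metrics import EvalReport, classification_report
from .pulse import features_table
from .simulate import face_region_masks, tongue_coating_mask, tongue_mask


@dataclasses.dataclass
class GroupComparison:
    feature: str
    test: str                 # mann_whitney_u | chi_square
    statistic: float
    p_value: float
    group0_summary: str
    group1_summary: str
    note: str = ""


@dataclasses.dataclass
class ImportanceRanking:
    ranking: list[tuple[str, float]]  # ordered by importance, descending
    selected: list[str]               # top-k names


def _is_binary(col: pd.Series) -> bool:
    return set(pd.unique(col.dropna())).issubset({0, 1, 0.0, 1.0})


def _median_iqr(x: np.ndarray) -> str:
    q1, med, q3 = np.percentile(x, [25, 50, 75])
    return f"{med:.2f} ({q1:.2f}, {q3:.2f})"


def benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    p = np.asarray(p, dtype=float)
    adj = np.full_like(p, np.nan)
    finite = np.flatnonzero(np.isfinite(p))
    m = len(finite)
    order = finite[np.argsort(p[finite])]
    prev = 1.0
    for rank_from_end, i in enumerate(order[::-1]):
        rank = m - rank_from_end
        prev = min(prev, min(p[i] * m / rank, 1.0))
        adj[i] = prev
    return adj


def compare_groups(clinical: pd.DataFrame, labels: np.ndarray,
                   bh_column: bool = False) -> list[GroupComparison]:
    """Per-feature two-group comparison in the style of a Table-1 screen."""
    labels = np.asarray(labels, dtype=int)
    if (labels == 0).sum() == 0 or (labels == 1).sum() == 0:
        raise ValueError("both groups must be non-empty")
    results = []
    for name in clinical.columns:
        col = clinical[name].to_numpy(dtype=float)
        g0, g1 = col[labels == 0], col[labels == 1]
        if _is_binary(clinical[name]):
            table = np.array([[np.sum(g0 == 1), np.sum(g0 == 0)],
                              [np.sum(g1 == 1), np.sum(g1 == 0)]], dtype=float)
            summ0 = f"{int(table[0, 0])}/{int(table[0, 1])} (yes/no)"
            summ1 = f"{int(table[1, 0])}/{int(table[1, 1])} (yes/no)"
            if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
                results.append(GroupComparison(name, "chi_square", np.nan, np.nan,
                                               summ0, summ1,
                                               note="degenerate: constant feature"))
                continue
            stat, p, _, _ = sps.chi2_contingency(table, correction=False)
            results.append(GroupComparison(name, "chi_square", float(stat),
                                           float(p), summ0, summ1))
        else:
            res = sps.mannwhitneyu(g0, g1, alternative="two-sided",
                                   method="asymptotic")
            results.append(GroupComparison(name, "mann_whitney_u",
                                           float(res.statistic), float(res.pvalue),
                                           _median_iqr(g0), _median_iqr(g1)))
    if bh_column:
        adj = benjamini_hochberg(np.array([r.p_value for r in results]))
        for r, a in zip(results, adj):
            r.note = (r.note + "; " if r.note else "") + f"p_adj_bh={a:.4g}"
    return results


def comparisons_frame(results: list[GroupComparison]) -> pd.DataFrame:
    return pd.DataFrame([dataclasses.asdict(r) for r in results])


# --------------------------------------------------------------------------

class TopKImportanceSelector(BaseEstimator, TransformerMixin):
    """Select the k most important features by random-forest impurity.

    Fitted attributes: ``ranking_`` (ordered (name, importance) pairs,
    importances sum to 1), ``selected_`` (the k chosen column names).
    """

    def __init__(self, k: int = 15, n_estimators: int = 500, seed: int = 0):
        self.k = k
        self.n_estimators = n_estimators
        self.seed = seed

    def fit(self, X: pd.DataFrame, y):
        if self.k > X.shape[1]:
            raise ValueError(f"k={self.k} exceeds {X.shape[1]} features")
        names = list(X.columns)
        rf = RandomForestClassifier(n_estimators=self.n_estimators,
                                    random_state=self.seed, n_jobs=1)
        rf.fit(X.to_numpy(dtype=float), np.asarray(y, dtype=int))
        imp = rf.feature_importances_
        order = np.argsort(-imp, kind="stable")
        self.ranking_ = [(names[i], float(imp[i])) for i in order]
        self.selected_ = [names[i] for i in order[: self.k]]
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        return X[self.selected_]


def select_top_features(clinical: pd.DataFrame, labels, k: int = 15,
                        n_estimators: int = 500, seed: int = 0) -> ImportanceRanking:
    sel = TopKImportanceSelector(k=k, n_estimators=n_estimators, seed=seed)
    sel.fit(clinical, labels)
    return ImportanceRanking(ranking=sel.ranking_, selected=sel.selected_)


# --------------------------------------------------------------------------
# image summary parameters for the classical baselines

def _region_stats(img01: np.ndarray, mask: np.ndarray, prefix: str) -> dict:
    out = {}
    spaces = {"rgb": img01, "hsv": skcolor.rgb2hsv(img01),
              "lab": skcolor.rgb2lab(img01)}
    for space, arr in spaces.items():
        pix = arr[mask]
        for ci, chan in enumerate(space):
            out[f"{prefix}_{space}_{chan}_mean"] = float(pix[:, ci].mean())
            out[f"{prefix}_{space}_{chan}_std"] = float(pix[:, ci].std())
    return out


def image_summary_features(manifest: CohortManifest,
                           image_size: tuple[int, int] = (64, 64)) -> pd.DataFrame:
    """Per-region color statistics standing in for instrument-derived
    tongue/face parameters: mean and SD per channel in RGB, HSV and L*a*b*
    for the whole tongue, the coating patch, and the three facial regions."""
    h, w = image_size
    regions_t = {"tongue_all": tongue_mask(h, w),
                 "tongue_coating": tongue_coating_mask(h, w)}
    regions_f = {f"face_{k}": v for k, v in face_region_masks(h, w).items()}
    rows = []
    for _, r in manifest.rows.iterrows():
        tongue = load_image(manifest.root / r["tongue_path"], image_size) / 255.0
        face = load_image(manifest.root / r["face_path"], image_size) / 255.0
        row = {}
        for name, mask in regions_t.items():
            row.update(_region_stats(tongue, mask, name))
        for name, mask in regions_f.items():
            row.update(_region_stats(face, mask, name))
        rows.append(row)
    return pd.DataFrame(rows, index=pd.Index(manifest.patient_ids,
                                             name="patient_id"))


def baseline_feature_table(manifest: CohortManifest, selected_clinical: list[str],
                           image_size: tuple[int, int] = (64, 64)) -> pd.DataFrame:
    """Pulse parameters + image summaries + screened labs, one row/patient."""
    pulse = features_table(manifest)
    imgs = image_summary_features(manifest, image_size)
    clin = manifest.clinical[selected_clinical]
    return pd.concat([pulse, imgs, clin], axis=1)


def _baseline_models(seed: int) -> dict:
    return {
        "logistic_regression": LogisticRegression(max_iter=2000, random_state=seed),
        "random_forest": RandomForestClassifier(n_estimators=500,
                                                random_state=seed, n_jobs=1),
        "svm": SVC(kernel="rbf", random_state=seed),
        "knn": KNeighborsClassifier(n_neighbors=5),
        "xgboost": XGBClassifier(n_estimators=100, max_depth=3,
                                 learning_rate=0.1, eval_metric="logloss",
                                 random_state=seed, n_jobs=1),
    }


def run_baselines(features: pd.DataFrame, labels: np.ndarray, splits: np.ndarray,
                  seed: int = 0) -> dict[str, dict[str, EvalReport]]:
    """Fit the five classical models on the train split; evaluate both
    held-out splits. Features are standardized with train-split statistics."""
    labels = np.asarray(labels, dtype=int)
    splits = np.asarray(splits)
    x = features.to_numpy(dtype=float)
    tr = splits == "train"
    if tr.sum() == 0:
        raise ValueError("empty training split")
    mu, sd = x[tr].mean(axis=0), x[tr].std(axis=0)
    sd = np.where(sd > 0, sd, 1.0)
    xs = (x - mu) / sd
    out: dict[str, dict[str, EvalReport]] = {}
    for name, model in _baseline_models(seed).items():
        model.fit(xs[tr], labels[tr])
        out[name] = {}
        for split in ("internal", "external"):
            m = splits == split
            if hasattr(model, "predict_proba"):
                prob = model.predict_proba(xs[m])[:, 1]
            else:  # margin classifiers: sigmoid of the decision margin keeps
                # the 0.5 probability threshold at the decision boundary
                prob = sps.logistic.cdf(model.decision_function(xs[m]))
            out[name][split] = classification_report(labels[m], prob, split=split)
    return out
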