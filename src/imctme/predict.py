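"""Clinical-outcome prediction from core-level features.

The framework mirrors a transfer-learning design: per-channel image
embeddings (or cell-type frequency vectors, or clinical covariates) are
reduced by mini-batch sparse PCA to a small number of components and
classified with an RBF-kernel support vector machine under k-fold
cross-validation.  Imbalanced training folds are balanced by random
oversampling; dimensionality reduction and oversampling are fit on the
training portion of each fold only, so held-out cores never leak into
the fitted artifacts.  Folds are stratified by class and grouped by
patient (both cores of a two-core patient land in the same fold).

Scores are compared against the baseline prediction score: the accuracy
of always predicting the modal class.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.decomposition import MiniBatchSparsePCA
from sklearn.metrics import precision_score, recall_score
from sklearn.model_selection import StratifiedGroupKFold, StratifiedKFold
from sklearn.svm import SVC

from .backbones import get_backbone
from .stacks import CoreImageStack


# ---------------------------------------------------------------------------
# Feature sources


def scale_channel(img: np.ndarray, percentile: float = 99.0) -> np.ndarray:
    """Per-channel scaling to [0, 1] by the channel's 99th percentile
    (network-input preprocessing)."""
    img = np.asarray(img, dtype=np.float64)
    q = np.percentile(img, percentile)
    if q <= 0:
        return np.zeros_like(img)
    return np.clip(img / q, 0.0, 1.0)


def embed_channels(
    stack: CoreImageStack,
    backbone,
    channel_subset: list[str] | None = None,
) -> np.ndarray:
    """Embed selected channels and concatenate in panel (stack) order."""
    if isinstance(backbone, str):
        backbone = get_backbone(backbone)
    names = stack.channel_names if channel_subset is None else list(channel_subset)
    missing = [n for n in names if n not in stack.channels]
    if missing:
        raise KeyError(f"channels not in stack: {missing}")
    ordered = [n for n in stack.channel_names if n in names]
    return np.concatenate([backbone.embed(scale_channel(stack[n])) for n in ordered])


def channel_embeddings(
    stacks: list[CoreImageStack], backbone, channels: list[str] | None = None
) -> dict[str, np.ndarray]:
    """Per-marker embedding matrices (n_cores x output_dim), computed
    once so marker rankings and subset searches can reuse them."""
    if isinstance(backbone, str):
        backbone = get_backbone(backbone)
    if channels is None:
        channels = stacks[0].channel_names
    out = {}
    for name in channels:
        out[name] = np.stack([backbone.embed(scale_channel(s[name])) for s in stacks])
    return out


def features_from_subset(embeddings: dict[str, np.ndarray], subset: list[str]) -> np.ndarray:
    missing = [m for m in subset if m not in embeddings]
    if missing:
        raise KeyError(f"no embeddings for: {missing}")
    return np.concatenate([embeddings[m] for m in subset], axis=1)


# ---------------------------------------------------------------------------
# Training and evaluation


def baseline_score(labels) -> float:
    """Modal-class fraction: accuracy of always predicting the majority."""
    labels = pd.Series(list(labels))
    if len(labels) == 0:
        raise ValueError("empty labels")
    return labels.value_counts().iloc[0] / len(labels)


def random_oversample(
    X: np.ndarray, y: np.ndarray, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Resample every class (with replacement) up to the majority count,
    so training classes end up exactly balanced."""
    y = np.asarray(y)
    classes, counts = np.unique(y, return_counts=True)
    target = counts.max()
    idx = []
    for cls, cnt in zip(classes, counts):
        members = np.flatnonzero(y == cls)
        idx.append(members)
        if cnt < target:
            idx.append(rng.choice(members, size=target - cnt, replace=True))
    idx = np.concatenate(idx)
    return X[idx], y[idx]


def reduce_features(
    X_train: np.ndarray,
    n_components: int = 9,
    seed: int = 0,
    X_test: np.ndarray | None = None,
):
    """Mini-batch sparse PCA fit on training cores only.

    Returns (reducer, train_reduced, test_reduced).  The transform of
    held-out cores uses the components learned from training cores.
    """
    n, d = X_train.shape
    if n_components > min(n, d):
        raise ValueError(
            f"n_components={n_components} exceeds min(n_samples={n}, n_features={d})"
        )
    reducer = MiniBatchSparsePCA(
        n_components=n_components,
        random_state=seed,
        batch_size=min(50, n),
        max_iter=100,
    )
    Ztr = reducer.fit_transform(X_train)
    Zte = reducer.transform(X_test) if X_test is not None else None
    return reducer, Ztr, Zte


@dataclass
class PredictionReport:
    target: str
    source: str
    fold_accuracies: list[float]
    mean_accuracy: float
    accuracy_sd: float
    precision: float
    recall: float
    baseline: float
    n_components: int
    seed: int
    predictions: pd.Series = field(repr=False)  # pooled out-of-fold predictions
    fold_details: list[dict] = field(default_factory=list, repr=False)

    def to_dict(self) -> dict:
        return {
            "target": self.target,
            "source": self.source,
            "fold_accuracies": [round(a, 6) for a in self.fold_accuracies],
            "mean_accuracy": round(self.mean_accuracy, 6),
            "accuracy_sd": round(self.accuracy_sd, 6),
            "precision": round(self.precision, 6),
            "recall": round(self.recall, 6),
            "baseline": round(self.baseline, 6),
            "n_components": self.n_components,
            "seed": self.seed,
        }


def make_folds(
    y: np.ndarray, groups: np.ndarray | None, k: int, seed: int
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Class-stratified folds, grouped by patient when groups are given."""
    if groups is not None:
        splitter = StratifiedGroupKFold(n_splits=k, shuffle=True, random_state=seed)
        return list(splitter.split(np.zeros(len(y)), y, groups))
    splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    return list(splitter.split(np.zeros(len(y)), y))


def train_eval(
    features: np.ndarray,
    labels,
    groups=None,
    k: int = 5,
    seed: int = 0,
    n_components: int = 9,
    C: float = 1.0,
    target: str = "",
    source: str = "",
    folds: list[tuple[np.ndarray, np.ndarray]] | None = None,
) -> PredictionReport:
    """k-fold cross-validated sparse-PCA + RBF-SVM evaluation.

    Per fold: fit the reducer on the training cores, oversample training
    classes to parity, fit the SVM (RBF kernel, C, gamma = 'scale'), and
    score the held-out fold.  ``folds`` may be supplied to pin the split
    (used e.g. by the leakage canary); otherwise folds are stratified by
    class and grouped by patient.
    """
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels)
    if len(np.unique(y)) < 2:
        raise ValueError("need at least 2 classes")
    if folds is None:
        folds = make_folds(y, None if groups is None else np.asarray(groups), k, seed)
    accs: list[float] = []
    details: list[dict] = []
    pooled_pred = pd.Series(index=range(len(y)), dtype=object)
    for fold_i, (tr, te) in enumerate(folds):
        if len(np.unique(y[tr])) < len(np.unique(y)):
            details.append({"fold": fold_i, "valid": False, "reason": "class missing in training"})
            continue
        ncomp = min(n_components, len(tr), X.shape[1])
        reducer, Ztr, Zte = reduce_features(X[tr], ncomp, seed=seed, X_test=X[te])
        rng = np.random.default_rng((seed, fold_i))
        Zb, yb = random_oversample(Ztr, y[tr], rng)
        clf = SVC(kernel="rbf", C=C, gamma="scale")
        clf.fit(Zb, yb)
        pred = clf.predict(Zte)
        pooled_pred.iloc[te] = pred
        accs.append(float((pred == y[te]).mean()))
        details.append(
            {
                "fold": fold_i,
                "valid": True,
                "accuracy": accs[-1],
                "n_train": len(tr),
                "n_test": len(te),
                "components_digest": hashlib.sha256(
                    np.ascontiguousarray(reducer.components_).tobytes()
                ).hexdigest(),
            }
        )
    if not accs:
        raise ValueError("no valid folds")
    evaluated = pooled_pred.notna()
    prec = precision_score(
        y[evaluated.to_numpy()], pooled_pred[evaluated].to_numpy(), average="macro", zero_division=0
    )
    rec = recall_score(
        y[evaluated.to_numpy()], pooled_pred[evaluated].to_numpy(), average="macro", zero_division=0
    )
    return PredictionReport(
        target=target,
        source=source,
        fold_accuracies=accs,
        mean_accuracy=float(np.mean(accs)),
        accuracy_sd=float(np.std(accs, ddof=1)) if len(accs) > 1 else 0.0,
        precision=float(prec),
        recall=float(rec),
        baseline=baseline_score(y),
        n_components=n_components,
        seed=seed,
        predictions=pooled_pred,
        fold_details=details,
    )


def rank_markers(
    stacks: list[CoreImageStack],
    labels,
    backbone,
    k: int = 5,
    seed: int = 0,
    groups=None,
    n_components: int = 9,
    embeddings: dict[str, np.ndarray] | None = None,
    channels: list[str] | None = None,
) -> pd.DataFrame:
    """Predictive performance of each single marker's spatial signal.

    One cross-validated run per channel; markers are ranked by mean
    accuracy, ties broken by panel order.
    """
    if embeddings is None:
        embeddings = channel_embeddings(stacks, backbone, channels)
    names = list(embeddings)
    if len(names) < 2:
        raise ValueError("need at least 2 markers to rank")
    rows = []
    for order, name in enumerate(names):
        rep = train_eval(
            embeddings[name], labels, groups=groups, k=k, seed=seed,
            n_components=n_components, source=f"raw:{name}",
        )
        rows.append(
            {"marker": name, "mean_accuracy": rep.mean_accuracy,
             "precision": rep.precision, "recall": rep.recall, "panel_order": order}
        )
    df = pd.DataFrame(rows)
    df = df.sort_values(
        ["mean_accuracy", "panel_order"], ascending=[False, True], kind="stable"
    ).reset_index(drop=True)
    return df


def evaluate_subsets(
    stacks: list[CoreImageStack],
    labels,
    subsets: list[list[str]],
    backbone,
    k: int = 5,
    seed: int = 0,
    groups=None,
    n_components: int = 9,
    embeddings: dict[str, np.ndarray] | None = None,
) -> pd.DataFrame:
    """Cross-validated performance of each channel subset."""
    if any(len(s) == 0 for s in subsets):
        raise ValueError("subsets must be non-empty")
    if embeddings is None:
        needed = sorted({m for s in subsets for m in s})
        embeddings = channel_embeddings(stacks, backbone, needed)
    rows = []
    for subset in subsets:
        rep = train_eval(
            features_from_subset(embeddings, subset), labels, groups=groups,
            k=k, seed=seed, n_components=n_components,
            source="raw:" + "+".join(subset),
        )
        rows.append(
            {"subset": "+".join(subset), "n_markers": len(subset),
             "mean_accuracy": rep.mean_accuracy, "precision": rep.precision,
             "recall": rep.recall, "baseline": rep.baseline}
        )
    return pd.DataFrame(rows)


def two_core_agreement(predictions: pd.Series, patients: pd.Series) -> float:
    """Fraction of two-core patients whose cores get the same predicted
    label (an intratumour-heterogeneity consistency report)."""
    df = pd.DataFrame({"pred": predictions, "patient": patients}).dropna()
    agree = []
    for _, grp in df.groupby("patient"):
        if len(grp) == 2:
            agree.append(grp["pred"].iloc[0] == grp["pred"].iloc[1])
    if not agree:
        raise ValueError("no two-core patients")
    return float(np.mean(agree))
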