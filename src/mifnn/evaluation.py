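"""ROC/AUC computation and the component-ablation harness.

The ablation harness mirrors the controlled comparisons used to attribute
performance to each component of the fusion model: single-branch features
with a plain SVM or a small feed-forward head, fused features with and
without swarm-tuned SVM hyperparameters, and the full model with and without
the bi-LSTM/attention stage.  All variants at a given seed share the same
train/test split.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from sklearn.metrics import roc_curve
from sklearn.model_selection import StratifiedShuffleSplit

from .chem_io import MoleculeRecord
from .fusion_head import (
    ModelConfig,
    TrainConfig,
    extract_features,
    predict_logits,
    prepare_molecules,
    train_extractor,
)
from .pso_svm import PSOConfig, pso_optimize, svm_fit


class SingleClassLabels(ValueError):
    pass


class UnknownVariant(KeyError):
    pass


@dataclass
class ROCResult:
    """An ROC curve (monotone TP/FP-rate points) and its trapezoidal area."""

    thresholds: np.ndarray
    tpr: np.ndarray
    fpr: np.ndarray
    auc: float


def roc_auc(scores, labels) -> ROCResult:
    """ROC curve over all distinct score thresholds and its area.

    The area is computed by the trapezoid rule, which credits tied
    positive-negative score pairs with 1/2 — equivalent to the normalized
    Mann-Whitney U statistic.
    """
    y = np.asarray(labels, dtype=int)
    s = np.asarray(scores, dtype=np.float64)
    if len(np.unique(y)) < 2:
        raise SingleClassLabels("ROC requires both classes present")
    fpr, tpr, thresholds = roc_curve(y, s, drop_intermediate=False)
    auc = float(np.trapezoid(tpr, fpr))
    return ROCResult(thresholds=thresholds, tpr=tpr, fpr=fpr, auc=auc)


ABLATION_VARIANTS = (
    "morgan+svm",
    "morgan+ffn",
    "directed+svm",
    "directed+ffn",
    "fusion+svm",
    "fusion+pso-svm",
    "mifnn-no-bilstm",
    "mifnn-full",
)

_SINGLE_BRANCH = {"morgan+svm", "morgan+ffn", "directed+svm", "directed+ffn"}
_FUSED = set(ABLATION_VARIANTS) - _SINGLE_BRANCH


def _variant_model_config(variant: str, base: ModelConfig) -> ModelConfig:
    if variant.startswith("morgan"):
        return replace(base, use_mdifen=False, use_mffen=True)
    if variant.startswith("directed"):
        return replace(base, use_mdifen=True, use_mffen=False)
    if variant == "mifnn-no-bilstm":
        return replace(base, extractor=replace(base.extractor, use_bilstm=False))
    return base


def default_gamma(X: np.ndarray) -> float:
    """The 'scale' heuristic 1 / (n_features * var(X)) for the plain SVM."""
    v = float(X.var())
    return 1.0 / (X.shape[1] * v) if v > 0 else 1.0 / X.shape[1]


def _split_hash(test_idx: np.ndarray) -> str:
    return hashlib.sha256(np.sort(test_idx).astype(np.int64).tobytes()).hexdigest()[:12]


def run_ablation(
    dataset: list[MoleculeRecord],
    variant_specs: list[str],
    seeds: list[int],
    model_config: ModelConfig | None = None,
    train_config: TrainConfig | None = None,
    pso_config: PSOConfig | None = None,
    test_fraction: float = 0.2,
) -> pd.DataFrame:
    """Train and evaluate each model variant under shared per-seed splits.

    Returns a tidy table with one row per (variant, seed): the test ROC-AUC
    and a hash of the test indices (identical across variants per seed).
    """
    for v in variant_specs:
        if v not in ABLATION_VARIANTS:
            raise UnknownVariant(f"{v!r}; known variants: {ABLATION_VARIANTS}")
    base_model = model_config or ModelConfig()
    base_train = train_config or TrainConfig()
    base_pso = pso_config or PSOConfig()

    labels = np.array([r.label for r in dataset], dtype=int)
    rows = []
    for seed in seeds:
        splitter = StratifiedShuffleSplit(
            n_splits=1, test_size=test_fraction, random_state=seed
        )
        (train_idx, test_idx), = splitter.split(np.zeros(len(dataset)), labels)
        shash = _split_hash(test_idx)
        train_records = [dataset[i] for i in train_idx]
        test_records = [dataset[i] for i in test_idx]
        y_test = labels[test_idx]
        for variant in variant_specs:
            mc = _variant_model_config(variant, base_model)
            tc = replace(base_train, seed=seed)
            trained = train_extractor(train_records, tc, mc)
            prepared_test, _ = prepare_molecules(test_records, mc)
            if variant.endswith("+ffn"):
                scores = predict_logits(prepared_test, trained)
            else:
                feats_train = extract_features(train_records, trained).values
                feats_test = extract_features(prepared_test, trained).values
                y_train = np.array([r.label for r in train_records], dtype=int)
                if variant.endswith("pso-svm") or variant.startswith("mifnn"):
                    pc = replace(base_pso, seed=seed)
                    C, g, _ = pso_optimize(feats_train, y_train, pc)
                else:
                    C, g = 1.0, default_gamma(feats_train)
                model = svm_fit(feats_train, y_train, C, g)
                scores = model.decision_function(feats_test)
            rows.append(
                {
                    "variant": variant,
                    "seed": seed,
                    "auc": roc_auc(scores, y_test).auc,
                    "split_hash": shash,
                }
            )
    return pd.DataFrame(rows)
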