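"""Cell-class prediction audit.

Tests whether class labels can be predicted from experimental features,
model features, model parameters, or model parameters augmented with three
morphology-derived predictors (total capacitance, soma/dendrite capacitance
ratio, mean steady-state voltage attenuation from soma to dendritic tips).

The classifier is a linear-kernel maximum-margin classifier (class weights
inverse to class frequency) with recursive feature elimination selected by
cross-validation, evaluated by stratified five-fold cross-validation; the
confusion matrix is row-normalized (each row: fraction of that class
assigned to each predicted class).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.feature_selection import RFECV
from sklearn.metrics import confusion_matrix
from sklearn.model_selection import StratifiedKFold, cross_val_predict
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import LinearSVC

PREDICTOR_SOURCES = ("exp_features", "model_features", "model_params",
                     "model_params_plus_morph")


@dataclass
class ClassifierDataset:
    """Cells x predictors matrix with class labels."""

    matrix: np.ndarray
    predictor_names: tuple
    labels: np.ndarray
    predictor_source: str

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float)
        self.labels = np.asarray(self.labels)
        if self.predictor_source not in PREDICTOR_SOURCES:
            raise ValueError(f"unknown predictor source {self.predictor_source!r}")
        if np.isnan(self.matrix).any():
            raise ValueError("dataset contains missing values")
        classes, counts = np.unique(self.labels, return_counts=True)
        if classes.size < 2 or counts.min() < 2:
            raise ValueError("need >= 2 classes with >= 2 members each")


@dataclass
class ClassificationResult:
    overall_accuracy: float
    confusion: np.ndarray         # row-normalized
    classes: np.ndarray
    selected_predictors: tuple


def morphology_predictors(model) -> dict:
    """Three morphology-derived predictors of a built model.

    total_capacitance_pF
        sum of compartment area x Cm.
    soma_dend_cap_ratio
        somatic / dendritic capacitance (None without dendrites).
    tip_attenuation
        soma voltage-clamped 10 mV above rest; the steady-state voltage
        change at each dendritic tip, averaged and divided by 10 mV.
    """
    c_pF = model.c_nF * 1e3
    total = float(c_pF.sum())
    kinds = model.kind_of_comp
    dend = (kinds == "basal") | (kinds == "apical")
    ratio = float(c_pF[kinds == "soma"].sum() / c_pF[dend].sum()) if dend.any() else None

    atten = 1.0
    tips = _tip_compartments(model)
    if tips:
        dv = _steady_state_offset(model, 10.0)
        atten = float(np.mean([dv[i] for i in tips]) / 10.0)
    return {"total_capacitance_pF": total, "soma_dend_cap_ratio": ratio,
            "tip_attenuation": atten}


def _tip_compartments(model) -> list:
    """Last compartment of each childless dendritic section."""
    sections = model.morph.sections
    has_child = set(s.parent for s in sections if s.parent >= 0)
    return [model.last_comp_of_sec[i] for i, s in enumerate(sections)
            if s.kind in ("basal", "apical") and i not in has_child]


def _steady_state_offset(model, v_soma: float) -> np.ndarray:
    """Steady-state passive voltage offset with the soma held at ``v_soma``."""
    n = model.ncomp
    G = np.zeros((n, n))
    for i in range(1, n):
        p = model.parent[i]
        G[i, i] += model.ga[i]
        G[p, p] += model.ga[i]
        G[i, p] -= model.ga[i]
        G[p, i] -= model.ga[i]
    G += np.diag(model.gpas)
    rhs = np.zeros(n)
    # clamp row 0
    G[0, :] = 0.0
    G[0, 0] = 1.0
    rhs[0] = v_soma
    return np.linalg.solve(G, rhs)


def train_and_score(dataset: ClassifierDataset, folds: int = 5,
                    seed: int = 0, C: float = 1.0) -> ClassificationResult:
    """RFE-CV predictor selection + stratified k-fold evaluation.

    Deterministic given ``seed`` (fold shuffling and the margin solver's
    internal state both derive from it).
    """
    X, y = dataset.matrix, dataset.labels
    classes, counts = np.unique(y, return_counts=True)
    if counts.min() < folds:
        raise ValueError(f"every class needs >= {folds} members for "
                         f"{folds}-fold stratified CV")
    scaler = StandardScaler()
    Xs = scaler.fit_transform(X)
    svc = LinearSVC(class_weight="balanced", C=C, dual=False, max_iter=5000,
                    random_state=seed)
    cv = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    selector = RFECV(svc, step=1, cv=cv, scoring="accuracy", min_features_to_select=1)
    selector.fit(Xs, y)
    keep = selector.support_
    pred = cross_val_predict(svc, Xs[:, keep], y, cv=cv)
    acc = float(np.mean(pred == y))
    cm = confusion_matrix(y, pred, labels=classes).astype(float)
    cm /= cm.sum(axis=1, keepdims=True)
    return ClassificationResult(
        overall_accuracy=acc, confusion=cm, classes=classes,
        selected_predictors=tuple(np.asarray(dataset.predictor_names)[keep]))
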