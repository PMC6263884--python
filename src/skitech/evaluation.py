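"""Evaluation protocols: leave-one-subject-out splits, sensor ablation,
confusion matrices and accuracy bookkeeping.

The shipped protocol trains only on flat-course cycles of the non-held-out
subjects and tests on the held-out subject's flat *and* natural cycles, one
split per subject.  Reports keep full 8x8 confusion matrices (rows = true,
columns = predicted, classes in code order 1-8) even when a split contains
no cycles of some class, so per-style sub-tables stay shape-compatible.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io import CLASSICAL_CODES, SKATING_CODES, TECHNIQUES, PRESETS, ValidationError, style_of
from .knn import CorrelationKNN, extract_features
from .model import CNNLSTMClassifier, ModelSpec
from .segmentation import CycleSet

__all__ = [
    "confusion", "accuracy", "loso_splits", "evaluate_split",
    "ablate_sensors", "style_separation", "EvalReport", "run_loso",
]

CLASSES = tuple(sorted(TECHNIQUES))


def confusion(y_true, y_pred, classes=CLASSES) -> np.ndarray:
    """Count matrix, rows = true class, columns = predicted class."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape:
        raise ValidationError(f"length mismatch: {y_true.shape} vs {y_pred.shape}")
    lut = {c: i for i, c in enumerate(classes)}
    bad = set(np.unique(y_true)) | set(np.unique(y_pred)) if len(y_true) else set()
    if bad - set(classes):
        raise ValidationError(f"labels outside class set: {sorted(bad - set(classes))}")
    mat = np.zeros((len(classes), len(classes)), dtype=np.int64)
    ti = np.array([lut[v] for v in y_true], dtype=np.intp)
    pi = np.array([lut[v] for v in y_pred], dtype=np.intp)
    np.add.at(mat, (ti, pi), 1)
    return mat


def accuracy(mat: np.ndarray) -> float:
    total = mat.sum()
    return float(np.trace(mat) / total) if total else float("nan")


def style_separation(mat: np.ndarray, classes=CLASSES) -> float:
    """Fraction of all cycles misclassified across styles.

    Mass in the classical-true x skating-predicted block plus the converse,
    divided by the total cycle count.
    """
    classical = np.array([c in CLASSICAL_CODES for c in classes])
    skating = np.array([c in SKATING_CODES for c in classes])
    total = mat.sum()
    if total == 0:
        return 0.0
    cross = mat[np.ix_(classical, skating)].sum() + mat[np.ix_(skating, classical)].sum()
    return float(cross / total)


@dataclass
class EvalReport:
    """Per-split confusion matrices keyed by subject/course/style/config/model.

    Each entry is a dict with keys ``subject, course, style, sensor_config,
    model, confusion`` (8x8 nested list of ints).  Aggregates are always
    recomputed from the stored entries.
    """

    entries: list[dict] = field(default_factory=list)
    classes: tuple = CLASSES

    def add(self, *, subject: str, course: str, style: str, sensor_config: str,
            model: str, mat: np.ndarray) -> None:
        self.entries.append({
            "subject": subject, "course": course, "style": style,
            "sensor_config": sensor_config, "model": model,
            "confusion": np.asarray(mat, dtype=np.int64).tolist(),
        })

    def _frame(self) -> pd.DataFrame:
        rows = []
        for e in self.entries:
            mat = np.asarray(e["confusion"])
            rows.append({k: e[k] for k in ("subject", "course", "style", "sensor_config", "model")}
                        | {"n_cycles": int(mat.sum()), "accuracy": accuracy(mat)})
        return pd.DataFrame(rows)

    def summary(self) -> pd.DataFrame:
        """One row per entry with cycle counts and accuracies."""
        return self._frame()

    def select(self, **keys) -> "EvalReport":
        out = [e for e in self.entries if all(e[k] == v for k, v in keys.items())]
        return EvalReport(out, self.classes)

    def total_confusion(self, **keys) -> np.ndarray:
        sel = self.select(**keys)
        mat = np.zeros((len(self.classes), len(self.classes)), dtype=np.int64)
        for e in sel.entries:
            mat += np.asarray(e["confusion"])
        return mat

    def mean_accuracy(self, weighted: bool = False, **keys) -> float:
        """Mean accuracy over the selected split cells.

        Unweighted by default (each cell counts once, the arithmetic of the
        usual per-split tables); ``weighted=True`` weights by cycle count.
        """
        df = self.select(**keys)._frame()
        df = df[df["n_cycles"] > 0]
        if df.empty:
            return float("nan")
        if weighted:
            return float(np.average(df["accuracy"], weights=df["n_cycles"]))
        return float(df["accuracy"].mean())

    def cross_style_fraction(self, **keys) -> float:
        return style_separation(self.total_confusion(**keys), self.classes)

    def to_json(self) -> str:
        return json.dumps({"classes": list(self.classes), "entries": self.entries}, indent=1)

    @staticmethod
    def from_json(text: str) -> "EvalReport":
        d = json.loads(text)
        return EvalReport(d["entries"], tuple(d["classes"]))

    def save(self, out_dir) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "report.json").write_text(self.to_json())
        self.summary().to_csv(out / "summary.csv", index=False)
        names = [TECHNIQUES[c][0] for c in self.classes]
        for i, e in enumerate(self.entries):
            tag = "_".join(str(e[k]) for k in ("model", "sensor_config", "subject", "course", "style"))
            pd.DataFrame(e["confusion"], index=names, columns=names).to_csv(
                out / f"confusion_{i:03d}_{tag}.csv")

    @staticmethod
    def load(in_dir) -> "EvalReport":
        return EvalReport.from_json((Path(in_dir) / "report.json").read_text())


def loso_splits(cs: CycleSet, training_course: str = "flat"
                ) -> list[tuple[CycleSet, CycleSet, str]]:
    """Leave-one-subject-out splits over the subjects in a cycle set.

    For each held-out subject: train = the *other* subjects' cycles from the
    training course only; test = all of the held-out subject's cycles (flat
    and natural).  Subjects without training-course data are excluded from
    training sides with a warning.
    """
    subjects = cs.subjects
    if len(subjects) < 2:
        raise ValidationError("need at least 2 subjects for leave-one-subject-out")
    subj = cs.provenance["subject"].to_numpy()
    course = cs.provenance["course"].to_numpy()
    for s in subjects:
        if not ((subj == s) & (course == training_course)).any():
            warnings.warn(f"subject {s!r} has no {training_course}-course cycles; "
                          "it never contributes to training")
    splits = []
    for held in subjects:
        train = cs.subset((subj != held) & (course == training_course))
        test = cs.subset(subj == held)
        splits.append((train, test, held))
    return splits


def _fit_predict(train: CycleSet, test: CycleSet, model_kind: str,
                 spec: ModelSpec | None, k: int, seed: int | None) -> np.ndarray:
    if model_kind == "cnn_lstm":
        fitted = CNNLSTMClassifier(spec or ModelSpec()).fit(train, seed=seed)
        pred, _ = fitted.predict(test)
        return pred
    if model_kind == "knn":
        result = CorrelationKNN(k).fit(extract_features(train), train.labels)
        return result.predict(extract_features(test))
    raise ValidationError(f"unknown model kind {model_kind!r}")


def evaluate_split(train: CycleSet, test: CycleSet, subject: str,
                   model_kind: str = "cnn_lstm", spec: ModelSpec | None = None,
                   k: int = 5, seed: int | None = None,
                   sensor_config: str = "whole_body",
                   report: EvalReport | None = None) -> EvalReport:
    """Fit on the train side, predict the test side, and record one
    confusion matrix per (course, style) cell of the test set."""
    report = report if report is not None else EvalReport()
    pred = _fit_predict(train, test, model_kind, spec, k, seed)
    course = test.provenance["course"].to_numpy()
    style = test.provenance["style"].to_numpy()
    for c in sorted(set(course)):
        for s in sorted(set(style[course == c])):
            mask = (course == c) & (style == s)
            report.add(subject=subject, course=c, style=s, sensor_config=sensor_config,
                       model=model_kind, mat=confusion(test.labels[mask], pred[mask]))
    return report


def ablate_sensors(train: CycleSet, test: CycleSet, subject: str,
                   presets=None, model_kind: str = "cnn_lstm",
                   spec: ModelSpec | None = None, k: int = 5,
                   seed: int | None = None,
                   report: EvalReport | None = None) -> EvalReport:
    """Evaluate one split under each sensor configuration.

    Cycle boundaries are shared across configurations by construction:
    segmentation ran on the reference channel before tensorization, and the
    ablation merely column-subsets the stored tensors.
    """
    report = report if report is not None else EvalReport()
    presets = list(PRESETS.values()) if presets is None else presets
    for cfg in presets:
        evaluate_split(train.select_channels(cfg), test.select_channels(cfg), subject,
                       model_kind=model_kind, spec=spec, k=k, seed=seed,
                       sensor_config=cfg.name, report=report)
    return report


def run_loso(cs: CycleSet, model_kind: str = "cnn_lstm",
             spec: ModelSpec | None = None, k: int = 5, seed: int | None = None,
             sensor_config: str = "whole_body",
             training_course: str = "flat") -> EvalReport:
    """Leave-one-subject-out evaluation over every subject in the set."""
    report = EvalReport()
    for train, test, held in loso_splits(cs, training_course):
        evaluate_split(train, test, held, model_kind=model_kind, spec=spec, k=k,
                       seed=seed, sensor_config=sensor_config, report=report)
    return report
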