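"""Cross-condition generalization (cross-decoding).

The classifier is trained on all samples of one condition and tested on all
samples of the other -- no folds -- in both directions, and the headline
metric is the average of the two directional accuracies.  Above-chance
generalization across formats (dot arrays vs Arabic digits) or across tasks
(identify vs compare) indicates condition-invariant numerosity patterns.

The suite mirrors the study's analyses: format generalization collapsed
across tasks (40 trials per class at default design), task generalization
collapsed across formats, and the restricted within-task / within-format
variants (20 trials per class).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dataset import FORMATS, TASKS, PatternDataset
from .decoding import ConfusionMatrix, decode
from .lda import ShrinkageLDA


@dataclass
class GeneralizationResult:
    train_condition: dict
    test_condition: dict
    accuracy_ab: float
    accuracy_ba: float
    confusion_ab: ConfusionMatrix
    confusion_ba: ConfusionMatrix
    sanity_mode: bool = False

    @property
    def accuracy_mean(self) -> float:
        return (self.accuracy_ab + self.accuracy_ba) / 2.0


def _direction(ds: PatternDataset, cond_train: dict, cond_test: dict,
               shrinkage: float) -> tuple[float, ConfusionMatrix]:
    train = ds.select_trials(**cond_train)
    test = ds.select_trials(**cond_test)
    y_tr = train.labels["numerosity"].to_numpy()
    y_te = test.labels["numerosity"].to_numpy()
    classes_tr = np.unique(y_tr)
    classes_te = np.unique(y_te)
    if not np.array_equal(classes_tr, classes_te):
        raise ValueError(
            f"label sets differ between conditions: {classes_tr.tolist()} "
            f"vs {classes_te.tolist()}"
        )
    model = ShrinkageLDA(shrinkage=shrinkage).fit(train.betas, y_tr)
    pred = model.predict(test.betas)
    counts = np.zeros((classes_tr.size, classes_tr.size))
    pos = {c: i for i, c in enumerate(classes_tr)}
    for t, p in zip(y_te, pred):
        counts[pos[t], pos[p]] += 1
    cm = ConfusionMatrix(labels=classes_tr, counts=counts,
                         fold_accuracies=[float(np.mean(pred == y_te))])
    return float(np.mean(pred == y_te)), cm


def cross_generalize(
    ds: PatternDataset,
    condition_a: dict,
    condition_b: dict,
    shrinkage: float = 0.01,
) -> GeneralizationResult:
    """Train on all samples of one condition, test on the other, both ways.

    When the two conditions are identical the result is the training-set
    self-accuracy and is flagged as ``sanity_mode``.
    """
    if not ds.normalized:
        raise ValueError("dataset must be z-normalized before decoding")
    sanity = condition_a == condition_b
    acc_ab, cm_ab = _direction(ds, condition_a, condition_b, shrinkage)
    acc_ba, cm_ba = _direction(ds, condition_b, condition_a, shrinkage)
    return GeneralizationResult(
        train_condition=condition_a, test_condition=condition_b,
        accuracy_ab=acc_ab, accuracy_ba=acc_ba,
        confusion_ab=cm_ab, confusion_ba=cm_ba, sanity_mode=sanity,
    )


def generalization_suite(
    patterns: dict[tuple[str, str], PatternDataset],
    shrinkage: float = 0.01,
    include_restricted: bool = True,
) -> pd.DataFrame:
    """Run the full cross-decoding battery per participant x region.

    Rows carry ``analysis`` in {format_generalization, task_generalization,
    format_within_task:<task>, task_within_format:<format>}, the directional
    accuracies, and their mean (the headline metric).
    """
    rows = []
    missing = []
    for (pid, roi), ds in sorted(patterns.items()):
        specs: list[tuple[str, dict, dict]] = [
            ("format_generalization",
             {"format": FORMATS[0]}, {"format": FORMATS[1]}),
            ("task_generalization",
             {"task": TASKS[0]}, {"task": TASKS[1]}),
        ]
        if include_restricted:
            specs += [
                (f"format_within_task:{t}",
                 {"format": FORMATS[0], "task": t},
                 {"format": FORMATS[1], "task": t})
                for t in TASKS
            ] + [
                (f"task_within_format:{f}",
                 {"task": TASKS[0], "format": f},
                 {"task": TASKS[1], "format": f})
                for f in FORMATS
            ]
        for name, cond_a, cond_b in specs:
            try:
                res = cross_generalize(ds, cond_a, cond_b, shrinkage)
            except ValueError as err:
                missing.append((pid, roi, name, str(err)))
                continue
            rows.append(dict(
                participant=pid, roi=roi, analysis=name,
                accuracy_ab=res.accuracy_ab, accuracy_ba=res.accuracy_ba,
                accuracy_mean=res.accuracy_mean,
            ))
    df = pd.DataFrame(rows)
    if missing:
        df.attrs["missing"] = missing
    return df


def within_condition_accuracy(
    ds: PatternDataset,
    condition: dict,
    shrinkage: float = 0.01,
    max_folds: int = 2000,
    seed: int | None = None,
) -> float:
    """Within-condition cross-validated accuracy, the comparison point for
    generalization accuracies."""
    return decode(ds, condition, shrinkage=shrinkage, max_folds=max_folds,
                  seed=seed).mean_accuracy
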