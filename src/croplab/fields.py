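"""Field-level crop identification by majority vote over pixel predictions.

Pixel-level classification is aggregated per agricultural field: the field
receives the label predicted for the greatest number of its pixels.  The
per-class and overall shares of correctly identified fields form the final
crop-identification accuracy table.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from croplab.classify import CLASS_ORDER, ClassifyError, ConfusionMatrix

__all__ = [
    "FieldResult",
    "FieldAccuracyTable",
    "majority_vote",
    "field_results",
    "field_accuracy",
    "field_accuracy_from_counts",
    "field_confusion",
]


@dataclass(frozen=True)
class FieldResult:
    """Outcome of majority voting in one field."""

    field_id: str
    true_class: str
    pixel_counts: dict
    majority_class: str
    correct: bool


@dataclass(frozen=True)
class FieldAccuracyTable:
    """Per-class and overall field-identification accuracy.

    ``table`` rows are per class (in the fixed reporting order) plus an
    ``overall`` row; the ``accuracy`` column keeps full precision and
    :meth:`to_rounded` renders integer percentages for tabular display.
    """

    table: pd.DataFrame

    @property
    def overall_accuracy(self) -> float:
        return float(self.table.loc[self.table["class"] == "overall", "accuracy"].iloc[0])

    def to_rounded(self) -> pd.DataFrame:
        out = self.table.copy()
        out["accuracy"] = out["accuracy"].round().astype(int)
        return out

    def to_json(self, path=None) -> str:
        payload = json.dumps(self.table.to_dict(orient="records"), indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(payload)
        return payload


def majority_vote(
    field_id: str,
    true_class: str,
    predicted: Sequence[str],
    class_order: Sequence[str] = CLASS_ORDER,
) -> FieldResult:
    """Assign a field the class predicted for the most pixels.

    Exact ties are broken by the fixed class order with a warning; the
    paper-scale pixel counts never tie in practice, so the convention only
    matters for tiny synthetic fields.
    """
    predicted = np.asarray(predicted)
    if len(predicted) == 0:
        raise ClassifyError(f"field {field_id}: no predicted pixels")
    counts = {c: int(np.sum(predicted == c)) for c in class_order}
    extra = set(np.unique(predicted)) - set(class_order)
    if extra:
        raise ClassifyError(f"field {field_id}: unknown labels {sorted(extra)}")
    best = max(counts.values())
    winners = [c for c in class_order if counts[c] == best]
    if len(winners) > 1:
        warnings.warn(
            f"field {field_id}: majority tie {winners}; using class order", stacklevel=2
        )
    return FieldResult(
        field_id=str(field_id),
        true_class=str(true_class),
        pixel_counts=counts,
        majority_class=winners[0],
        correct=winners[0] == str(true_class),
    )


def field_results(
    predictions: pd.DataFrame, class_order: Sequence[str] = CLASS_ORDER
) -> list[FieldResult]:
    """Majority-vote every field of a predictions table.

    ``predictions`` needs columns field_id, true (one class per field), and
    predicted (per pixel).
    """
    required = {"field_id", "true", "predicted"}
    if not required <= set(predictions.columns):
        raise ClassifyError(f"predictions table must have columns {sorted(required)}")
    out = []
    for fid, group in predictions.groupby("field_id", sort=True):
        true = group["true"].unique()
        if len(true) != 1:
            raise ClassifyError(f"field {fid} has conflicting true labels {true.tolist()}")
        out.append(majority_vote(fid, true[0], group["predicted"].to_numpy(), class_order))
    return out


def field_accuracy(
    results: Iterable[FieldResult], class_order: Sequence[str] = CLASS_ORDER
) -> FieldAccuracyTable:
    """Per-class and overall correctly-identified-field shares."""
    results = list(results)
    if not results:
        raise ClassifyError("no field results")
    rows = []
    for cls in class_order:
        in_class = [r for r in results if r.true_class == cls]
        correct = sum(r.correct for r in in_class)
        rows.append(
            {
                "class": cls,
                "correct": correct,
                "fields": len(in_class),
                "accuracy": 100.0 * correct / len(in_class) if in_class else float("nan"),
            }
        )
    correct_all = sum(r.correct for r in results)
    rows.append(
        {
            "class": "overall",
            "correct": correct_all,
            "fields": len(results),
            "accuracy": 100.0 * correct_all / len(results),
        }
    )
    return FieldAccuracyTable(pd.DataFrame(rows))


def field_accuracy_from_counts(
    counts: Mapping[str, tuple], class_order: Sequence[str] = CLASS_ORDER
) -> FieldAccuracyTable:
    """Accuracy table from per-class (correct, total) field counts.

    Convenience for recomputing published field-identification tables:
    synthesizes one :class:`FieldResult` per field (correct fields keep
    their class, incorrect ones get a different label) and delegates to
    :func:`field_accuracy`.
    """
    results = []
    for cls, (correct, total) in counts.items():
        if not 0 <= correct <= total:
            raise ClassifyError(f"class {cls}: correct={correct} outside [0, {total}]")
        wrong_label = next(c for c in class_order if c != cls)
        for i in range(total):
            majority = cls if i < correct else wrong_label
            results.append(
                FieldResult(
                    field_id=f"{cls}_{i}",
                    true_class=cls,
                    pixel_counts={majority: 1},
                    majority_class=majority,
                    correct=majority == cls,
                )
            )
    return field_accuracy(results, class_order)


def field_confusion(
    results: Iterable[FieldResult], class_order: Sequence[str] = CLASS_ORDER
) -> ConfusionMatrix:
    """Field-level confusion matrix induced by the majority labels."""
    results = list(results)
    index = {c: i for i, c in enumerate(class_order)}
    counts = np.zeros((len(class_order), len(class_order)), dtype=int)
    for r in results:
        counts[index[r.true_class], index[r.majority_class]] += 1
    return ConfusionMatrix(counts, tuple(class_order))
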