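"""Evaluation machinery: confusion matrices, per-class accuracy,
critical errors, safe/dangerous re-scoring and subset re-sampling.

Ground truth and predictions are zone labels 0-3 per parameter per
frame.  Accuracy is reported two ways:

* overall accuracy = trace / total of the confusion matrix (the
  headline number), and
* per-class one-vs-rest accuracy A_c = (TP_c + TN_c) / TOTAL.

The 2-class re-scoring collapses zones 0-1 to safe and 2-3 to
dangerous before scoring; merging classes can only keep or add
diagonal mass, so 2-class accuracy is never below 4-class accuracy on
the same samples.  A *critical error* is a dangerous truth (zone 2-3)
predicted safe (zone 0-1) — direction matters.

The re-sampling evaluation draws ``n_subsets`` random subsets of
``fraction`` of the samples *without replacement*, scores each subset
independently, and summarises each accuracy column with MIN / MAX /
MEAN / STD (population) plus the relative percent improvement of the
2-class mean over the 4-class mean.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .angles import PARAMETER_NAMES
from .zones import SAFE, collapse_to_binary

__all__ = [
    "LabelledSample",
    "ConfusionMatrix",
    "ClassScores",
    "SummaryRows",
    "BootstrapSummary",
    "confusion_matrix",
    "accuracy",
    "overall_accuracy",
    "to_binary",
    "critical_errors",
    "resample_eval",
    "summarize_accuracies",
    "read_labelled_csv",
    "write_labelled_csv",
    "read_subset_table",
]


class EmptyInputError(ValueError):
    """An operation that needs at least one valid sample got none."""


@dataclass(frozen=True)
class LabelledSample:
    """Ground truth and prediction zones for one frame.

    Values are zone integers 0-3; a None prediction marks a frame where
    the parameter could not be measured (absent keypoints).
    """

    frame: int
    truth: dict[str, int]
    pred: dict[str, int | None]

    def __post_init__(self) -> None:
        for z in self.truth.values():
            if z not in (0, 1, 2, 3):
                raise ValueError(f"truth zone {z} outside 0..3")
        for z in self.pred.values():
            if z is not None and z not in (0, 1, 2, 3):
                raise ValueError(f"predicted zone {z} outside 0..3")


@dataclass(frozen=True)
class ConfusionMatrix:
    """Counts[g][p]: rows are ground truth, columns are prediction."""

    parameter: str
    counts: np.ndarray  # (k, k) int array
    n_invalid: int = 0

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @property
    def n_classes(self) -> int:
        return self.counts.shape[0]

    def to_frame(self) -> pd.DataFrame:
        labels = list(range(self.n_classes))
        return pd.DataFrame(self.counts, index=labels, columns=labels).rename_axis(
            index="truth", columns="pred"
        )


@dataclass(frozen=True)
class ClassScores:
    """One-vs-rest counts for one class; TP+TN+FP+FN = TOTAL."""

    label: int | str
    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    @property
    def accuracy(self) -> float:
        return (self.tp + self.tn) / self.total


@dataclass(frozen=True)
class SummaryRows:
    """The MIN/MAX/MEAN/STD summary of one accuracy column."""

    values: tuple[float, ...]
    min: float
    max: float
    mean: float
    std: float  # population (divide by n)


@dataclass(frozen=True)
class BootstrapSummary:
    """Per-parameter 4-class and 2-class subset accuracy summaries."""

    parameter: str
    four_class: SummaryRows
    two_class: SummaryRows
    improve_pct: float  # 100 * (mean2 - mean4) / mean4


def _valid_pairs(samples: Sequence[LabelledSample], parameter: str) -> list[tuple[int, int]]:
    return [
        (s.truth[parameter], s.pred[parameter])
        for s in samples
        if parameter in s.truth and s.pred.get(parameter) is not None
    ]


def confusion_matrix(
    samples: Sequence[LabelledSample], parameter: str, n_classes: int = 4
) -> ConfusionMatrix:
    """Tabulate truth vs prediction counts; invalid predictions are
    excluded from the matrix and reported in ``n_invalid``."""
    pairs = _valid_pairs(samples, parameter)
    n_invalid = sum(1 for s in samples if parameter in s.truth) - len(pairs)
    if not pairs:
        raise EmptyInputError(f"no valid samples for parameter {parameter!r}")
    counts = np.zeros((n_classes, n_classes), dtype=int)
    for g, p in pairs:
        counts[g][p] += 1
    return ConfusionMatrix(parameter=parameter, counts=counts, n_invalid=n_invalid)


def accuracy(matrix: ConfusionMatrix) -> tuple[list[ClassScores], float]:
    """Per-class one-vs-rest scores and the overall (trace/total) accuracy."""
    total = matrix.total
    if total == 0:
        raise EmptyInputError("confusion matrix has zero total")
    scores = []
    c = matrix.counts
    for k in range(matrix.n_classes):
        tp = int(c[k, k])
        fn = int(c[k, :].sum()) - tp
        fp = int(c[:, k].sum()) - tp
        tn = total - tp - fn - fp
        scores.append(ClassScores(label=k, tp=tp, tn=tn, fp=fp, fn=fn))
    overall = float(np.trace(c)) / total
    return scores, overall


def overall_accuracy(samples: Sequence[LabelledSample], parameter: str) -> float:
    pairs = _valid_pairs(samples, parameter)
    if not pairs:
        raise EmptyInputError(f"no valid samples for parameter {parameter!r}")
    return sum(1 for g, p in pairs if g == p) / len(pairs)


def to_binary(samples: Sequence[LabelledSample]) -> list[LabelledSample]:
    """Collapse truth and prediction to safe(0)/dangerous(1) zones."""

    def collapse(z: int | None) -> int | None:
        if z is None:
            return None
        return 0 if collapse_to_binary(z) == SAFE else 1

    return [
        LabelledSample(
            frame=s.frame,
            truth={p: collapse(z) for p, z in s.truth.items()},  # type: ignore[misc]
            pred={p: collapse(z) for p, z in s.pred.items()},
        )
        for s in samples
    ]


def critical_errors(samples: Sequence[LabelledSample], parameter: str) -> int:
    """Count dangerous truths (zone 2-3) predicted safe (zone 0-1)."""
    return sum(
        1 for g, p in _valid_pairs(samples, parameter) if g >= 2 and p <= 1
    )


def summarize_accuracies(
    values: Sequence[float], values_2class: Sequence[float] | None = None
) -> tuple[SummaryRows, SummaryRows | None, float | None]:
    """MIN/MAX/MEAN/STD rows and the 2-class-over-4-class improvement.

    STD is the population standard deviation (divide by n).  Improve is
    100 * (mean_2class - mean_4class) / mean_4class, None when no
    2-class column is given.
    """

    def rows(vals: Sequence[float]) -> SummaryRows:
        if len(vals) == 0:
            raise EmptyInputError("empty accuracy list")
        arr = np.asarray(vals, dtype=float)
        lo, hi = float(arr.min()), float(arr.max())
        # a constant list has exactly zero spread; avoid one-ulp mean residue
        std = 0.0 if lo == hi else float(arr.std(ddof=0))
        return SummaryRows(
            values=tuple(arr.tolist()), min=lo, max=hi, mean=float(arr.mean()), std=std,
        )

    four = rows(values)
    if values_2class is None:
        return four, None, None
    if len(values_2class) != len(values):
        raise ValueError("4-class and 2-class lists must describe the same subsets")
    two = rows(values_2class)
    improve = 100.0 * (two.mean - four.mean) / four.mean
    return four, two, improve


def resample_eval(
    samples: Sequence[LabelledSample],
    n_subsets: int = 15,
    fraction: float = 0.5,
    seed: int | np.random.Generator = 0,
    parameters: Sequence[str] = PARAMETER_NAMES,
    replace: bool = False,
) -> dict[str, BootstrapSummary]:
    """Random-subset evaluation of 4-class and 2-class accuracy.

    Draws ``n_subsets`` subsets of size round(fraction * n), without
    replacement by default (``replace=True`` gives classic bootstrap
    resampling), scores each independently, and summarises per
    parameter.  Fully reproducible given the seed.
    """
    if n_subsets < 1:
        raise ValueError("n_subsets must be >= 1")
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    n = len(samples)
    size = int(round(fraction * n))
    if size < 1:
        raise EmptyInputError(f"subset size {size} from {n} samples is empty")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    acc4: dict[str, list[float]] = {p: [] for p in parameters}
    acc2: dict[str, list[float]] = {p: [] for p in parameters}
    for _ in range(n_subsets):
        idx = rng.choice(n, size=size, replace=replace)
        subset = [samples[i] for i in idx]
        subset2 = to_binary(subset)
        for p in parameters:
            acc4[p].append(overall_accuracy(subset, p))
            acc2[p].append(overall_accuracy(subset2, p))

    out = {}
    for p in parameters:
        four, two, improve = summarize_accuracies(acc4[p], acc2[p])
        assert two is not None and improve is not None
        out[p] = BootstrapSummary(parameter=p, four_class=four, two_class=two, improve_pct=improve)
    return out


# ---------------------------------------------------------------------------
# CSV interchange


def read_labelled_csv(
    path: str | Path, parameters: Sequence[str] = PARAMETER_NAMES
) -> list[LabelledSample]:
    """Read labelled samples: columns frame, <param>_truth, <param>_pred.

    Zone values are integers 0-3; a blank prediction cell marks an
    invalid (unmeasurable) frame for that parameter.
    """
    df = pd.read_csv(path)
    if "frame" not in df.columns:
        raise ValueError(f"{path}: missing 'frame' column")
    samples = []
    for i, row in df.iterrows():
        truth: dict[str, int] = {}
        pred: dict[str, int | None] = {}
        for p in parameters:
            tcol, pcol = f"{p}_truth", f"{p}_pred"
            if tcol in df.columns and not pd.isna(row[tcol]):
                truth[p] = int(row[tcol])
            if pcol in df.columns:
                pred[p] = None if pd.isna(row[pcol]) else int(row[pcol])
        try:
            samples.append(LabelledSample(frame=int(row["frame"]), truth=truth, pred=pred))
        except ValueError as exc:
            raise ValueError(f"{path}: row {i + 2}: {exc}") from exc
    return samples


def write_labelled_csv(
    samples: Sequence[LabelledSample],
    path: str | Path,
    parameters: Sequence[str] = PARAMETER_NAMES,
) -> Path:
    rows = []
    for s in samples:
        row: dict[str, int | None] = {"frame": s.frame}
        for p in parameters:
            row[f"{p}_truth"] = s.truth.get(p)
            row[f"{p}_pred"] = s.pred.get(p)
        rows.append(row)
    cols = ["frame"] + [f"{p}_{k}" for p in parameters for k in ("truth", "pred")]
    df = pd.DataFrame(rows, columns=cols)
    # keep zone columns integral in the file (pandas would float-ify None-bearing cols)
    df.to_csv(path, index=False, float_format="%.0f")
    return Path(path)


def read_subset_table(path: str | Path) -> pd.DataFrame:
    """Read a per-subset accuracy table: one column per parameter/scheme,
    one row per subset (for standalone summary recomputation)."""
    df = pd.read_csv(path)
    non_numeric = [c for c in df.columns if not np.issubdtype(df[c].dtype, np.number)]
    if non_numeric:
        raise ValueError(f"{path}: non-numeric accuracy columns {non_numeric}")
    return df
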