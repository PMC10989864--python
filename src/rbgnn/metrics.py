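"""Confusion-matrix statistics for the two-class RB/NRB problem.

The positive class is RB (readily biodegradable): sensitivity is the
fraction of RB molecules recovered, specificity the fraction of NRB
molecules recovered. Balanced accuracy is their mean and the error rate
its complement, which makes both invariant to which class is called
positive — the right summary for the imbalanced benchmark.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Sequence

from .errors import ContractError

logger = logging.getLogger(__name__)

LABELS = ("RB", "NRB")


@dataclass(frozen=True)
class Metrics:
    TP: int
    TN: int
    FP: int
    FN: int
    Sn: float
    Sp: float
    BA: float
    ER: float


def confusion(y_true: Sequence[str], y_pred: Sequence[str],
              positive: str = "RB") -> tuple[int, int, int, int]:
    """Count (TP, TN, FP, FN) over paired RB/NRB label sequences."""
    if len(y_true) != len(y_pred):
        raise ContractError(
            f"label sequences differ in length: {len(y_true)} vs {len(y_pred)}")
    if positive not in LABELS:
        raise ContractError(f"positive class must be one of {LABELS}")
    tp = tn = fp = fn = 0
    for t, p in zip(y_true, y_pred):
        if t not in LABELS or p not in LABELS:
            raise ContractError(f"label outside {{RB, NRB}}: {(t, p)!r}")
        if t == positive:
            if p == positive:
                tp += 1
            else:
                fn += 1
        else:
            if p == positive:
                fp += 1
            else:
                tn += 1
    return tp, tn, fp, fn


def score(conf: tuple[int, int, int, int]) -> Metrics:
    """Sn, Sp, BA and ER from a (TP, TN, FP, FN) tuple.

    A single-class evaluation leaves one ratio undefined; it and the
    derived BA/ER are reported as NaN with a warning rather than raised.
    """
    tp, tn, fp, fn = conf
    if min(tp, tn, fp, fn) < 0:
        raise ContractError("confusion counts must be non-negative")
    sn = tp / (tp + fn) if (tp + fn) > 0 else math.nan
    sp = tn / (tn + fp) if (tn + fp) > 0 else math.nan
    if math.isnan(sn) or math.isnan(sp):
        logger.warning("single-class evaluation: undefined ratio reported as NaN")
        ba = er = math.nan
    else:
        ba = (sn + sp) / 2.0
        er = 1.0 - ba
    return Metrics(TP=tp, TN=tn, FP=fp, FN=fn, Sn=sn, Sp=sp, BA=ba, ER=er)


def evaluate(y_true: Sequence[str], y_pred: Sequence[str]) -> Metrics:
    """confusion + score in one call."""
    return score(confusion(y_true, y_pred))


def write_metrics_table(rows: Iterable[tuple[str, Metrics]], path) -> None:
    """Tab-separated table (dataset, BA, Sn, Sp, ER), two decimals."""
    with open(path, "w") as fh:
        fh.write("dataset\tBA\tSn\tSp\tER\n")
        for name, m in rows:
            fh.write(f"{name}\t{m.BA:.2f}\t{m.Sn:.2f}\t{m.Sp:.2f}\t{m.ER:.2f}\n")


def format_metrics_row(name: str, m: Metrics) -> str:
    return f"{name}\t{m.BA:.2f}\t{m.Sn:.2f}\t{m.Sp:.2f}\t{m.ER:.2f}"
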