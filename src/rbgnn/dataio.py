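"""Benchmark table loading, deduplication and the RB/NRB decision rule.

The on-disk contract is a UTF-8 comma-separated table with a header and
columns ``id, smiles, label, split``: label in {RB, NRB} (case-folded on
load), split in {train, test, external}. Every accepted row carries a
parseable SMILES, which is canonicalized on load so that duplicate
detection is exact string matching on canonical forms — the same
convention the benchmark's curators used.

The decision rule mirrors the MITI-I screen it is calibrated against: a
compound is called RB when the predicted ready-biodegradability
percentage is 60% or higher, NRB below.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

from .chemgraph import canonicalize
from .errors import ContractError, FormatError, ParseError

logger = logging.getLogger(__name__)

REQUIRED_COLUMNS = ("id", "smiles", "label", "split")
LABELS = ("RB", "NRB")
SPLITS = ("train", "test", "external")

RB_THRESHOLD_PERCENT = 60.0


@dataclass(frozen=True)
class DatasetRecord:
    id: str
    smiles: str
    smiles_canonical: str
    label: str          # "RB" | "NRB"
    split: str          # "train" | "test" | "external"


@dataclass(frozen=True)
class Prediction:
    smiles: str
    probability: float

    @property
    def percent(self) -> float:
        return 100.0 * self.probability

    @property
    def klass(self) -> str:
        return classify(self.probability)


def classify(p: float) -> str:
    """RB iff the predicted percentage is >= 60 (boundary inclusive)."""
    if not 0.0 <= p <= 1.0:
        raise ContractError(f"probability {p} outside [0, 1]")
    return "RB" if 100.0 * p >= RB_THRESHOLD_PERCENT else "NRB"


def load_dataset(path) -> tuple[list[DatasetRecord], dict]:
    """Load and verify a benchmark CSV.

    Returns the accepted records plus a load report with per-class and
    per-split counts, normalized tokens and rejected rows with reasons.
    """
    frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in REQUIRED_COLUMNS if c not in frame.columns]
    if missing:
        raise FormatError(f"missing required column(s): {', '.join(missing)}")
    records: list[DatasetRecord] = []
    report: dict = {
        "total_rows": int(len(frame)), "accepted": 0,
        "rejected": [], "normalized": [],
        "per_class": {c: 0 for c in LABELS},
        "per_split": {s: 0 for s in SPLITS},
    }

    def reject(row_index, row_id, reason):
        report["rejected"].append(
            {"row": int(row_index), "id": row_id, "reason": reason})
        logger.warning("row %s (id=%s) rejected: %s", row_index, row_id, reason)

    for idx, row in frame.iterrows():
        label_raw, split_raw = row["label"].strip(), row["split"].strip()
        label, split = label_raw.upper(), split_raw.lower()
        if label not in LABELS:
            reject(idx, row["id"], f"unknown label {label_raw!r}")
            continue
        if split not in SPLITS:
            reject(idx, row["id"], f"unknown split {split_raw!r}")
            continue
        if label != label_raw or split != split_raw:
            report["normalized"].append({"row": int(idx), "id": row["id"]})
        try:
            smiles_canonical = canonicalize(row["smiles"].strip())
        except ParseError as exc:
            reject(idx, row["id"], str(exc))
            continue
        records.append(DatasetRecord(
            id=row["id"], smiles=row["smiles"].strip(),
            smiles_canonical=smiles_canonical, label=label, split=split))
        report["accepted"] += 1
        report["per_class"][label] += 1
        report["per_split"][split] += 1
    return records, report


def dedup_by_smiles(
        records: Sequence[DatasetRecord],
) -> tuple[list[DatasetRecord], dict]:
    """Collapse exact canonical-SMILES duplicates.

    Consistent duplicates keep the first occurrence; duplicate groups
    whose labels disagree are contradictory ground truth and are removed
    entirely. Everything is reported, nothing raised.
    """
    groups: dict[str, list[DatasetRecord]] = {}
    order: list[str] = []
    for rec in records:
        if rec.smiles_canonical not in groups:
            order.append(rec.smiles_canonical)
        groups.setdefault(rec.smiles_canonical, []).append(rec)
    kept: list[DatasetRecord] = []
    report = {"duplicates": [], "conflicts": []}
    for smiles in order:
        group = groups[smiles]
        labels = {r.label for r in group}
        if len(labels) > 1:
            report["conflicts"].append(
                {"smiles": smiles, "ids": [r.id for r in group],
                 "labels": sorted(labels)})
            continue
        kept.append(group[0])
        if len(group) > 1:
            report["duplicates"].append(
                {"smiles": smiles, "kept": group[0].id,
                 "removed": [r.id for r in group[1:]]})
    return kept, report


def save_dataset(records: Iterable[DatasetRecord], path) -> None:
    """Write records as the canonical CSV (canonical SMILES in ``smiles``)."""
    frame = pd.DataFrame(
        [{"id": r.id, "smiles": r.smiles_canonical, "label": r.label,
          "split": r.split} for r in records])
    frame.to_csv(path, index=False)


def prediction_record(pred: Prediction) -> dict:
    """JSON-ready prediction record."""
    return {"smiles": pred.smiles, "probability": pred.probability,
            "percent": pred.percent, "class": pred.klass}
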