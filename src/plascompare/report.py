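"""Batch evaluation, aggregation and machine-readable reports.

Turns single comparisons into JSON reports, and manifests of many sample
pairs into per-row component tables with mean/standard-deviation summaries —
the shape of a benchmarking table: one row per (sample, tool-vs-reference)
pair carrying the four normalized components, the normalized dissimilarity
and optionally the F1 score, plus a Pearson correlation helper to relate
the two accuracy measures across samples.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sp_stats

from .bins_io import BinSet, filter_min_length, read_bins, read_tsv, validate_pair
from .classic_scores import precision_recall_f1
from .dissimilarity import ComparisonResult
from .repeats import dissimilarity

logger = logging.getLogger(__name__)

DEFAULT_ALPHA = 0.5
COMPONENT_COLUMNS = ("splits", "joins", "extra", "missing", "d", "f1")


def compare_binsets(
    left: BinSet, right: BinSet, alpha: float = DEFAULT_ALPHA, min_len: int = 0
) -> tuple[ComparisonResult, BinSet, BinSet]:
    """Filter both sets at ``min_len``, validate, and compute the dissimilarity.

    Returns the result together with the filtered pair (the content the
    score actually describes, and what the normalization denominator uses).
    """
    left_f = filter_min_length(left, min_len)
    right_f = filter_min_length(right, min_len)
    validate_pair(left_f, right_f)
    return dissimilarity(left_f, right_f, alpha), left_f, right_f


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def compare_report(
    left_path: str | Path,
    right_path: str | Path,
    alpha: float = DEFAULT_ALPHA,
    min_len: int = 0,
    dedupe: bool = False,
) -> dict:
    """Full comparison of two bin TSV files as a JSON-serialisable report."""
    left_path, right_path = Path(left_path), Path(right_path)
    left = read_bins(left_path, label=left_path.stem, dedupe=dedupe)
    right = read_bins(right_path, label=right_path.stem, dedupe=dedupe)
    result, left_f, right_f = compare_binsets(left, right, alpha=alpha, min_len=min_len)
    return {
        "alpha": alpha,
        "min_length": min_len,
        "left": _input_block(left_path, left_f),
        "right": _input_block(right_path, right_f),
        "raw": {**result.components(), "total": result.total},
        "normalized": {**result.normalized_components(), "total": result.normalized_total},
        "denominator": result.denominator,
        "matchings": [
            {
                "contig": m.contig_id,
                "edges": [list(e) for e in m.edges],
                "unmatched_left": list(m.unmatched_left),
                "unmatched_right": list(m.unmatched_right),
            }
            for m in result.matchings
        ],
    }


def _input_block(path: Path, bs: BinSet) -> dict:
    return {
        "path": str(path),
        "label": bs.label,
        "sha256": _digest(path),
        "n_bins": len(bs.bins),
        "n_contig_occurrences": sum(len(cs) for cs in bs.bins.values()),
    }


def pearson(x: Sequence[float], y: Sequence[float]) -> float:
    """Product-moment correlation; rejects degenerate inputs explicitly."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 2:
        raise ValueError("pearson needs two equal-length 1-d sequences of length >= 2")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("pearson is undefined for a zero-variance sequence")
    return float(sp_stats.pearsonr(x, y).statistic)


# -- batch mode ------------------------------------------------------------


@dataclass(frozen=True)
class BatchRow:
    sample: str
    left_label: str
    right_label: str
    splits: float
    joins: float
    extra: float
    missing: float
    d: float
    f1: float | None


def read_manifest(path: str | Path) -> list[tuple[str, Path, Path]]:
    """Manifest TSV with columns sample, left, right (paths to bin TSVs)."""
    table = read_tsv(path, dtype=str)
    for col in ("sample", "left", "right"):
        if col not in table.columns:
            raise ValueError(f"{path}: manifest is missing column {col!r}")
    base = Path(path).parent
    out = []
    for row in table.itertuples(index=False):
        out.append(
            (
                str(row.sample),
                base / str(row.left) if not Path(str(row.left)).is_absolute() else Path(str(row.left)),
                base / str(row.right) if not Path(str(row.right)).is_absolute() else Path(str(row.right)),
            )
        )
    return out


def batch_summary(
    pairs: Sequence[tuple[str, Path, Path]],
    alpha: float = DEFAULT_ALPHA,
    min_len: int = 0,
    dedupe: bool = False,
    with_f1: bool = False,
) -> dict:
    """Per-pair components and aggregate mean/std over a manifest.

    Rows failing to parse or validate are excluded with a logged warning.
    ``with_f1`` marks the right side as ground truth and adds the F1 column.
    Aggregates use the sample (n−1) standard deviation, reported as 0 and
    flagged when only one row remains.
    """
    rows: list[BatchRow] = []
    failures: list[dict] = []
    for sample, left_path, right_path in pairs:
        try:
            left = read_bins(left_path, label=left_path.stem, dedupe=dedupe)
            right = read_bins(right_path, label=right_path.stem, dedupe=dedupe)
            result, left_f, right_f = compare_binsets(left, right, alpha=alpha, min_len=min_len)
            f1 = precision_recall_f1(left_f, right_f).f1 if with_f1 else None
        except (OSError, ValueError) as exc:
            logger.warning("sample %s excluded: %s", sample, exc)
            failures.append({"sample": sample, "error": str(exc)})
            continue
        rows.append(
            BatchRow(
                sample=sample,
                left_label=left.label,
                right_label=right.label,
                splits=result.normalized_splits,
                joins=result.normalized_joins,
                extra=result.normalized_extra,
                missing=result.normalized_missing,
                d=result.normalized_total,
                f1=f1,
            )
        )

    def aggregate(values: list[float]) -> dict:
        if not values:
            return {"mean": None, "std": None, "n": 0}
        arr = np.asarray(values, dtype=float)
        std = float(arr.std(ddof=1)) if len(arr) > 1 else 0.0
        return {"mean": float(arr.mean()), "std": std, "n": int(len(arr)), **(
            {"single_row": True} if len(arr) == 1 else {}
        )}

    columns = ["splits", "joins", "extra", "missing", "d"] + (["f1"] if with_f1 else [])
    aggregates = {
        col: aggregate([getattr(r, col) for r in rows if getattr(r, col) is not None])
        for col in columns
    }
    return {
        "alpha": alpha,
        "min_length": min_len,
        "rows": [r.__dict__ for r in rows],
        "aggregates": aggregates,
        "excluded": failures,
    }


def write_json(obj: dict, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    Path(path).write_text(json.dumps(obj, indent=2) + "\n", encoding="utf-8")


def write_batch_tsv(summary: dict, path: str | Path) -> None:
    """Tabular view of a batch summary (rows, then mean/std footer rows)."""
    rows = summary["rows"]
    cols = ["sample", "left_label", "right_label", "splits", "joins", "extra", "missing", "d"]
    if any(r.get("f1") is not None for r in rows):
        cols.append("f1")
    frame = pd.DataFrame(rows, columns=cols)
    footer = []
    for stat in ("mean", "std"):
        entry: dict = {"sample": stat, "left_label": "", "right_label": ""}
        for col in cols[3:]:
            agg = summary["aggregates"].get(col, {})
            entry[col] = agg.get(stat)
        footer.append(entry)
    frame = pd.concat([frame, pd.DataFrame(footer, columns=cols)], ignore_index=True)
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    frame.to_csv(path, sep="\t", index=False, float_format="%.12g")
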