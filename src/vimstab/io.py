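"""Dataset loading and report writing.

Input dialect: delimited text (comma or tab, sniffed) with a header row of
feature names and one label column selected by name or 0-based index.
Features must already be numerically encoded (integer codes are fine); the
loader rejects missing or non-numeric cells with a row/column diagnostic
rather than imputing or one-hot encoding, so feature identity stays aligned
with ranking positions.

Reports serialize to JSON (full provenance including every seed), a tidy
CSV of pairwise index values (one row per protocol/method/arm/index/pair),
and a summary CSV of means and variances per index.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .forest_vim import Dataset
from .protocols import ExperimentReport
from .stability import StabilityResult

__all__ = ["load_dataset", "save_dataset", "write_report", "read_report"]


def load_dataset(path, label_column) -> Dataset:
    """Load a delimited text file into a :class:`Dataset`.

    ``label_column`` selects the class-label column by header name (str) or
    0-based position (int).  Feature ids are assigned 1..d in the remaining
    columns' header order.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=None, engine="python")
    if isinstance(label_column, int):
        if not (0 <= label_column < df.shape[1]):
            raise ValueError(f"label column index {label_column} out of range")
        label_name = df.columns[label_column]
    else:
        if label_column not in df.columns:
            raise ValueError(f"label column {label_column!r} not found in header")
        label_name = label_column

    features = df.drop(columns=[label_name])
    if df[label_name].isna().any():
        row = int(df.index[df[label_name].isna()][0])
        raise ValueError(f"missing label at row {row}")
    na = features.isna()
    if na.to_numpy().any():
        col = na.any(axis=0).idxmax()
        row = int(na[col].idxmax())
        raise ValueError(f"missing value at row {row}, column {col!r}")
    try:
        X = features.to_numpy(dtype=float)
    except (TypeError, ValueError):
        for col in features.columns:
            coerced = pd.to_numeric(features[col], errors="coerce")
            if coerced.isna().any():
                row = int(coerced.index[coerced.isna()][0])
                raise ValueError(
                    f"non-numeric feature value at row {row}, column {col!r}"
                ) from None
        raise
    y = df[label_name].to_numpy()
    return Dataset(
        X=X,
        y=y,
        feature_ids=np.arange(1, features.shape[1] + 1),
        name=path.stem,
        feature_names=tuple(str(c) for c in features.columns),
    )


def save_dataset(data: Dataset, path) -> None:
    """Write a dataset in the same delimited format the loader reads."""
    names = data.feature_names or tuple(f"f{i}" for i in data.feature_ids)
    df = pd.DataFrame(data.X, columns=list(names))
    df["label"] = data.y
    df.to_csv(path, index=False)


def _report_dict(report: ExperimentReport) -> dict:
    return {
        "protocol": report.protocol,
        "method": report.method,
        "dataset": report.dataset_name,
        "cap": report.cap,
        "stability_sets": {
            arm: {idx: res.to_dict() for idx, res in sets.items()}
            for arm, sets in report.stability_sets.items()
        },
        "scalars": report.scalars,
        "provenance": report.provenance,
    }


def write_report(report: ExperimentReport, out_dir) -> dict:
    """Write JSON + tidy CSV + summary CSV; returns the paths written."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stem = f"{report.protocol}_{report.method.lower()}"
    paths = {
        "json": out / f"{stem}.json",
        "pairs": out / f"{stem}_pairs.csv",
        "summary": out / f"{stem}_summary.csv",
    }
    with open(paths["json"], "w") as fh:
        json.dump(_report_dict(report), fh, indent=1)

    pair_rows, summary_rows = [], []
    for arm, sets in report.stability_sets.items():
        for idx, res in sets.items():
            for pair_id, value in enumerate(res.values):
                pair_rows.append(
                    {"protocol": report.protocol, "method": report.method, "arm": arm,
                     "index": idx, "pair_id": pair_id, "value": value}
                )
            summary_rows.append(
                {"protocol": report.protocol, "method": report.method, "arm": arm,
                 "index": idx, "mean": res.mean, "variance": res.variance}
            )
    pd.DataFrame(pair_rows).to_csv(paths["pairs"], index=False)
    pd.DataFrame(summary_rows).to_csv(paths["summary"], index=False)
    return paths


def read_report(json_path) -> ExperimentReport:
    """Reload a JSON report; stability results round-trip exactly."""
    with open(json_path) as fh:
        d = json.load(fh)
    return ExperimentReport(
        protocol=d["protocol"],
        method=d["method"],
        dataset_name=d["dataset"],
        cap=d["cap"],
        stability_sets={
            arm: {idx: StabilityResult.from_dict(r) for idx, r in sets.items()}
            for arm, sets in d["stability_sets"].items()
        },
        scalars=d.get("scalars", {}),
        provenance=d.get("provenance", {}),
    )
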