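"""Predictive-accuracy metrics and the factorial-vs-neural comparison table.

For predicted values Ypre and experimental values Yexp over n runs:

    R^2  = 1 - sum (Ypre - Yexp)^2 / sum (Ym - Yexp)^2,  Ym = mean(Yexp)
    RMSE = sqrt( mean (Ypre - Yexp)^2 )
    MAE  = mean |Ypre - Yexp|

R^2 here is computed against the experimental mean (not a regression of
predicted on experimental), so it can be negative for a model worse than the
mean.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .dataset import ResponseTable
from .ffd_model import FitResult

__all__ = ["ComparisonMetrics", "metrics", "comparison_report"]


@dataclass(frozen=True)
class ComparisonMetrics:
    n: int
    mae: float
    rmse: float
    r2: float


def metrics(pred: np.ndarray, exp: np.ndarray) -> ComparisonMetrics:
    """MAE, RMSE and R^2 of predictions against experimental values."""
    pred = np.asarray(pred, dtype=float)
    exp = np.asarray(exp, dtype=float)
    if pred.shape != exp.shape or pred.ndim != 1:
        raise ValueError("pred and exp must be 1-D vectors of equal length")
    n = pred.size
    if n < 2:
        raise ValueError("need at least 2 points")
    sst = float(((exp - exp.mean()) ** 2).sum())
    if sst == 0:
        raise ValueError("experimental values have zero variance; R^2 undefined")
    err = pred - exp
    return ComparisonMetrics(
        n=n,
        mae=float(np.abs(err).mean()),
        rmse=float(np.sqrt((err**2).mean())),
        r2=1.0 - float((err**2).sum()) / sst,
    )


def comparison_report(
    table: ResponseTable,
    ffd_fits: Mapping[str, FitResult],
    ann_preds: pd.DataFrame,
    responses: Sequence[str] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-run value table and per-response metric table for both models.

    ``ann_preds`` must carry a ``run`` column aligned with the run table plus
    one column per response.  Returns ``(values, metric_table)``: the values
    frame holds experimental / factorial-model / neural-model columns per
    response over all runs; the metric frame holds MAE, RMSE and R^2 per
    model and response.
    """
    names = list(responses) if responses is not None else [
        r for r in table.response_names if r in ann_preds.columns
    ]
    if not names:
        raise ValueError("no overlapping responses between table and ann_preds")
    if "run" in ann_preds.columns and "run" in table.data.columns:
        if not np.array_equal(
            np.sort(ann_preds["run"].to_numpy()), np.sort(table.data["run"].to_numpy())
        ):
            raise ValueError("run sets of table and ann_preds differ")
        ann = ann_preds.sort_values("run").reset_index(drop=True)
        tab = table.data.sort_values("run").reset_index(drop=True)
    else:
        if len(ann_preds) != len(table):
            raise ValueError("table and ann_preds have different lengths")
        ann = ann_preds.reset_index(drop=True)
        tab = table.data.reset_index(drop=True)

    values = tab[list(table.factor_names)].copy()
    if "run" in tab.columns:
        values.insert(0, "run", tab["run"])
    metric_rows = []
    for r in names:
        if r not in ffd_fits:
            raise KeyError(f"no factorial fit provided for response {r!r}")
        exp = tab[r].to_numpy(dtype=float)
        ffd = np.asarray(ffd_fits[r].fitted, dtype=float)
        annv = ann[r].to_numpy(dtype=float)
        values[f"{r}_exp"] = exp
        values[f"{r}_ffd"] = ffd
        values[f"{r}_ann"] = annv
        for label, predv in (("FFD", ffd), ("ANN", annv)):
            m = metrics(predv, exp)
            metric_rows.append(
                {"response": r, "model": label, "MAE": m.mae, "RMSE": m.rmse, "R2": m.r2}
            )
    return values, pd.DataFrame(metric_rows)
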