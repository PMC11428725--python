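"""The 27-run extraction dataset, CSV I/O, yield and correlation analysis.

The packaged study table holds, for every combination of temperature
(20/50/80 degC), ethanol fraction (0/20/40 %) and extraction time (3/6/24 h),
the mean and standard deviation of seven responses measured on Turkey-oak
(Quercus cerris) wood-chip extracts: extraction yield (%), DPPH radical
scavenging activity (mg TE/g), FRAP (mg TE/g), total phenolic content
(mg GAE/g), total flavonoid content (mg QE/g), and condensed / hydrolyzable
tannin content (mg TAE/g).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .design import (
    STUDY_FACTORS,
    DesignPoint,
    FactorSpec,
    ModelMatrix,
    model_matrix,
)

__all__ = [
    "SchemaError",
    "ValidationError",
    "ResponseTable",
    "STUDY_RESPONSES",
    "load_table",
    "study_table",
    "ann_reference_predictions",
    "yield_percent",
    "pearson_matrix",
]

#: Response columns of the study table, in reporting order.
STUDY_RESPONSES: tuple[str, ...] = (
    "yield_pct",
    "dpph",
    "frap",
    "tpc",
    "tfc",
    "ctc",
    "htc",
)

#: Assay responses modelled by the regression / neural stages (no yield).
ASSAY_RESPONSES: tuple[str, ...] = ("dpph", "frap", "tpc", "tfc", "ctc", "htc")


class SchemaError(ValueError):
    """A required column is missing or the file is structurally unusable."""


class ValidationError(ValueError):
    """The file parsed but violates a dataset invariant."""


@dataclass
class ResponseTable:
    """A factorial-run dataset: factor settings plus response means (and SDs).

    ``data`` holds one row per run with a ``run`` column, one natural-unit
    column per factor, one column per response, and optionally ``<name>_sd``
    columns.  Coded settings are derived on demand from ``factors``.
    """

    data: pd.DataFrame
    factors: tuple[FactorSpec, ...] = STUDY_FACTORS
    response_names: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        self.factors = tuple(self.factors)
        if not self.response_names:
            skip = {"run"} | {f.name for f in self.factors}
            self.response_names = tuple(
                c for c in self.data.columns if c not in skip and not c.endswith("_sd")
            )
        self.response_names = tuple(self.response_names)
        self._validate()

    def _validate(self) -> None:
        for f in self.factors:
            if f.name not in self.data.columns:
                raise SchemaError(f"missing factor column {f.name!r}")
        for r in self.response_names:
            if r not in self.data.columns:
                raise SchemaError(f"missing response column {r!r}")
        if "run" in self.data.columns:
            runs = self.data["run"]
            if runs.duplicated().any():
                dupes = sorted(runs[runs.duplicated()].unique().tolist())
                raise ValidationError(f"duplicate run identifiers: {dupes}")
        sd_cols = [c for c in self.data.columns if c.endswith("_sd")]
        for c in sd_cols:
            if (self.data[c] < 0).any():
                raise ValidationError(f"negative standard deviation in {c!r}")

    def __len__(self) -> int:
        return len(self.data)

    @property
    def factor_names(self) -> tuple[str, ...]:
        return tuple(f.name for f in self.factors)

    def design_points(self) -> list[DesignPoint]:
        return [
            DesignPoint.from_natural(self.factors, row)
            for row in self.data[list(self.factor_names)].to_dict("records")
        ]

    def model_matrix(self) -> ModelMatrix:
        return model_matrix(self.design_points(), self.factor_names)

    def response(self, name: str) -> np.ndarray:
        if name not in self.response_names:
            raise KeyError(f"unknown response {name!r}; have {self.response_names}")
        return self.data[name].to_numpy(dtype=float)

    def to_csv(self, path: str | Path) -> None:
        self.data.to_csv(path, index=False)


def load_table(
    path: str | Path,
    factors: Sequence[FactorSpec] = STUDY_FACTORS,
    response_names: Sequence[str] | None = None,
) -> ResponseTable:
    """Read a run table from CSV (comma-separated, period decimal, header row).

    Raises
    ------
    SchemaError
        If the file is empty or a factor/response column is absent.
    ValidationError
        On duplicate run identifiers or a non-numeric cell (reported with its
        row and column).
    """
    path = Path(path)
    try:
        raw = pd.read_csv(path)
    except pd.errors.EmptyDataError as exc:
        raise SchemaError(f"{path}: empty file, no header row") from exc
    if raw.empty:
        raise SchemaError(f"{path}: no data rows")
    value_cols = [c for c in raw.columns if c != "run"]
    for col in value_cols:
        converted = pd.to_numeric(raw[col], errors="coerce")
        bad = converted.isna() & raw[col].notna()
        if bad.any():
            i = int(bad.idxmax())
            raise ValidationError(
                f"{path}: non-numeric value {raw.loc[i, col]!r} at row {i + 2}, column {col!r}"
            )
        raw[col] = converted
    return ResponseTable(
        data=raw,
        factors=tuple(factors),
        response_names=tuple(response_names) if response_names else (),
    )


def _data_path(name: str) -> Path:
    return Path(str(resources.files("extractopt").joinpath("data", name)))


def study_table() -> ResponseTable:
    """The packaged 27-run Turkey-oak extraction dataset.

    Means are the published run means; where the run table and the
    model-comparison table of the source study disagree in the last digit
    (three DPPH/FRAP cells), the higher-precision comparison-table values are
    used, which reproduce the published grand means and error metrics exactly.
    """
    table = load_table(_data_path("turkey_oak_runs.csv"), STUDY_FACTORS, STUDY_RESPONSES)
    means = table.data[list(STUDY_RESPONSES)]
    if (means < 0).any().any():
        raise ValidationError("study table contains a negative response mean")
    return table


def ann_reference_predictions() -> pd.DataFrame:
    """Published neural-network predictions for DPPH/FRAP/TPC on the 27 runs.

    The original trained network's weights are not published, so its printed
    per-run predictions are shipped as data; they make the published
    FFD-vs-ANN comparison metrics exactly recomputable without retraining.
    """
    return pd.read_csv(_data_path("ann_predictions_reference.csv"))


def yield_percent(dried_mass: float, input_mass: float) -> float:
    """Extraction yield: dried extract mass as % of milled-wood input mass."""
    if input_mass <= 0:
        raise ValueError(f"input_mass must be positive, got {input_mass}")
    if dried_mass < 0:
        raise ValueError(f"dried_mass must be nonnegative, got {dried_mass}")
    return 100.0 * dried_mass / input_mass


def pearson_matrix(table: ResponseTable, responses: Sequence[str] | None = None) -> pd.DataFrame:
    """Sample Pearson correlation matrix of response means across runs.

    Correlations are computed on the per-run means (replicate-level raw data
    are not part of the dataset).
    """
    names = list(responses) if responses is not None else list(table.response_names)
    if len(table) < 3:
        raise ValidationError("need at least 3 runs for a correlation")
    sub = table.data[names].astype(float)
    sd = sub.std(ddof=1)
    zero = [n for n in names if sd[n] == 0]
    if zero:
        raise ValidationError(f"zero-variance response(s), correlation undefined: {zero}")
    return sub.corr(method="pearson")
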