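"""Expression matrices, experimental designs, and per-protein summaries.

The per-protein differential-expression summary ``E(x)`` is deliberately
simple — the method scores *paths*, it is agnostic to how individual values
were produced:

* paired (two-channel) data: each column is a log-ratio channel and ``E(x)``
  is the arithmetic mean of the protein's row;
* unpaired (single-channel) data: ``E(x)`` is the difference between the
  logarithms of the arithmetic group means, ``log_b(mean case) -
  log_b(mean control)`` (base 2 by default).

Positive values mean over-expression, negative under-expression.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import IO, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionStudy",
    "ExpressionSummary",
    "expression_summary",
    "read_expression_table",
    "write_expression_table",
    "read_design_table",
]

PAIRED = "paired"
UNPAIRED = "unpaired"


@dataclass
class ExpressionStudy:
    """A protein x sample value matrix plus its experimental design.

    Parameters
    ----------
    values : DataFrame
        Rows indexed by protein identifier, columns by sample identifier.
    design : DataFrame
        Indexed by sample identifier; for unpaired studies it must carry a
        ``condition`` column with exactly two levels, optionally ``pair_id``
        and numeric covariate columns.
    mode : str
        ``"paired"`` (columns are log-ratio channels) or ``"unpaired"``.
    log_base : float
        Base of the logarithm used by the unpaired summary (default 2).
    """

    values: pd.DataFrame
    design: pd.DataFrame
    mode: str = PAIRED
    log_base: float = 2.0

    def __post_init__(self) -> None:
        if self.mode not in (PAIRED, UNPAIRED):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.log_base <= 0 or self.log_base == 1:
            raise ValueError("log_base must be positive and != 1")
        if list(self.values.columns) != list(self.design.index):
            raise ValueError("design rows must match value columns one-to-one")
        if self.mode == UNPAIRED:
            levels = self.condition_levels()
            if len(levels) != 2:
                raise ValueError(
                    f"unpaired design needs exactly 2 condition levels, "
                    f"got {levels}")

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    @property
    def proteins(self) -> pd.Index:
        return self.values.index

    def condition_levels(self) -> list[str]:
        if "condition" not in self.design.columns:
            raise ValueError("unpaired design requires a 'condition' column")
        return sorted(self.design["condition"].astype(str).unique())

    def with_values(self, matrix: np.ndarray) -> "ExpressionStudy":
        """Same design/mode with a replaced value matrix (used by rotation)."""
        frame = pd.DataFrame(matrix, index=self.values.index,
                             columns=self.values.columns)
        return ExpressionStudy(frame, self.design, self.mode, self.log_base)


@dataclass
class ExpressionSummary:
    """Mapping protein -> signed differential-expression value E(x).

    Proteins absent from the mapping contribute nothing to node sums; the
    scoring layer counts them in its coverage diagnostic.
    """

    values: Mapping[str, float]
    missing_policy: str = "zero"

    def get(self, protein: str) -> float | None:
        return self.values.get(protein)

    def __contains__(self, protein: str) -> bool:
        return protein in self.values

    def __len__(self) -> int:
        return len(self.values)


def expression_summary(study: ExpressionStudy,
                       case: str | None = None,
                       control: str | None = None) -> ExpressionSummary:
    """Compute E(x) for every protein in the study.

    For unpaired studies the case/control labels may be given explicitly;
    by default ``case``/``control`` labels are recognised, otherwise the
    lexicographically later level is treated as the case.  A non-positive
    group mean is an error (its logarithm is undefined): shift the data or
    use paired log-ratios.
    """
    if study.mode == PAIRED:
        e = study.values.mean(axis=1)
        return ExpressionSummary(dict(zip(study.values.index, e.to_numpy())))
    levels = study.condition_levels()
    if case is None or control is None:
        if {"case", "control"} <= set(levels):
            case, control = "case", "control"
        else:
            control, case = levels  # sorted: earlier level is the baseline
    cond = study.design["condition"].astype(str)
    case_cols = study.design.index[cond == case]
    ctrl_cols = study.design.index[cond == control]
    if len(case_cols) == 0 or len(ctrl_cols) == 0:
        raise ValueError(f"no samples for case={case!r} or control={control!r}")
    mean_case = study.values[case_cols].mean(axis=1).to_numpy()
    mean_ctrl = study.values[ctrl_cols].mean(axis=1).to_numpy()
    if np.any(mean_case <= 0) or np.any(mean_ctrl <= 0):
        bad = study.values.index[(mean_case <= 0) | (mean_ctrl <= 0)][:5]
        raise ValueError(
            "non-positive group mean(s), logarithm undefined (e.g. "
            f"{list(bad)}); pre-shift the data or use paired log-ratios")
    log_base = math.log(study.log_base)
    e = (np.log(mean_case) - np.log(mean_ctrl)) / log_base
    return ExpressionSummary(dict(zip(study.values.index, e)))


# -- tabular I/O ----------------------------------------------------------


def read_expression_table(stream: IO[str] | str) -> pd.DataFrame:
    """Read an expression TSV: first column protein ID, remainder samples."""
    frame = pd.read_csv(stream, sep="\t", index_col=0, comment="#")
    frame.index = frame.index.astype(str)
    return frame


def write_expression_table(values: pd.DataFrame, stream: IO[str] | str) -> None:
    values.to_csv(stream, sep="\t", index_label="protein")


def read_design_table(stream: IO[str] | str) -> pd.DataFrame:
    """Read a design TSV indexed by ``sample_id``."""
    design = pd.read_csv(stream, sep="\t", comment="#")
    if "sample_id" not in design.columns:
        raise ValueError("design table requires a 'sample_id' column")
    return design.set_index("sample_id")
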