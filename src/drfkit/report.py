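"""Measured-vs-predicted validation tables and structured reports.

Joins a measured and a predicted distraction curve on the protocol step
grid, recomputes per-step absolute errors (never trusting a supplied error
column) and summarises them as RMSE, max error and mean absolute error.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .metrology import CalibrationReport
from .predictor import DistractionCurve

__all__ = ["ComparisonTable", "absolute_errors", "rmse", "build_report"]

#: Printed-rounding tolerance for strict-mode error-column checks (N).
PRINTED_ROUNDING_N = 0.005

_COLUMNS = ["step_mm", "measured_n", "predicted_n", "abs_error_n"]


@dataclass(frozen=True)
class ComparisonTable:
    """Per-step measured/predicted/absolute-error records."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data
        missing = set(_COLUMNS[:3]) - set(df.columns)
        if missing:
            raise ValueError(f"comparison table missing columns: {sorted(missing)}")
        df = df.sort_values("step_mm").reset_index(drop=True)
        recomputed = (df["measured_n"] - df["predicted_n"]).abs()
        if "abs_error_n" in df.columns:
            if (df["abs_error_n"] - recomputed).abs().max() > PRINTED_ROUNDING_N:
                raise ValueError(
                    "supplied error column disagrees with |measured - predicted| "
                    f"by more than {PRINTED_ROUNDING_N} N"
                )
        df = df.assign(abs_error_n=recomputed)
        object.__setattr__(self, "data", df[_COLUMNS])

    def __len__(self) -> int:
        return len(self.data)

    @property
    def abs_errors(self) -> np.ndarray:
        return self.data["abs_error_n"].to_numpy()

    @property
    def max_error_n(self) -> float:
        return float(self.abs_errors.max())

    @property
    def mean_abs_error_n(self) -> float:
        return float(self.abs_errors.mean())

    def summary(self) -> dict:
        return {
            "rmse_n": round(rmse(self), 2),
            "max_error_n": self.max_error_n,
            "mean_abs_error_n": self.mean_abs_error_n,
            "worst_step_mm": float(self.data.loc[self.data["abs_error_n"].idxmax(), "step_mm"]),
            "n_steps": len(self),
        }


def absolute_errors(measured: DistractionCurve, predicted: DistractionCurve) -> ComparisonTable:
    """Join the two curves on the step grid and recompute absolute errors.

    Steps are matched after rounding to 0.1 mm (protocol steps are discrete);
    any orphan step on either side is a hard error listing the offenders.
    """
    m = pd.DataFrame(
        {"step_mm": np.round(measured.lengths_mm, 1), "measured_n": measured.forces_n}
    )
    p = pd.DataFrame(
        {"step_mm": np.round(predicted.lengths_mm, 1), "predicted_n": predicted.forces_n}
    )
    joined = m.merge(p, on="step_mm", how="outer", sort=True)
    orphans = joined[joined.isna().any(axis=1)]["step_mm"].tolist()
    if orphans:
        raise ValueError(f"curves do not share these distraction steps (mm): {orphans}")
    return ComparisonTable(joined)


def rmse(table: ComparisonTable) -> float:
    """Root-mean-square of the recomputed per-step errors (N)."""
    if len(table) == 0:
        raise ValueError("empty comparison table")
    return float(np.sqrt(np.mean(table.abs_errors**2)))


def build_report(
    table: ComparisonTable,
    calibration: CalibrationReport | None = None,
    metadata: dict | None = None,
) -> dict:
    """Bundle comparison statistics into a JSON-serializable report.

    The report is deterministic for fixed inputs; callers that want a
    timestamp add it downstream so byte-identity checks stay possible.
    """
    report = {
        "comparison": {
            "rows": table.data.to_dict(orient="records"),
            **table.summary(),
        },
    }
    if calibration is not None:
        report["calibration"] = calibration.to_dict()
    if metadata:
        report["metadata"] = dict(metadata)
    return report
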