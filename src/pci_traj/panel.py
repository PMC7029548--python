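"""Longitudinal patient x day x variable container with a missingness mask."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class LongitudinalPanel:
    """Dense patient x day x variable array with an observed-mask.

    ``values`` always retains the underlying numbers (including under cells
    currently flagged missing, which serves as ground truth for imputation
    experiments); ``mask`` says which cells count as observed. Days are
    1-based and contiguous.
    """

    values: np.ndarray  # (n_patients, n_days, n_vars), float
    mask: np.ndarray  # same shape, bool: True = observed
    variables: list[str]
    patient_ids: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.values.shape != self.mask.shape:
            raise ValueError("values and mask shapes differ")
        if self.values.ndim != 3:
            raise ValueError("panel must be 3-dimensional")
        if self.values.shape[2] != len(self.variables):
            raise ValueError("variable list length mismatch")
        if self.patient_ids is None:
            self.patient_ids = np.arange(self.values.shape[0])
        if not np.all(np.isfinite(self.values[self.mask])):
            raise ValueError("observed cells must be finite")

    @property
    def n_patients(self) -> int:
        return self.values.shape[0]

    @property
    def n_days(self) -> int:
        return self.values.shape[1]

    @property
    def days(self) -> np.ndarray:
        return np.arange(1, self.n_days + 1)

    def var_index(self, name: str) -> int:
        try:
            return self.variables.index(name)
        except ValueError:
            raise KeyError(f"variable {name!r} not in panel (has {self.variables})") from None

    def get(self, name: str, masked: bool = True) -> np.ndarray:
        """(n_patients, n_days) array for one variable; NaN where missing."""
        j = self.var_index(name)
        out = self.values[:, :, j].copy()
        if masked:
            out[~self.mask[:, :, j]] = np.nan
        return out

    def copy(self) -> "LongitudinalPanel":
        return LongitudinalPanel(
            self.values.copy(), self.mask.copy(), list(self.variables), self.patient_ids.copy()
        )

    def to_long(self) -> pd.DataFrame:
        """Long-format DataFrame: patient_id, day, variable, value (observed cells only)."""
        n, t, v = self.values.shape
        pid = np.repeat(self.patient_ids, t * v)
        day = np.tile(np.repeat(self.days, v), n)
        var = np.tile(np.array(self.variables, dtype=object), n * t)
        val = self.values.reshape(-1)
        obs = self.mask.reshape(-1)
        return pd.DataFrame(
            {"patient_id": pid[obs], "day": day[obs], "variable": var[obs], "value": val[obs]}
        )

    @classmethod
    def from_long(cls, df: pd.DataFrame, n_days: int | None = None,
                  variables: list[str] | None = None) -> "LongitudinalPanel":
        pids = np.sort(df["patient_id"].unique())
        variables = variables or sorted(df["variable"].unique())
        n_days = n_days or int(df["day"].max())
        pid_idx = {p: i for i, p in enumerate(pids)}
        var_idx = {v: j for j, v in enumerate(variables)}
        values = np.full((len(pids), n_days, len(variables)), np.nan)
        mask = np.zeros_like(values, dtype=bool)
        i = df["patient_id"].map(pid_idx).to_numpy()
        d = df["day"].to_numpy(dtype=int) - 1
        j = df["variable"].map(var_idx).to_numpy()
        values[i, d, j] = df["value"].to_numpy(dtype=float)
        mask[i, d, j] = True
        return cls(values, mask, list(variables), pids)

    def wide_frame(self) -> pd.DataFrame:
        """Wide per-(patient, day) frame with one column per variable; NaN = missing."""
        n, t, _ = self.values.shape
        data = {"patient_id": np.repeat(self.patient_ids, t), "day": np.tile(self.days, n)}
        vals = self.values.copy()
        vals[~self.mask] = np.nan
        for j, name in enumerate(self.variables):
            data[name] = vals[:, :, j].reshape(-1)
        return pd.DataFrame(data)
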