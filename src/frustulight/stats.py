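"""Weighted-mean statistics of structural parameters across valves.

Each SEM / FIB-SEM image of valve *i* yields a per-valve mean ``X_av,i`` with
standard deviation ``dX_av,i``.  Across N valves the inverse-variance
weighted mean is

    w_i = 1/dX_av,i²,   X_w = Σ w_i X_i / Σ w_i,

with the *internal* error (propagated measurement uncertainty)

    dX_int = (Σ w_i)^(−1/2)

and the *external* (Birge-style, scatter-based) error

    dX_ext = sqrt( Σ w_i (X_i − X_w)² / ((N−1) Σ w_i) ).

If dX_int > dX_ext the within-valve variation dominates; otherwise the
valve-to-valve variation does.  The dominant error sets the parameter's
precision, 100·max(dX_int, dX_ext)/X_w percent.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .params import ValveParameters


@dataclass
class MeasurementTable:
    """Per-valve measurements of one structural parameter.

    values / sds : per-valve means X_av,i and standard deviations dX_av,i.
    counts : number of measurements behind each per-valve mean (bookkeeping).
    """

    parameter: str
    values: np.ndarray
    sds: np.ndarray
    counts: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.sds = np.asarray(self.sds, dtype=float)
        if self.values.shape != self.sds.shape:
            raise ValueError("values and sds must have the same length")
        if np.any(self.sds <= 0):
            raise ValueError("per-valve standard deviations must be positive")
        if self.counts is None:
            self.counts = np.ones_like(self.values, dtype=int)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "parameter": self.parameter,
            "valve_id": np.arange(1, len(self.values) + 1),
            "value": self.values,
            "sd": self.sds,
            "n": self.counts,
        })

    @classmethod
    def from_frame(cls, df: pd.DataFrame, parameter: str | None = None
                   ) -> "MeasurementTable":
        if parameter is not None:
            df = df[df["parameter"] == parameter]
        else:
            parameter = str(df["parameter"].iloc[0])
        return cls(parameter=parameter,
                   values=df["value"].to_numpy(),
                   sds=df["sd"].to_numpy(),
                   counts=df["n"].to_numpy() if "n" in df else None)


@dataclass
class ParameterSummary:
    parameter: str
    X_w: float
    dX_int: float
    dX_ext: float
    dominant: str            # "internal" or "external"
    precision_pct: float
    n_valves: int
    external_defined: bool = True


def summarize(table: MeasurementTable) -> ParameterSummary:
    """Weighted mean with internal/external errors and the dominant source."""
    x, s = table.values, table.sds
    n = len(x)
    if n < 1:
        raise ValueError("empty measurement table")
    w = 1.0 / s**2
    sw = w.sum()
    xw = float((w * x).sum() / sw)
    dx_int = float(sw ** -0.5)
    if n < 2:
        return ParameterSummary(table.parameter, xw, dx_int, float("nan"),
                                "internal", 100.0 * dx_int / xw, n,
                                external_defined=False)
    dx_ext = float(np.sqrt((w * (x - xw) ** 2).sum() / ((n - 1) * sw)))
    dominant = "internal" if dx_int > dx_ext else "external"
    precision = 100.0 * max(dx_int, dx_ext) / xw
    return ParameterSummary(table.parameter, xw, dx_int, dx_ext,
                            dominant, precision, n)


def summaries_to_frame(summaries: list[ParameterSummary]) -> pd.DataFrame:
    """Tabulate summaries with the columns of the structural-parameter table."""
    return pd.DataFrame([{
        "parameter": s.parameter,
        "X_w": s.X_w,
        "dX_int": s.dX_int,
        "dX_ext": s.dX_ext,
        "dominant": s.dominant,
        "precision_pct": s.precision_pct,
        "n_valves": s.n_valves,
    } for s in summaries])


def build_table_from_synthetic(n_valves: int,
                               truth: float | ValveParameters,
                               within_sd: float,
                               between_sd: float,
                               seed: int,
                               parameter: str = "D_v",
                               n_per_valve: int = 10) -> MeasurementTable:
    """Draw a synthetic per-valve measurement table around a true value.

    Valve means are drawn N(truth, between_sd²); each valve then contributes
    ``n_per_valve`` image measurements N(valve mean, within_sd²), collapsed to
    the per-valve mean and sample SD, mirroring how real image measurements
    are reduced.  Deterministic for a given seed.
    """
    if within_sd < 0 or between_sd < 0:
        raise ValueError("standard deviations must be non-negative")
    if isinstance(truth, ValveParameters):
        truth = float(getattr(truth, parameter))
    rng = np.random.default_rng(seed)
    valve_means = truth + between_sd * rng.standard_normal(n_valves)
    values = np.empty(n_valves)
    sds = np.empty(n_valves)
    for i in range(n_valves):
        meas = valve_means[i] + within_sd * rng.standard_normal(n_per_valve)
        values[i] = meas.mean()
        # sample SD of the per-image measurements; floor avoids a degenerate
        # zero weight when within_sd == 0
        sds[i] = max(meas.std(ddof=1), 1e-12 * max(abs(truth), 1.0))
    return MeasurementTable(parameter=parameter, values=values, sds=sds,
                            counts=np.full(n_valves, n_per_valve))
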