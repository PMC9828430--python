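"""Goodness-of-fit statistics and the packaged field-trial fixtures.

The model was evaluated against multi-site field-trial yields by linear
regression of modelled on measured values; this module reproduces those
statistics (r-squared, RMSE, mean bias, plus a modelling-efficiency
variant about the 1:1 line) and ships the published (measured, modelled)
yield pairs and canopy extinction coefficients as plain-text fixtures.

The upland pair set contains one extreme outlier (Yangling 2010: measured
30.2 vs modelled 8.9 Mg ha-1) whose inclusion in the original regression
is ambiguous; ``fit_stats`` therefore supports computing statistics with
and without flagged rows, and callers are expected to report both.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

__all__ = [
    "FitStats",
    "fit_stats",
    "field_trial_pairs",
    "extinction_coefficient_table",
    "median_extinction_coefficient",
    "UPLAND_OUTLIER",
]

#: (site, harvest_year) of the ambiguous upland outlier pair
UPLAND_OUTLIER = ("Yangling", 2010)


@dataclass(frozen=True)
class FitStats:
    """Modelled-versus-measured goodness of fit."""

    n: int
    r2: float            # squared Pearson correlation
    rmse: float          # Mg ha-1
    bias: float          # mean(modelled - measured), Mg ha-1
    efficiency: float    # 1 - SSE/SST about the 1:1 line (can be < 0)
    degenerate: bool = False


def fit_stats(pairs: pd.DataFrame) -> FitStats:
    """Fit statistics for a frame with ``measured`` and ``modelled`` columns.

    ``r2`` is the squared Pearson correlation of the pair set (the
    regression definition); ``efficiency`` is the 1 - SSE/SST modelling
    efficiency about the 1:1 line, which penalises bias as well as
    scatter.  Needs at least three pairs; a zero-variance measured column
    is flagged degenerate (r2 reported as 0).
    """
    measured = np.asarray(pairs["measured"], dtype=float)
    modelled = np.asarray(pairs["modelled"], dtype=float)
    n = measured.size
    if n < 3:
        raise ValueError("need at least three pairs")

    resid = modelled - measured
    rmse = float(np.sqrt(np.mean(resid ** 2)))
    bias = float(np.mean(resid))
    sst = float(np.sum((measured - measured.mean()) ** 2))
    degenerate = sst == 0.0 or np.var(modelled) == 0.0
    if degenerate:
        r2 = 0.0
        efficiency = float("nan") if sst == 0.0 else 1.0 - float(
            np.sum(resid ** 2)) / sst
    else:
        r = float(np.corrcoef(measured, modelled)[0, 1])
        r2 = r * r
        efficiency = 1.0 - float(np.sum(resid ** 2)) / sst
    return FitStats(n=n, r2=r2, rmse=rmse, bias=bias,
                    efficiency=efficiency, degenerate=degenerate)


def _load_csv(name: str) -> pd.DataFrame:
    ref = resources.files("switchfor.data") / name
    with ref.open("r") as fh:
        return pd.read_csv(fh, comment="#")


def field_trial_pairs(subset: str = "all",
                      include_outlier: bool = True) -> pd.DataFrame:
    """Packaged field-trial (measured, modelled) yield pairs.

    ``subset`` is ``"upland"``, ``"lowland"`` or ``"all"``.  With
    ``include_outlier=False`` the ambiguous Yangling 2010 upland row is
    dropped.
    """
    df = _load_csv("field_trial_yields.csv")
    if subset not in ("all", "upland", "lowland"):
        raise ValueError(f"unknown subset {subset!r}")
    if subset != "all":
        df = df[df["ecotype"] == subset]
    if not include_outlier:
        site, year = UPLAND_OUTLIER
        df = df[~((df["site"] == site) & (df["harvest_year"] == year))]
    return df.reset_index(drop=True)


def extinction_coefficient_table() -> pd.DataFrame:
    """Packaged published canopy extinction coefficients (signed)."""
    return _load_csv("extinction_coefficients.csv")


def median_extinction_coefficient(k_values=None) -> float:
    """Median of the absolute extinction coefficients.

    Signs differ between source conventions, so the median is taken over
    absolute values.  With no argument, uses the packaged table (whose
    median is the model's shared k of 0.36).
    """
    if k_values is None:
        k_values = extinction_coefficient_table()["k"]
    k = np.abs(np.asarray(k_values, dtype=float))
    if k.size == 0:
        raise ValueError("empty extinction-coefficient list")
    return float(np.median(k))
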