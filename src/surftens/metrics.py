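"""Deviation statistics for surface-tension models.

For a model value :math:`\\sigma(T_i)` against a datum :math:`\\sigma_i`:

* ``PD_i = 100 (\\sigma(T_i) - \\sigma_i) / \\sigma_i`` — signed percent
  deviation;
* ``AAD = mean |PD_i|`` over a data set (percent);
* ``PDm = max |PD_i|`` — the worst prediction (percent);
* ``RMSE = sqrt(mean (\\sigma_i - \\sigma(T_i))^2)`` in N/m;
* ``R^2 = 1 - SS_res / SS_tot`` with ``SS_tot`` about the data mean.

PD-based statistics blow up where the data value approaches zero (near the
critical point), so :func:`build_report` can exclude data below a small
sigma floor from the PD statistics; RMSE and R^2 always use all points.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data import Dataset, SplitAssignment

logger = logging.getLogger(__name__)


def percent_deviation(sigma_model, sigma_data):
    """Signed percent deviation ``100 (model - data) / data``.

    Accepts scalars or arrays; ``sigma_data`` must be strictly positive.
    """
    model = np.asarray(sigma_model, dtype=float)
    data = np.asarray(sigma_data, dtype=float)
    if np.any(data <= 0):
        raise ValueError("percent deviation undefined for sigma_data <= 0")
    out = 100.0 * (model - data) / data
    return float(out) if out.ndim == 0 else out


def aad(pds) -> float:
    """Absolute average deviation: mean of ``|PD_i|``, percent."""
    arr = np.asarray(pds, dtype=float)
    if arr.size == 0:
        raise ValueError("AAD of an empty sequence is undefined")
    return float(np.mean(np.abs(arr)))


def pdm(pds) -> float:
    """Maximum absolute percent deviation."""
    arr = np.asarray(pds, dtype=float)
    if arr.size == 0:
        raise ValueError("PDm of an empty sequence is undefined")
    return float(np.max(np.abs(arr)))


def rmse(sigma_data, sigma_calc) -> float:
    """Root mean square error in the native sigma units (N/m)."""
    data = np.asarray(sigma_data, dtype=float)
    calc = np.asarray(sigma_calc, dtype=float)
    if data.shape != calc.shape:
        raise ValueError(f"length mismatch: {data.shape} vs {calc.shape}")
    if data.size == 0:
        raise ValueError("RMSE of empty sequences is undefined")
    return float(np.sqrt(np.mean((data - calc) ** 2)))


def r_squared(sigma_data, sigma_calc) -> float:
    """Coefficient of determination about the data mean."""
    data = np.asarray(sigma_data, dtype=float)
    calc = np.asarray(sigma_calc, dtype=float)
    if data.shape != calc.shape:
        raise ValueError(f"length mismatch: {data.shape} vs {calc.shape}")
    ss_tot = float(np.sum((data - data.mean()) ** 2))
    if ss_tot == 0.0:
        raise ValueError("R^2 undefined: all data values identical")
    ss_res = float(np.sum((data - calc) ** 2))
    return 1.0 - ss_res / ss_tot


@dataclass(frozen=True)
class FitReport:
    """Deviation statistics for one data subset (one row of a summary table)."""

    subset: str
    AAD: float        # percent
    PDm: float        # percent
    RMSE: float       # N/m
    R2: float
    N: int

    def as_row(self) -> dict:
        return {
            "subset": self.subset,
            "N": self.N,
            "AAD_pct": round(self.AAD, 2),
            "PDm_pct": round(self.PDm, 2),
            "RMSE_N_per_m": self.RMSE,
            "R2": self.R2,
        }


def subset_report(subset: str, sigma_data, sigma_calc,
                  sigma_floor: float = 1e-6) -> FitReport:
    """Assemble a :class:`FitReport` from raw data/model value arrays."""
    data = np.asarray(sigma_data, dtype=float)
    calc = np.asarray(sigma_calc, dtype=float)
    keep = data >= sigma_floor
    if not keep.all():
        logger.warning(
            "%s: excluding %d point(s) with sigma < %g N/m from PD statistics",
            subset, int((~keep).sum()), sigma_floor,
        )
    if keep.sum() == 0:
        raise ValueError(f"{subset}: no data above the sigma floor")
    pds = percent_deviation(calc[keep], data[keep])
    try:
        r2 = r_squared(data, calc)
    except ValueError:
        # a one-point or constant subset has no variance to explain
        r2 = float("nan")
    return FitReport(
        subset=subset,
        AAD=aad(pds),
        PDm=pdm(pds),
        RMSE=rmse(data, calc),
        R2=r2,
        N=int(data.size),
    )


def build_report(
    dataset: Dataset,
    predictions,
    split: SplitAssignment | None = None,
    sigma_floor: float = 1e-6,
) -> tuple[dict[str, FitReport], pd.DataFrame]:
    """Per-subset :class:`FitReport` plus the per-fluid AAD/PDm table.

    Parameters
    ----------
    dataset : Dataset
    predictions : array-like, one model value (N/m) per datum, in dataset order.
    split : SplitAssignment, optional
        If given, reports are produced for training/test/prediction in
        addition to the complete set; R^2 on each subset uses that subset's
        own mean.
    sigma_floor : float
        Data below this sigma (N/m) are excluded from PD-based statistics
        (logged); RMSE and R^2 always use every point.

    Returns
    -------
    reports : dict subset -> FitReport
    per_fluid : DataFrame with columns ``fluid, N, AAD_pct, PDm_pct``,
        computed over each fluid's own data.
    """
    calc = np.asarray(predictions, dtype=float)
    if calc.shape != (dataset.N,):
        raise ValueError(
            f"need exactly one prediction per datum: got {calc.shape}, "
            f"dataset has N={dataset.N}"
        )
    data = dataset.data["sigma"].to_numpy()
    reports: dict[str, FitReport] = {}
    if split is not None:
        for subset in ("training", "test", "prediction"):
            idx = split.indices(subset)
            if idx.size:
                reports[subset] = subset_report(
                    subset, data[idx], calc[idx], sigma_floor
                )
    reports["complete"] = subset_report("complete", data, calc, sigma_floor)

    rows = []
    fluid_col = dataset.data["fluid"].to_numpy()
    for name in dataset.fluid_names():
        mask = (fluid_col == name) & (data >= sigma_floor)
        n_all = int((fluid_col == name).sum())
        if mask.sum() == 0:
            continue
        pds = percent_deviation(calc[mask], data[mask])
        rows.append({"fluid": name, "N": n_all, "AAD_pct": aad(pds),
                     "PDm_pct": pdm(pds)})
    per_fluid = pd.DataFrame(rows, columns=["fluid", "N", "AAD_pct", "PDm_pct"])
    return reports, per_fluid


def render_report(reports: dict[str, FitReport]) -> pd.DataFrame:
    """Summary-table rendering (subset rows; percents rounded to 2 decimals)."""
    order = [s for s in ("training", "test", "prediction", "complete")
             if s in reports]
    return pd.DataFrame([reports[s].as_row() for s in order])
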