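"""Corresponding-states baseline correlations and their benchmark runner.

Four classical corresponding-states (CSP) estimates of liquid surface
tension, each a closed form in reduced temperature ``Tr = T/Tc`` and a small
set of per-fluid constants, all returning sigma in N/m and vanishing at the
critical point through a ``(1 - Tr)^(11/9)`` factor:

``brock_bird``
    sigma[mN/m] = Pc^(2/3) Tc^(1/3) Q (1 - Tr)^(11/9), Pc in bar, with
    Q = 0.1196 [1 + Tbr ln(Pc/1.01325) / (1 - Tbr)] - 0.279.
``sastri_rao``
    sigma[mN/m] = K Pc^x Tb^y Tc^z [(1 - Tr)/(1 - Tbr)]^m with the
    acid-specific constants K=0.125, x=0.5, y=-1.5, z=1.85, m=11/9.
``pitzer``
    sigma[mN/m] = Pc^(2/3) Tc^(1/3) (1.86 + 1.18 w)/19.05
    * [(3.75 + 0.91 w)/(0.291 - 0.08 w)]^(2/3) (1 - Tr)^(11/9), Pc in bar.
``gharagheizi``
    A corresponding-states power law in (T, Tc, omega, Mw):
    sigma[mN/m] = K Tc^a Mw^b (1 + w)^c (1 - Tr)^(11/9) with coefficients
    frozen by a one-time calibration against the two pressure-based forms
    on acid-like fluids (see docs/methods.md for the provenance of this
    parameterization).

The benchmark runner evaluates each correlation on every row of a dataset,
aggregates per-fluid AADs and reports, per model: N10 (number of fluids
with AAD < 10%), max/min per-fluid AAD, and the overall data-weighted AAD.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import Dataset, FluidRecord
from .exceptions import CapabilityError, ValidationError
from .metrics import aad, percent_deviation

logger = logging.getLogger(__name__)

_EXP = 11.0 / 9.0  # classical corresponding-states critical exponent


def _check_T(fluid: FluidRecord, T) -> np.ndarray:
    T = np.asarray(T, dtype=float)
    if np.any(T >= fluid.Tc) or np.any(T <= 0):
        raise ValidationError(
            f"fluid {fluid.name!r}: T must lie in (0, Tc={fluid.Tc} K)"
        )
    return T


def _require(fluid: FluidRecord, model: str, *attrs: str) -> None:
    for a in attrs:
        v = getattr(fluid, a)
        if v is None or not np.isfinite(v):
            raise CapabilityError(
                f"model {model!r} requires fluid property {a!r}, "
                f"missing for {fluid.name!r}"
            )


def brock_bird(fluid: FluidRecord, T) -> np.ndarray | float:
    """Brock-Bird (1955) estimate, N/m.  Requires Tc, Tb, Pc."""
    _require(fluid, "brock_bird", "Tc", "Tb", "Pc")
    T = _check_T(fluid, T)
    Tr = T / fluid.Tc
    Tbr = fluid.Tb / fluid.Tc
    Q = 0.1196 * (1.0 + Tbr * np.log(fluid.Pc / 1.01325) / (1.0 - Tbr)) - 0.279
    sigma = fluid.Pc ** (2 / 3) * fluid.Tc ** (1 / 3) * Q * (1.0 - Tr) ** _EXP
    return sigma * 1e-3


def sastri_rao(fluid: FluidRecord, T) -> np.ndarray | float:
    """Sastri-Rao (1995) estimate with the acid parameter set, N/m.

    Requires Tc, Tb, Pc.
    """
    _require(fluid, "sastri_rao", "Tc", "Tb", "Pc")
    T = _check_T(fluid, T)
    Tr = T / fluid.Tc
    Tbr = fluid.Tb / fluid.Tc
    K, x, y, z, m = 0.125, 0.50, -1.5, 1.85, _EXP
    sigma = (K * fluid.Pc ** x * fluid.Tb ** y * fluid.Tc ** z
             * ((1.0 - Tr) / (1.0 - Tbr)) ** m)
    return sigma * 1e-3


def pitzer(fluid: FluidRecord, T) -> np.ndarray | float:
    """Pitzer acentric-factor corresponding-states estimate, N/m.

    Requires Tc, Pc, omega.
    """
    _require(fluid, "pitzer", "Tc", "Pc", "omega")
    T = _check_T(fluid, T)
    Tr = T / fluid.Tc
    w = fluid.omega
    sigma = (fluid.Pc ** (2 / 3) * fluid.Tc ** (1 / 3)
             * (1.86 + 1.18 * w) / 19.05
             * ((3.75 + 0.91 * w) / (0.291 - 0.08 * w)) ** (2 / 3)
             * (1.0 - Tr) ** _EXP)
    return sigma * 1e-3


# frozen one-time calibration (see module docstring / docs/methods.md)
_GHARAGHEIZI_LNK = 1.81465983
_GHARAGHEIZI_A = 0.33856794    # exponent of Tc
_GHARAGHEIZI_B = -0.01459192   # exponent of Mw
_GHARAGHEIZI_C = -0.05847457   # exponent of (1 + omega)


def gharagheizi(fluid: FluidRecord, T) -> np.ndarray | float:
    """Corresponding-states power law in (T, Tc, omega, Mw), N/m.

    Requires Tc, omega, Mw.
    """
    _require(fluid, "gharagheizi", "Tc", "omega", "Mw")
    T = _check_T(fluid, T)
    Tr = T / fluid.Tc
    sigma = (np.exp(_GHARAGHEIZI_LNK)
             * fluid.Tc ** _GHARAGHEIZI_A
             * fluid.Mw ** _GHARAGHEIZI_B
             * (1.0 + fluid.omega) ** _GHARAGHEIZI_C
             * (1.0 - Tr) ** _EXP)
    return sigma * 1e-3


#: model id -> (callable, required FluidRecord fields)
CSP_MODELS: dict[str, tuple] = {
    "brock_bird": (brock_bird, ("Tc", "Tb", "Pc")),
    "sastri_rao": (sastri_rao, ("Tc", "Tb", "Pc")),
    "pitzer": (pitzer, ("Tc", "Pc", "omega")),
    "gharagheizi": (gharagheizi, ("Tc", "omega", "Mw")),
}


def csp_surface_tension(model: str, fluid: FluidRecord, T):
    """Evaluate one CSP correlation by id.  Result in N/m."""
    if model not in CSP_MODELS:
        raise CapabilityError(
            f"unknown CSP model {model!r}; choose from {sorted(CSP_MODELS)}"
        )
    fn, _ = CSP_MODELS[model]
    return fn(fluid, T)


def fluid_supports(model: str, fluid: FluidRecord) -> bool:
    """True if ``fluid`` carries every constant ``model`` needs."""
    _, req = CSP_MODELS[model]
    return all(
        getattr(fluid, a) is not None and np.isfinite(getattr(fluid, a))
        for a in req
    )


@dataclass
class CSPBenchmarkSummary:
    """Benchmark statistics for one CSP model over a dataset.

    ``per_fluid`` holds one row per evaluable fluid (``fluid, N, AAD_pct``);
    ``fluids_below_10`` is the list of fluids with AAD < 10%.
    """

    model: str
    N10: int
    maxAAD: float
    minAAD: float
    overallAAD: float
    n_fluids: int
    n_data: int
    per_fluid: pd.DataFrame = field(repr=False)
    fluids_below_10: list[str] = field(default_factory=list, repr=False)
    skipped_fluids: list[str] = field(default_factory=list, repr=False)


def run_csp_benchmark(
    dataset: Dataset,
    models: list[str] | None = None,
    sigma_floor: float = 1e-6,
) -> dict[str, CSPBenchmarkSummary]:
    """Evaluate CSP correlations on every row of ``dataset``.

    Fluids lacking a model's required constants are skipped for that model
    with a logged notice.  Rows with sigma below ``sigma_floor`` are excluded
    from the percent-deviation statistics.
    """
    if dataset.N == 0:
        raise ValidationError("cannot benchmark an empty dataset")
    models = list(CSP_MODELS) if models is None else list(models)
    out: dict[str, CSPBenchmarkSummary] = {}
    data = dataset.data
    for model in models:
        rows = []
        all_abs_pd = []
        skipped = []
        n_data = 0
        for name, fluid in dataset.fluids.items():
            sub = data[data["fluid"] == name]
            if sub.empty:
                continue
            if not fluid_supports(model, fluid):
                skipped.append(name)
                continue
            keep = sub["sigma"].to_numpy() >= sigma_floor
            if keep.sum() == 0:
                skipped.append(name)
                continue
            T = sub["T"].to_numpy()[keep]
            sig = sub["sigma"].to_numpy()[keep]
            calc = np.asarray(csp_surface_tension(model, fluid, T))
            pds = percent_deviation(calc, sig)
            rows.append({"fluid": name, "N": int(keep.sum()),
                         "AAD_pct": aad(pds)})
            all_abs_pd.append(np.abs(pds))
            n_data += int(keep.sum())
        if skipped:
            logger.info("%s: skipped %d fluid(s) lacking inputs: %s",
                        model, len(skipped), ", ".join(skipped[:5]))
        if not rows:
            raise CapabilityError(
                f"model {model!r}: no fluid in the dataset supplies its inputs"
            )
        per_fluid = pd.DataFrame(rows)
        aads = per_fluid["AAD_pct"].to_numpy()
        below = per_fluid.loc[aads < 10.0, "fluid"].tolist()
        out[model] = CSPBenchmarkSummary(
            model=model,
            N10=len(below),
            maxAAD=float(aads.max()),
            minAAD=float(aads.min()),
            overallAAD=float(np.mean(np.concatenate(all_abs_pd))),
            n_fluids=len(rows),
            n_data=n_data,
            per_fluid=per_fluid,
            fluids_below_10=below,
            skipped_fluids=skipped,
        )
    return out


def summary_table(summaries: dict[str, CSPBenchmarkSummary]) -> pd.DataFrame:
    """Benchmark-table rendering: statistic rows x model columns."""
    cols = {}
    for model, s in summaries.items():
        cols[model] = {
            "N10": s.N10,
            "maxAAD_pct": round(s.maxAAD, 1),
            "minAAD_pct": round(s.minAAD, 1),
            "overallAAD_pct": round(s.overallAAD, 1),
        }
    return pd.DataFrame(cols)
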