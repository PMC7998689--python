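"""Domain types, dataset I/O, min-max normalization and the three-way split.

The central container is :class:`Dataset`: a list of per-fluid constant
records (:class:`FluidRecord`) plus an ordered table of surface-tension
observations, one row per ``(fluid, T, sigma, source)``.  Duplicate
``(fluid, T)`` rows with different ``sigma`` are legal and deliberately kept:
experimental compilations frequently report several sources at the same
temperature, and deviation statistics are defined per row.

Internal units are SI throughout: temperatures in K, surface tension in N/m,
critical pressure in bar, molar mass in g/mol.  CSV files may declare
surface tension in mN/m via ``units="mN_per_m"``; values are converted on
read/write so that in-memory data is always N/m.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .exceptions import (
    ConfigurationError,
    DegenerateRangeError,
    ParseError,
    SchemaError,
    ValidationError,
)

FAMILIES = ("carboxylic", "aliphatic", "polyfunctional", "unknown")

#: required columns of the dataset CSV dialect
REQUIRED_COLUMNS = ("fluid", "family", "Tc_K", "Tb_K", "omega", "T_K", "sigma")
#: recognized optional per-fluid constant columns -> FluidRecord attribute
OPTIONAL_COLUMNS = {
    "Pc_bar": "Pc",
    "Mw_g_mol": "Mw",
    "radius_of_gyration_m": "radius_of_gyration",
    "liquid_molar_volume_L_mol": "liquid_molar_volume",
    "dipole_moment_D": "dipole_moment",
}

SIGMA_UNITS = {"N_per_m": 1.0, "mN_per_m": 1e-3}


@dataclass(frozen=True)
class FluidRecord:
    """Constant properties of one fluid.

    Parameters
    ----------
    name : str
        Text identifier, unique within a dataset.
    family : str
        One of ``carboxylic``, ``aliphatic``, ``polyfunctional``, ``unknown``.
    Tc, Tb : float
        Critical and normal boiling temperature, K.  ``Tc > Tb > 0``.
    omega : float
        Acentric factor (dimensionless).
    Pc : float, optional
        Critical pressure, bar.
    Mw : float, optional
        Molar mass, g/mol.
    radius_of_gyration : float, optional
        m.
    liquid_molar_volume : float, optional
        L/mol.
    dipole_moment : float, optional
        debye.
    """

    name: str
    family: str = "unknown"
    Tc: float = float("nan")
    Tb: float = float("nan")
    omega: float = float("nan")
    Pc: float | None = None
    Mw: float | None = None
    radius_of_gyration: float | None = None
    liquid_molar_volume: float | None = None
    dipole_moment: float | None = None

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValidationError(
                f"fluid {self.name!r}: unknown family {self.family!r}; "
                f"expected one of {FAMILIES}"
            )
        if not (self.Tc > self.Tb > 0):
            raise ValidationError(
                f"fluid {self.name!r}: requires Tc > Tb > 0, got "
                f"Tc={self.Tc}, Tb={self.Tb}"
            )
        if not np.isfinite(self.omega):
            raise ValidationError(f"fluid {self.name!r}: acentric factor not finite")
        if self.Pc is not None and not self.Pc > 0:
            raise ValidationError(f"fluid {self.name!r}: Pc must be > 0, got {self.Pc}")


@dataclass(frozen=True)
class SurfaceTensionDatum:
    """One surface-tension observation: ``sigma`` (N/m) at ``T`` (K)."""

    fluid: str
    T: float
    sigma: float
    source: str = ""


class Dataset:
    """Fluids plus their surface-tension observations.

    Parameters
    ----------
    fluids : iterable of FluidRecord
    data : iterable of SurfaceTensionDatum, or a DataFrame with columns
        ``fluid, T, sigma[, source]``.
    """

    def __init__(
        self,
        fluids: Iterable[FluidRecord],
        data: Iterable[SurfaceTensionDatum] | pd.DataFrame,
    ):
        self.fluids: dict[str, FluidRecord] = {}
        for f in fluids:
            if f.name in self.fluids:
                raise ValidationError(f"duplicate fluid record {f.name!r}")
            self.fluids[f.name] = f
        if isinstance(data, pd.DataFrame):
            cols = {"fluid", "T", "sigma"}
            missing = cols - set(data.columns)
            if missing:
                raise SchemaError(f"data frame missing columns {sorted(missing)}")
            df = data.copy()
            if "source" not in df.columns:
                df["source"] = ""
        else:
            df = pd.DataFrame(
                [(d.fluid, d.T, d.sigma, d.source) for d in data],
                columns=["fluid", "T", "sigma", "source"],
            )
        df = df.reset_index(drop=True)
        df["T"] = df["T"].astype(float)
        df["sigma"] = df["sigma"].astype(float)
        self.data: pd.DataFrame = df[["fluid", "T", "sigma", "source"]]
        self._validate()

    # -- basic protocol ----------------------------------------------------
    @property
    def N(self) -> int:
        return len(self.data)

    def __len__(self) -> int:
        return self.N

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Dataset):
            return NotImplemented
        if set(self.fluids) != set(other.fluids):
            return False
        for name, f in self.fluids.items():
            g = other.fluids[name]
            for fld in dataclasses.fields(FluidRecord):
                a, b = getattr(f, fld.name), getattr(g, fld.name)
                if isinstance(a, float) and isinstance(b, float):
                    if not np.isclose(a, b, rtol=1e-12, atol=0, equal_nan=True):
                        return False
                elif a != b:
                    return False
        if len(self.data) != len(other.data):
            return False
        a, b = self.data, other.data
        return (
            (a["fluid"].values == b["fluid"].values).all()
            and np.allclose(a["T"], b["T"], rtol=1e-12)
            and np.allclose(a["sigma"], b["sigma"], rtol=1e-12)
        )

    def _validate(self) -> None:
        for i, row in self.data.iterrows():
            fluid = self.fluids.get(row["fluid"])
            if fluid is None:
                raise ValidationError(
                    f"row {i}: datum references unknown fluid {row['fluid']!r}"
                )
            if not (0 < row["T"] < fluid.Tc):
                raise ValidationError(
                    f"row {i}: T={row['T']} K outside (0, Tc={fluid.Tc} K) "
                    f"for fluid {fluid.name!r}"
                )
            if not row["sigma"] > 0:
                raise ValidationError(
                    f"row {i}: sigma={row['sigma']} must be > 0 "
                    f"(fluid {fluid.name!r})"
                )

    # -- convenience views -------------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        """Observations merged with the per-fluid constants, one row per datum.

        Adds a ``Tr`` column (T/Tc).
        """
        consts = pd.DataFrame(
            [dataclasses.asdict(f) for f in self.fluids.values()]
        ).rename(columns={"name": "fluid"})
        out = self.data.merge(consts, on="fluid", how="left", validate="m:1")
        out["Tr"] = out["T"] / out["Tc"]
        return out

    def fluid_names(self) -> list[str]:
        return list(self.fluids)


# ---------------------------------------------------------------------------
# CSV I/O
# ---------------------------------------------------------------------------

def read_dataset(path, units: str = "N_per_m") -> Dataset:
    """Read a dataset CSV (one row per observation, constants repeated).

    Required columns: ``fluid, family, Tc_K, Tb_K, omega, T_K, sigma``.
    Optional: ``source`` plus the constant columns in
    :data:`OPTIONAL_COLUMNS`.  ``units`` declares the sigma column unit.
    """
    if units not in SIGMA_UNITS:
        raise ConfigurationError(
            f"unknown sigma units {units!r}; expected one of {sorted(SIGMA_UNITS)}"
        )
    try:
        raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    except FileNotFoundError:
        raise
    missing = [c for c in REQUIRED_COLUMNS if c not in raw.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")

    def _num(series: pd.Series, col: str, optional: bool = False) -> pd.Series:
        s = series.replace("", "nan") if optional else series
        try:
            return s.astype(float)
        except ValueError as exc:
            raise ParseError(f"{path}: column {col!r}: {exc}") from exc

    fluids: dict[str, FluidRecord] = {}
    for key in raw["fluid"].unique():
        sub = raw[raw["fluid"] == key].iloc[0]
        kwargs = {}
        for col, attr in OPTIONAL_COLUMNS.items():
            if col in raw.columns and sub[col] != "":
                kwargs[attr] = _num(pd.Series([sub[col]]), col).iloc[0]
        fluids[key] = FluidRecord(
            name=key,
            family=sub["family"] or "unknown",
            Tc=_num(pd.Series([sub["Tc_K"]]), "Tc_K").iloc[0],
            Tb=_num(pd.Series([sub["Tb_K"]]), "Tb_K").iloc[0],
            omega=_num(pd.Series([sub["omega"]]), "omega").iloc[0],
            **kwargs,
        )
    df = pd.DataFrame(
        {
            "fluid": raw["fluid"],
            "T": _num(raw["T_K"], "T_K"),
            "sigma": _num(raw["sigma"], "sigma") * SIGMA_UNITS[units],
            "source": raw["source"] if "source" in raw.columns else "",
        }
    )
    return Dataset(fluids.values(), df)


def write_dataset(dataset: Dataset, path, units: str = "N_per_m") -> None:
    """Write ``dataset`` to the CSV dialect read by :func:`read_dataset`."""
    if units not in SIGMA_UNITS:
        raise ConfigurationError(
            f"unknown sigma units {units!r}; expected one of {sorted(SIGMA_UNITS)}"
        )
    df = dataset.to_frame()
    out = pd.DataFrame(
        {
            "fluid": df["fluid"],
            "family": df["family"],
            "Tc_K": df["Tc"],
            "Tb_K": df["Tb"],
            "omega": df["omega"],
            "T_K": df["T"],
            "sigma": df["sigma"] / SIGMA_UNITS[units],
            "source": df["source"],
        }
    )
    for col, attr in OPTIONAL_COLUMNS.items():
        if df[attr].notna().any():
            out[col] = df[attr]
    if dataset.N == 0:
        out = out.iloc[0:0]
    out.to_csv(path, index=False, float_format="%.17g")


def read_fluid_constants(path) -> list[FluidRecord]:
    """Read a fluid-constants CSV (no measurements) for prediction-only use."""
    raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    required = ("fluid", "family", "Tc_K", "Tb_K", "omega")
    missing = [c for c in required if c not in raw.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")
    records = []
    for _, row in raw.iterrows():
        kwargs = {}
        for col, attr in OPTIONAL_COLUMNS.items():
            if col in raw.columns and row[col] != "":
                try:
                    kwargs[attr] = float(row[col])
                except ValueError as exc:
                    raise ParseError(f"{path}: column {col!r}: {exc}") from exc
        try:
            records.append(
                FluidRecord(
                    name=row["fluid"],
                    family=row["family"] or "unknown",
                    Tc=float(row["Tc_K"]),
                    Tb=float(row["Tb_K"]),
                    omega=float(row["omega"]),
                    **kwargs,
                )
            )
        except ValueError as exc:
            raise ParseError(f"{path}: fluid {row['fluid']!r}: {exc}") from exc
    return records


# ---------------------------------------------------------------------------
# Min-max normalization
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class NormalizationSpec:
    """Affine map of ``[vmin, vmax]`` onto ``[0, 1]`` and back."""

    name: str
    vmin: float
    vmax: float

    def __post_init__(self) -> None:
        if not self.vmax > self.vmin:
            raise DegenerateRangeError(
                f"{self.name!r}: vmax ({self.vmax}) must exceed vmin ({self.vmin})"
            )

    def normalize(self, x):
        return (np.asarray(x, dtype=float) - self.vmin) / (self.vmax - self.vmin)

    def denormalize(self, u):
        return np.asarray(u, dtype=float) * (self.vmax - self.vmin) + self.vmin


def fit_normalization(values: Sequence[float], name: str = "") -> NormalizationSpec:
    """Min-max spec over ``values``; raises on a constant sequence."""
    arr = np.asarray(list(values), dtype=float)
    if arr.size < 2:
        raise DegenerateRangeError(f"{name!r}: need at least two values")
    return NormalizationSpec(name, float(arr.min()), float(arr.max()))


# ---------------------------------------------------------------------------
# Random three-way split
# ---------------------------------------------------------------------------

SUBSETS = ("training", "test", "prediction")


@dataclass(frozen=True)
class SplitAssignment:
    """Per-datum subset labels for a train/test/prediction partition."""

    labels: np.ndarray  # array of str, len N
    seed: int
    fractions: tuple[float, float, float]

    def indices(self, subset: str) -> np.ndarray:
        if subset == "complete":
            return np.arange(len(self.labels))
        if subset not in SUBSETS:
            raise ConfigurationError(f"unknown subset {subset!r}")
        return np.flatnonzero(self.labels == subset)

    def counts(self) -> dict[str, int]:
        return {s: int((self.labels == s).sum()) for s in SUBSETS}


def split_sizes(n: int, fractions=(0.75, 0.15, 0.10)) -> tuple[int, int, int]:
    """Deterministic subset sizes: round half up for training and test,
    prediction takes the remainder, so sizes always sum to ``n``."""
    n_train = int(np.floor(fractions[0] * n + 0.5))
    n_test = int(np.floor(fractions[1] * n + 0.5))
    return n_train, n_test, n - n_train - n_test


def split_dataset(
    dataset: Dataset | int,
    fractions: tuple[float, float, float] = (0.75, 0.15, 0.10),
    seed: int = 0,
) -> SplitAssignment:
    """Uniformly random train/test/prediction partition, reproducible from seed.

    ``dataset`` may be a :class:`Dataset` or a bare row count.  The split is
    by datum, not by fluid: all observations are pooled before shuffling.
    """
    n = dataset if isinstance(dataset, int) else dataset.N
    fractions = tuple(float(f) for f in fractions)
    if len(fractions) != 3 or any(f <= 0 for f in fractions):
        raise ConfigurationError("need three positive split fractions")
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ConfigurationError(
            f"split fractions must sum to 1, got {sum(fractions)}"
        )
    if n < 10:
        raise ConfigurationError(f"need at least 10 data to split, got {n}")
    n_train, n_test, n_pred = split_sizes(n, fractions)
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    labels = np.empty(n, dtype=object)
    labels[perm[:n_train]] = "training"
    labels[perm[n_train : n_train + n_test]] = "test"
    labels[perm[n_train + n_test :]] = "prediction"
    return SplitAssignment(labels=labels, seed=seed, fractions=fractions)
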