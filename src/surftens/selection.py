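"""Input ranking (effect factors) and the hidden-layer size sweep.

``effect_factors`` scores each candidate input by its coefficient in a
joint multilinear least-squares regression of min-max-normalized sigma on
the min-max-normalized candidates.  The score is signed (negative: sigma
decreases as the factor increases) and candidates are ranked by decreasing
absolute value.  This is a transparent surrogate for the proprietary
factor-analysis score used in the commercial tooling this step replaces;
only signs and ordering are meaningful, not the numeric values.

``architecture_sweep`` trains a best-of-restarts network for each hidden
size in a range against a fixed split and selects the size with the lowest
test-subset AAD (ties go to the smaller network).  The prediction subset is
never consulted during selection.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .data import Dataset, SplitAssignment, fit_normalization
from .exceptions import ConfigurationError
from .metrics import aad, percent_deviation
from .network import (
    DEFAULT_INPUTS,
    FEATURES,
    MLPNetwork,
    TrainingConfig,
    design_matrix,
    train_lm,
)

logger = logging.getLogger(__name__)

#: full candidate list for input ranking
CANDIDATE_FACTORS = (
    "Mw", "radius_of_gyration", "Tc", "Tr", "liquid_molar_volume",
    "Tb", "Pc", "omega", "dipole_moment",
)


@dataclass
class EffectFactorTable:
    """Ranked signed sensitivity scores, one row per candidate input."""

    table: pd.DataFrame  # columns: factor, EFF, rank (1 = largest |EFF|)

    def top(self, k: int) -> list[str]:
        return self.table["factor"].head(k).tolist()


def effect_factors(
    dataset: Dataset,
    candidates=CANDIDATE_FACTORS,
    min_coverage: float = 0.8,
    condition_threshold: float = 1e8,
) -> EffectFactorTable:
    """Joint multilinear regression of normalized sigma on normalized factors.

    Candidates missing for more than ``1 - min_coverage`` of rows are
    rejected up front; rows missing any retained candidate are dropped from
    the joint fit.  A badly conditioned design (collinear factors) is
    warned about but both factors are retained.
    """
    df = dataset.to_frame()
    n = len(df)
    cols = {}
    for name in candidates:
        if name not in FEATURES:
            raise ConfigurationError(f"unknown candidate factor {name!r}")
        col = np.asarray(FEATURES[name](df), dtype=float)
        cover = np.isfinite(col).mean()
        if cover < min_coverage:
            raise ConfigurationError(
                f"candidate {name!r} available for only {cover:.0%} of rows "
                f"(need >= {min_coverage:.0%})"
            )
        cols[name] = col
    X = np.column_stack(list(cols.values()))
    y = df["sigma"].to_numpy()
    keep = np.isfinite(X).all(axis=1)
    if keep.sum() < max(len(candidates) + 2, int(min_coverage * n)):
        raise ConfigurationError("too few complete rows for the joint fit")
    X, y = X[keep], y[keep]
    Xn = np.column_stack([
        fit_normalization(X[:, j], name).normalize(X[:, j])
        for j, name in enumerate(cols)
    ])
    yn = fit_normalization(y, "sigma").normalize(y)
    A = np.column_stack([np.ones(len(yn)), Xn])
    cond = np.linalg.cond(A)
    if cond > condition_threshold:
        logger.warning("effect-factor design badly conditioned (cond=%.3g); "
                       "collinear candidates retained", cond)
    coef, *_ = np.linalg.lstsq(A, yn, rcond=None)
    eff = coef[1:]
    table = pd.DataFrame({"factor": list(cols), "EFF": eff})
    table = table.reindex(
        table["EFF"].abs().sort_values(ascending=False).index
    ).reset_index(drop=True)
    table["rank"] = np.arange(1, len(table) + 1)
    return EffectFactorTable(table=table)


@dataclass
class SweepResult:
    """Outcome of a hidden-size sweep under a fixed split."""

    table: pd.DataFrame   # hidden_size, train_AAD, test_AAD, prediction_AAD,
                          # winning_restart, seed
    selected_size: int
    provenance: dict = field(default_factory=dict)


def _subset_aads(net: MLPNetwork, dataset: Dataset, split: SplitAssignment,
                 sigma_floor: float = 1e-6) -> dict[str, float]:
    calc = np.asarray(net.predict_dataset(dataset))
    data = dataset.data["sigma"].to_numpy()
    out = {}
    for subset in ("training", "test", "prediction"):
        idx = split.indices(subset)
        idx = idx[data[idx] >= sigma_floor]
        out[subset] = aad(percent_deviation(calc[idx], data[idx])) if idx.size \
            else float("nan")
    return out


def architecture_sweep(
    dataset: Dataset,
    split: SplitAssignment,
    hidden_range=range(2, 51),
    restarts: int = 30,
    seed: int = 0,
    config: TrainingConfig | None = None,
    input_names=DEFAULT_INPUTS,
) -> SweepResult:
    """Train best-of-restarts networks across hidden sizes; pick by test AAD.

    The split is fixed across the sweep for comparability.  Any cell is
    reproducible in isolation: restart ``r`` of size ``h`` trains from seed
    ``seed + 1000 * h + r``.  Sizes where every restart fails are skipped
    with a warning.
    """
    base = config or TrainingConfig()
    rows = []
    for h in hidden_range:
        cfg = replace(base, restarts=restarts, seed=seed + 1000 * h)
        try:
            net, results = train_lm(dataset, split, h, cfg,
                                    input_names=input_names)
        except Exception as exc:  # all restarts failed for this size
            logger.warning("hidden size %d skipped: %s", h, exc)
            continue
        # within a size, the sweep judges restarts by its own criterion,
        # the test-subset AAD (ties -> lower restart index); this keeps
        # "more restarts can only help" an exact property of the sweep
        best = None
        for res in results:
            net.set_params(res.theta.copy())
            aads = _subset_aads(net, dataset, split)
            key = (aads["test"], res.restart_index)
            if best is None or key < best[0]:
                best = (key, res.restart_index, aads)
        _, win_idx, aads = best
        rows.append({
            "hidden_size": h,
            "train_AAD": aads["training"],
            "test_AAD": aads["test"],
            "prediction_AAD": aads["prediction"],
            "winning_restart": win_idx,
            "seed": cfg.seed,
        })
    if not rows:
        raise ConfigurationError("sweep produced no trainable size")
    table = pd.DataFrame(rows)
    # minimum test AAD; ties -> smaller size (stable order of hidden_range)
    best = table.loc[table["test_AAD"].idxmin()]
    ties = table[np.isclose(table["test_AAD"], best["test_AAD"])]
    selected = int(ties["hidden_size"].min())
    return SweepResult(
        table=table,
        selected_size=selected,
        provenance={"seed": seed, "restarts": restarts,
                    "input_names": list(input_names)},
    )
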