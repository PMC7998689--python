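"""Statsmodels-style front end: a model object fitted to a dataset.

:class:`SurfaceTensionANN` bundles a :class:`~surftens.data.Dataset`, an
input choice, a hidden-layer size and a train/test/prediction split;
``fit()`` runs the multi-restart Levenberg-Marquardt training and returns a
:class:`SurfaceTensionANNResults` carrying the trained network, the
per-subset deviation statistics, the per-fluid table and a ``summary()``.

Example
-------
>>> from surftens import GeneratorConfig, generate_dataset, SurfaceTensionANN
>>> ds, _ = generate_dataset(GeneratorConfig(n_fluids=20, seed=1))
>>> res = SurfaceTensionANN(ds, n_hidden=8, seed=1).fit(restarts=3)
>>> print(res.summary())                       # doctest: +SKIP
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import (
    Dataset,
    FluidRecord,
    SplitAssignment,
    read_dataset,
    split_dataset,
)
from .metrics import FitReport, build_report, render_report
from .network import (
    DEFAULT_INPUTS,
    MLPNetwork,
    RestartResult,
    TrainingConfig,
    save_model,
    train_lm,
)


class SurfaceTensionANN:
    """Feed-forward surface-tension model for a dataset of liquid fluids.

    Parameters
    ----------
    dataset : Dataset
        Observations plus per-fluid constants.
    n_hidden : int
        Hidden-layer width (default 41, the selected architecture).
    inputs : sequence of str
        Input features; default ``("Tr", "Tb", "omega")``.
    split_fractions : (float, float, float)
        Train/test/prediction fractions (default 0.75/0.15/0.10).
    seed : int
        Seeds both the split and the weight initializations.
    split : SplitAssignment, optional
        Pre-computed split; overrides ``split_fractions``/``seed`` for the
        partition.
    """

    def __init__(
        self,
        dataset: Dataset,
        n_hidden: int = 41,
        inputs=DEFAULT_INPUTS,
        split_fractions=(0.75, 0.15, 0.10),
        seed: int = 0,
        split: SplitAssignment | None = None,
    ):
        self.dataset = dataset
        self.n_hidden = int(n_hidden)
        self.inputs = tuple(inputs)
        self.seed = int(seed)
        self.split = split if split is not None else split_dataset(
            dataset, split_fractions, seed=seed)

    @classmethod
    def from_csv(cls, path, units: str = "N_per_m", **kwargs
                 ) -> "SurfaceTensionANN":
        """Build the model straight from a dataset CSV."""
        return cls(read_dataset(path, units=units), **kwargs)

    def fit(
        self,
        restarts: int = 30,
        config: TrainingConfig | None = None,
    ) -> "SurfaceTensionANNResults":
        """Best-of-restarts Levenberg-Marquardt fit; see module docs."""
        cfg = config or TrainingConfig()
        cfg = TrainingConfig(**{**cfg.__dict__, "restarts": restarts,
                                "seed": cfg.seed or self.seed})
        net, restart_results = train_lm(
            self.dataset, self.split, self.n_hidden, cfg,
            input_names=self.inputs)
        predictions = np.asarray(net.predict_dataset(self.dataset))
        reports, per_fluid = build_report(self.dataset, predictions, self.split)
        return SurfaceTensionANNResults(
            model=self, network=net, reports=reports, per_fluid=per_fluid,
            restarts=restart_results, config=cfg,
        )


@dataclass
class SurfaceTensionANNResults:
    """Results of a :meth:`SurfaceTensionANN.fit` call."""

    model: SurfaceTensionANN
    network: MLPNetwork
    reports: dict[str, FitReport]
    per_fluid: pd.DataFrame
    restarts: list[RestartResult] = field(repr=False, default_factory=list)
    config: TrainingConfig | None = None

    # -- headline statistics ----------------------------------------------
    @property
    def aad(self) -> float:
        """Complete-set absolute average deviation, percent."""
        return self.reports["complete"].AAD

    @property
    def pdm(self) -> float:
        """Complete-set maximum absolute percent deviation."""
        return self.reports["complete"].PDm

    @property
    def rmse(self) -> float:
        """Complete-set RMSE, N/m."""
        return self.reports["complete"].RMSE

    @property
    def r2(self) -> float:
        return self.reports["complete"].R2

    def predict(self, fluid: FluidRecord, T, return_flags: bool = False):
        """Surface tension (N/m) for a fluid at temperature(s) T (K)."""
        return self.network.predict(fluid, T, return_flags=return_flags)

    def report_table(self) -> pd.DataFrame:
        return render_report(self.reports)

    def save(self, path, metadata: dict | None = None) -> None:
        meta = {"n_hidden": self.model.n_hidden,
                "inputs": list(self.model.inputs),
                "seed": self.model.seed}
        meta.update(metadata or {})
        save_model(self.network, path, metadata=meta)

    def summary(self) -> str:
        """Plain-text summary: architecture, split sizes, per-subset stats."""
        net = self.network
        counts = self.model.split.counts()
        lines = [
            "Surface-tension feed-forward network",
            "=" * 52,
            f"architecture      ({net.n_in}, {net.n_hidden}, 1)"
            f"   [{net.n_params} coefficients]",
            f"inputs            {', '.join(net.input_names)}",
            f"activation        {net.activation} (hidden), linear (output)",
            f"data              N = {self.model.dataset.N}"
            f" over {len(self.model.dataset.fluids)} fluids",
            "split             training/test/prediction = "
            + "/".join(str(counts[s]) for s in ("training", "test", "prediction")),
            f"restarts          {len(self.restarts)} completed"
            + (f" (winner #{self.restarts[0].restart_index})"
               if self.restarts else ""),
            "",
            self.report_table().to_string(index=False),
        ]
        return "\n".join(lines)
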