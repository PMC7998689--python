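"""Feed-forward (n_in, n_hidden, 1) perceptron with Levenberg-Marquardt training.

The network maps min-max-normalized inputs through one sigmoid hidden layer
to a linear output neuron; the output is denormalized back to N/m.  For the
surface-tension model the default inputs are the reduced temperature
``Tr = T/Tc``, the boiling temperature ``Tb`` and the acentric factor
``omega``; a (3, 41, 1) network carries ``41*(3+1) + 41 + 1 = 206``
trainable coefficients.

Training minimizes the RMSE of the normalized residuals with a damped
Gauss-Newton (Levenberg-Marquardt) iteration using the exact analytic
Jacobian.  Overfitting is controlled by snapshotting the weights at the
minimum of the test-subset RMSE (early stopping), and the optimizer is
restarted from multiple random initializations, keeping the restart with
the lowest test RMSE.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace

import numpy as np

from .data import (
    Dataset,
    FluidRecord,
    NormalizationSpec,
    SplitAssignment,
    fit_normalization,
)
from .exceptions import ConfigurationError, ModelFileError, TrainingError

logger = logging.getLogger(__name__)

SCHEMA_VERSION = 1

#: feature name -> callable(frame) on the merged observation frame
FEATURES = {
    "Tr": lambda df: df["T"] / df["Tc"],
    "Tb": lambda df: df["Tb"],
    "Tc": lambda df: df["Tc"],
    "omega": lambda df: df["omega"],
    "Pc": lambda df: df["Pc"],
    "Mw": lambda df: df["Mw"],
    "radius_of_gyration": lambda df: df["radius_of_gyration"],
    "liquid_molar_volume": lambda df: df["liquid_molar_volume"],
    "dipole_moment": lambda df: df["dipole_moment"],
}

DEFAULT_INPUTS = ("Tr", "Tb", "omega")


def sigmoid(x):
    """Standard logistic function ``1 / (1 + exp(-x))``, saturating safely."""
    x = np.asarray(x, dtype=float)
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out if out.ndim else float(out)


def sigmoid_decreasing(x):
    """The mirrored logistic ``1 / (1 + exp(x))`` (selectable variant)."""
    return sigmoid(-np.asarray(x, dtype=float))


ACTIVATIONS = {"logistic": sigmoid, "logistic_decreasing": sigmoid_decreasing}


def n_parameters(n_in: int, n_hidden: int) -> int:
    """Trainable coefficient count of an (n_in, n_hidden, 1) network."""
    return n_hidden * (n_in + 1) + n_hidden + 1


def design_matrix(dataset: Dataset, input_names=DEFAULT_INPUTS) -> np.ndarray:
    """Raw (unnormalized) feature matrix, one row per datum."""
    df = dataset.to_frame()
    cols = []
    for name in input_names:
        if name not in FEATURES:
            raise ConfigurationError(
                f"unknown input feature {name!r}; choose from {sorted(FEATURES)}"
            )
        col = np.asarray(FEATURES[name](df), dtype=float)
        if not np.isfinite(col).all():
            raise ConfigurationError(
                f"feature {name!r} missing/non-finite for some fluids"
            )
        cols.append(col)
    return np.column_stack(cols)


@dataclass
class MLPNetwork:
    """Weights, biases and normalization specs of a trained (or hand-built)
    single-hidden-layer perceptron."""

    input_names: tuple[str, ...]
    hidden_weights: np.ndarray   # (n_hidden, n_in)
    hidden_biases: np.ndarray    # (n_hidden,)
    output_weights: np.ndarray   # (n_hidden,)
    output_bias: float
    input_norms: tuple[NormalizationSpec, ...]
    output_norm: NormalizationSpec
    activation: str = "logistic"

    def __post_init__(self) -> None:
        self.hidden_weights = np.atleast_2d(
            np.asarray(self.hidden_weights, dtype=float))
        self.hidden_biases = np.asarray(self.hidden_biases, dtype=float)
        self.output_weights = np.asarray(self.output_weights, dtype=float)
        nh, ni = self.hidden_weights.shape
        if len(self.input_names) != ni or len(self.input_norms) != ni:
            raise ConfigurationError("input names/norms inconsistent with weights")
        if self.hidden_biases.shape != (nh,) or self.output_weights.shape != (nh,):
            raise ConfigurationError("bias/output weight shapes inconsistent")
        if self.activation not in ACTIVATIONS:
            raise ConfigurationError(f"unknown activation {self.activation!r}")
        arrays = (self.hidden_weights, self.hidden_biases, self.output_weights)
        if not all(np.isfinite(a).all() for a in arrays) or not np.isfinite(
                self.output_bias):
            raise ConfigurationError("network weights must be finite")

    # -- introspection -----------------------------------------------------
    @property
    def n_in(self) -> int:
        return self.hidden_weights.shape[1]

    @property
    def n_hidden(self) -> int:
        return self.hidden_weights.shape[0]

    @property
    def n_params(self) -> int:
        return n_parameters(self.n_in, self.n_hidden)

    # -- parameter vector --------------------------------------------------
    def get_params(self) -> np.ndarray:
        return np.concatenate([
            self.hidden_weights.ravel(),
            self.hidden_biases,
            self.output_weights,
            [self.output_bias],
        ])

    def set_params(self, theta: np.ndarray) -> None:
        nh, ni = self.n_hidden, self.n_in
        theta = np.asarray(theta, dtype=float)
        if theta.shape != (self.n_params,):
            raise ConfigurationError(
                f"expected {self.n_params} parameters, got {theta.shape}")
        k = nh * ni
        self.hidden_weights = theta[:k].reshape(nh, ni)
        self.hidden_biases = theta[k:k + nh]
        self.output_weights = theta[k + nh:k + 2 * nh]
        self.output_bias = float(theta[-1])

    # -- evaluation --------------------------------------------------------
    def forward_normalized(self, Xn: np.ndarray) -> np.ndarray:
        """Normalized output for already-normalized inputs (rows of ``Xn``)."""
        act = ACTIVATIONS[self.activation]
        h = act(Xn @ self.hidden_weights.T + self.hidden_biases)
        return h @ self.output_weights + self.output_bias

    def normalize_inputs(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        return np.column_stack(
            [spec.normalize(X[:, j]) for j, spec in enumerate(self.input_norms)]
        )

    def predict_features(self, X: np.ndarray, return_flags: bool = False):
        """Sigma (N/m) for raw feature rows; optionally flag extrapolation.

        A row extrapolates when any normalized input leaves [0, 1] by more
        than 1e-9; such rows are evaluated anyway and flagged (and logged),
        never rejected.
        """
        Xn = self.normalize_inputs(X)
        flags = ((Xn < -1e-9) | (Xn > 1 + 1e-9)).any(axis=1)
        if flags.any():
            logger.warning(
                "%d input row(s) outside the training normalization range "
                "(extrapolation)", int(flags.sum()))
        sigma = self.output_norm.denormalize(self.forward_normalized(Xn))
        return (sigma, flags) if return_flags else sigma

    def predict(self, fluid: FluidRecord, T, return_flags: bool = False):
        """Sigma (N/m) for one fluid at temperature(s) ``T`` (K)."""
        T = np.atleast_1d(np.asarray(T, dtype=float))
        df = _single_fluid_frame(fluid, T)
        X = np.column_stack(
            [np.asarray(FEATURES[n](df), dtype=float) for n in self.input_names]
        )
        out = self.predict_features(X, return_flags=return_flags)
        return out

    def predict_dataset(self, dataset: Dataset, return_flags: bool = False):
        X = design_matrix(dataset, self.input_names)
        return self.predict_features(X, return_flags=return_flags)


def _single_fluid_frame(fluid: FluidRecord, T: np.ndarray):
    import dataclasses as _dc

    import pandas as pd

    consts = _dc.asdict(fluid)
    consts.pop("name")
    df = pd.DataFrame({"T": T})
    for k, v in consts.items():
        df[k] = np.nan if v is None else v
    return df


# ---------------------------------------------------------------------------
# Levenberg-Marquardt
# ---------------------------------------------------------------------------

@dataclass
class TrainingConfig:
    """Optimizer settings for :func:`train_lm`.

    ``initial_damping`` starts the LM damping parameter lambda; each rejected
    step multiplies it by ``damping_increase``, each accepted step by
    ``damping_decrease``.  A restart aborts when lambda exceeds
    ``max_damping`` (near-singular normal equations).  Convergence is
    declared after ``patience`` consecutive accepted steps whose relative
    RMSE improvement is below ``tol``.
    """

    max_iterations: int = 1000
    initial_damping: float = 1e-3
    damping_increase: float = 10.0
    damping_decrease: float = 0.1
    max_damping: float = 1e12
    tol: float = 1e-9
    patience: int = 10
    restarts: int = 30
    seed: int = 0
    init_scale: float = 0.5  # initial weights uniform on [-init_scale, +init_scale]

    def __post_init__(self) -> None:
        if self.restarts < 1:
            raise ConfigurationError("restarts must be >= 1")
        if self.tol <= 0 or self.initial_damping <= 0:
            raise ConfigurationError("tolerances and damping must be positive")


def lm_jacobian(net: MLPNetwork, Xn: np.ndarray) -> np.ndarray:
    """Analytic Jacobian d(output)/d(theta), shape (N, n_params).

    Column order matches :meth:`MLPNetwork.get_params`: hidden weights
    (row-major), hidden biases, output weights, output bias.
    """
    act = ACTIVATIONS[net.activation]
    Z = Xn @ net.hidden_weights.T + net.hidden_biases        # (N, nh)
    H = act(Z)
    # derivative of both logistic variants w.r.t. pre-activation:
    dH = H * (1.0 - H)
    if net.activation == "logistic_decreasing":
        dH = -dH
    G = dH * net.output_weights                               # (N, nh)
    n, nh = H.shape
    ni = net.n_in
    J = np.empty((n, net.n_params))
    # d/d hidden_weights[j, k] = G[:, j] * Xn[:, k]
    J[:, : nh * ni] = (G[:, :, None] * Xn[:, None, :]).reshape(n, nh * ni)
    J[:, nh * ni : nh * ni + nh] = G
    J[:, nh * ni + nh : nh * ni + 2 * nh] = H
    J[:, -1] = 1.0
    return J


@dataclass
class RestartResult:
    theta: np.ndarray
    test_rmse: float
    train_rmse: float
    restart_index: int
    n_accepted: int
    aborted: bool
    history: list = field(repr=False, default_factory=list)


def _lm_single(net: MLPNetwork, Xn, tn, Xn_test, tn_test,
               theta0: np.ndarray, cfg: TrainingConfig,
               restart_index: int = 0) -> RestartResult:
    """One LM run from ``theta0``; returns the early-stopped best weights."""
    work = replace(net)
    work.set_params(theta0.copy())

    def train_rmse(th):
        work.set_params(th)
        r = work.forward_normalized(Xn) - tn
        return float(np.sqrt(np.mean(r * r)))

    def test_rmse(th):
        work.set_params(th)
        ref_X, ref_t = (Xn_test, tn_test) if len(tn_test) else (Xn, tn)
        r = work.forward_normalized(ref_X) - ref_t
        return float(np.sqrt(np.mean(r * r)))

    theta = theta0.copy()
    lam = cfg.initial_damping
    cur_rmse = train_rmse(theta)
    best_test = test_rmse(theta)
    best_theta = theta.copy()
    best_train_at_best = cur_rmse
    history = [(0, cur_rmse, best_test)]
    n_accepted = 0
    stall = 0
    aborted = False

    it = 0
    while it < cfg.max_iterations:
        it += 1
        work.set_params(theta)
        r = work.forward_normalized(Xn) - tn
        J = lm_jacobian(work, Xn)
        A = J.T @ J
        g = J.T @ r
        sse = float(r @ r)
        accepted = False
        while lam <= cfg.max_damping:
            try:
                delta = np.linalg.solve(
                    A + lam * np.eye(A.shape[0]), -g)
            except np.linalg.LinAlgError:
                lam *= cfg.damping_increase
                continue
            cand = theta + delta
            work.set_params(cand)
            r_new = work.forward_normalized(Xn) - tn
            sse_new = float(r_new @ r_new)
            if np.isfinite(sse_new) and sse_new < sse:
                theta = cand
                lam = max(lam * cfg.damping_decrease, 1e-15)
                accepted = True
                n_accepted += 1
                new_rmse = float(np.sqrt(sse_new / len(tn)))
                rel = (cur_rmse - new_rmse) / max(cur_rmse, 1e-300)
                stall = stall + 1 if rel < cfg.tol else 0
                cur_rmse = new_rmse
                tr = test_rmse(theta)
                history.append((it, cur_rmse, tr))
                if tr < best_test:
                    best_test = tr
                    best_theta = theta.copy()
                    best_train_at_best = cur_rmse
                break
            lam *= cfg.damping_increase
        if not accepted:
            aborted = True
            logger.debug("restart %d: damping exceeded %g at iteration %d",
                         restart_index, cfg.max_damping, it)
            break
        if stall >= cfg.patience:
            break
    return RestartResult(
        theta=best_theta, test_rmse=best_test, train_rmse=best_train_at_best,
        restart_index=restart_index, n_accepted=n_accepted,
        aborted=aborted and n_accepted == 0, history=history,
    )


def train_lm(
    dataset: Dataset,
    split: SplitAssignment | None,
    n_hidden: int,
    config: TrainingConfig | None = None,
    input_names=DEFAULT_INPUTS,
) -> tuple[MLPNetwork, list[RestartResult]]:
    """Best-of-restarts Levenberg-Marquardt fit of an (n_in, n_hidden, 1) net.

    Normalization bounds are fitted on the full ``dataset`` (so all subsets
    map inside [0, 1]) and stored in the returned network.  Residuals are
    defined on normalized sigma.  The winning restart has the lowest
    test-subset RMSE; ties break on training RMSE, then restart index.
    """
    if n_hidden < 1:
        raise ConfigurationError("need at least one hidden neuron")
    cfg = config or TrainingConfig()
    X = design_matrix(dataset, input_names)
    y = dataset.data["sigma"].to_numpy()
    input_norms = tuple(
        fit_normalization(X[:, j], name) for j, name in enumerate(input_names)
    )
    output_norm = fit_normalization(y, "sigma")

    proto = MLPNetwork(
        input_names=tuple(input_names),
        hidden_weights=np.zeros((n_hidden, len(input_names))),
        hidden_biases=np.zeros(n_hidden),
        output_weights=np.zeros(n_hidden),
        output_bias=0.0,
        input_norms=input_norms,
        output_norm=output_norm,
    )
    Xn_all = proto.normalize_inputs(X)
    tn_all = output_norm.normalize(y)
    if split is not None:
        itr = split.indices("training")
        ite = split.indices("test")
        if itr.size == 0:
            raise ConfigurationError("training subset is empty")
        Xn, tn = Xn_all[itr], tn_all[itr]
        Xn_test, tn_test = Xn_all[ite], tn_all[ite]
    else:
        Xn, tn = Xn_all, tn_all
        Xn_test, tn_test = Xn_all[:0], tn_all[:0]

    results: list[RestartResult] = []
    for k in range(cfg.restarts):
        rng = np.random.default_rng(cfg.seed + k)
        theta0 = rng.uniform(-cfg.init_scale, cfg.init_scale, proto.n_params)
        res = _lm_single(proto, Xn, tn, Xn_test, tn_test, theta0, cfg,
                         restart_index=k)
        if res.aborted:
            logger.warning("restart %d aborted (singular normal equations)", k)
            continue
        results.append(res)
    if not results:
        raise TrainingError("all restarts failed")
    results.sort(key=lambda r: (r.test_rmse, r.train_rmse, r.restart_index))
    best = results[0]
    net = replace(proto)
    net.set_params(best.theta.copy())
    return net, results


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------

def save_model(net: MLPNetwork, path, metadata: dict | None = None) -> None:
    """Write the network to a JSON document (full float precision)."""
    doc = {
        "schema_version": SCHEMA_VERSION,
        "architecture": [net.n_in, net.n_hidden, 1],
        "activation": net.activation,
        "input_names": list(net.input_names),
        "input_norms": [
            {"name": s.name, "vmin": s.vmin, "vmax": s.vmax}
            for s in net.input_norms
        ],
        "output_norm": {
            "name": net.output_norm.name,
            "vmin": net.output_norm.vmin,
            "vmax": net.output_norm.vmax,
        },
        "hidden_weights": net.hidden_weights.tolist(),
        "hidden_biases": net.hidden_biases.tolist(),
        "output_weights": net.output_weights.tolist(),
        "output_bias": net.output_bias,
        "metadata": metadata or {},
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(doc, fh, indent=1)


def load_model(path) -> MLPNetwork:
    """Read a network written by :func:`save_model`, validating the schema."""
    with open(path, encoding="utf-8") as fh:
        try:
            doc = json.load(fh)
        except json.JSONDecodeError as exc:
            raise ModelFileError(f"{path}: not valid JSON: {exc}") from exc
    if doc.get("schema_version") != SCHEMA_VERSION:
        raise ModelFileError(
            f"{path}: schema version {doc.get('schema_version')!r}, "
            f"expected {SCHEMA_VERSION}"
        )
    try:
        ni, nh, _ = doc["architecture"]
        W = np.asarray(doc["hidden_weights"], dtype=float)
        bh = np.asarray(doc["hidden_biases"], dtype=float)
        wo = np.asarray(doc["output_weights"], dtype=float)
        bo = float(doc["output_bias"])
        input_norms = tuple(
            NormalizationSpec(d["name"], d["vmin"], d["vmax"])
            for d in doc["input_norms"]
        )
        on = doc["output_norm"]
        output_norm = NormalizationSpec(on["name"], on["vmin"], on["vmax"])
        names = tuple(doc["input_names"])
    except (KeyError, TypeError, ValueError) as exc:
        raise ModelFileError(f"{path}: malformed model document: {exc}") from exc
    got = W.size + bh.size + wo.size + 1
    expected = n_parameters(ni, nh)
    if W.shape != (nh, ni) or got != expected:
        raise ModelFileError(
            f"{path}: weight count {got} inconsistent with architecture "
            f"({ni},{nh},1), expected {expected}"
        )
    return MLPNetwork(
        input_names=names, hidden_weights=W, hidden_biases=bh,
        output_weights=wo, output_bias=bo, input_norms=input_norms,
        output_norm=output_norm, activation=doc.get("activation", "logistic"),
    )
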