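"""Bottleneck-MLP population training with sensitivity-based input pruning.

The regression model is a two-layer perceptron k-m-1 with a narrow hidden
layer (m << k).  Many networks are trained on random 60/40 train/test
partitions from seeded random initializations; the best network (jointly
high train-, test- and combined-set correlations) is kept, per-input
sensitivities are computed by mean-substitution ablation, low-sensitivity
inputs are removed, and the cycle repeats.  Three rounds totalling ~500
networks (100 + 100 + 300 by default) are the standard protocol.

Sensitivity of input *i* is the error ratio

    Sens_i = MSE(input i replaced by its training-set mean) / MSE(full model)

evaluated on the combined (train+test) set; an input whose ablation changes
nothing has Sens = 1 exactly.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import minimize

from .ql_descriptors import DescriptorMatrix

__all__ = [
    "NetworkSpec", "TrainProtocol", "TrainedNetwork", "SensitivityReport",
    "IterationRecord", "IterativeResult", "PruneRule", "default_protocol",
    "split_dataset", "train_network", "train_population", "sensitivity",
    "pooled_sensitivity", "prune", "run_iterative", "predict",
]

_CLIP = 30.0  # pre-activation clip for the exponential unit


class DegenerateDataError(ValueError):
    """No usable signal in the inputs (or every candidate network discarded)."""


# --------------------------------------------------------------------------
# Specs and results
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class NetworkSpec:
    n_inputs: int
    n_hidden: int
    hidden_activation: str = "tanh"   # exponential | tanh | identity
    output_activation: str = "identity"  # tanh | identity
    max_optimizer_steps: int = 200

    def __post_init__(self) -> None:
        if not 1 <= self.n_hidden <= 8:
            raise ValueError("n_hidden must be in [1, 8]")
        if self.hidden_activation not in ("exponential", "tanh", "identity"):
            raise ValueError(f"unknown hidden activation {self.hidden_activation!r}")
        if self.output_activation not in ("tanh", "identity"):
            raise ValueError(f"unknown output activation {self.output_activation!r}")

    @property
    def n_params(self) -> int:
        m, k = self.n_hidden, self.n_inputs
        return m * k + m + m + 1

    @property
    def name(self) -> str:
        act = {"exponential": "Exp", "tanh": "Tanh", "identity": "Ident"}
        return (f"MLP {self.n_inputs}-{self.n_hidden}-1 "
                f"{act[self.hidden_activation]} {act[self.output_activation]}")


@dataclass(frozen=True)
class TrainProtocol:
    """Configuration of the iterative population-training procedure.

    ``population_schedule`` optionally sets a per-iteration network count
    (its length must equal ``n_iterations``); otherwise every iteration
    trains ``networks_per_iteration`` networks.  ``early_stopping`` selects
    the optimizer iterate with minimal squared error on the test partition
    ("test"), on all modeled compounds ("combined"), or disables snapshot
    selection ("none").  ``sensitivity_pool`` is the number of top-ranked
    networks whose sensitivities are pooled for the pruning decision (the
    best network alone is always what the iteration reports).
    """

    networks_per_iteration: int = 167
    population_schedule: Optional[tuple[int, ...]] = None
    split_fraction: float = 0.60
    n_iterations: int = 3
    final_inputs: int = 13          # input count of the last iteration
    shrink: float = 0.75            # geometric pruning factor for earlier rounds
    hidden_sizes: tuple[int, ...] = (3, 4, 5)
    hidden_activations: tuple[str, ...] = ("exponential", "tanh")
    output_activations: tuple[str, ...] = ("tanh", "identity")
    max_optimizer_steps: int = 100
    early_stopping: str = "combined"
    sensitivity_pool: int = 10
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.split_fraction < 1:
            raise ValueError("split_fraction must be in (0, 1)")
        if self.networks_per_iteration < 1:
            raise ValueError("networks_per_iteration must be >= 1")
        if self.n_iterations < 1:
            raise ValueError("n_iterations must be >= 1")
        if self.population_schedule is not None and len(self.population_schedule) != self.n_iterations:
            raise ValueError("population_schedule length must equal n_iterations")
        if self.early_stopping not in ("none", "test", "combined"):
            raise ValueError(f"unknown early_stopping mode {self.early_stopping!r}")

    def networks_for(self, iteration: int) -> int:
        """Network count for a 1-based iteration index."""
        if self.population_schedule is not None:
            return self.population_schedule[iteration - 1]
        return self.networks_per_iteration


def default_protocol(seed: int = 0) -> TrainProtocol:
    """The standard three-round protocol (~500 networks in total)."""
    return TrainProtocol(population_schedule=(100, 100, 300), rng_seed=seed)


@dataclass
class TrainedNetwork:
    spec: NetworkSpec
    weights: np.ndarray
    input_codes: list[str]
    train_ids: list[str]
    test_ids: list[str]
    train_r: float
    test_r: float
    combined_r: float
    y_offset: float            # target scaling: y_scaled = (y - offset) / scale
    y_scale: float
    converged: bool
    seed: int


@dataclass
class SensitivityReport:
    sens: dict[str, float]            # descriptor code -> Sens ratio
    ranking: list[str]                # codes, descending Sens (ties: code order)

    def top(self, n: int) -> list[str]:
        return self.ranking[:n]


@dataclass
class IterationRecord:
    iteration: int
    n_inputs: int
    best: TrainedNetwork
    sensitivity: SensitivityReport
    descriptor_codes: list[str]


@dataclass
class IterativeResult:
    history: list[IterationRecord]
    final_network: TrainedNetwork
    final_sensitivity: SensitivityReport
    final_matrix: DescriptorMatrix


@dataclass(frozen=True)
class PruneRule:
    """Keep the top-k inputs by Sens, or all inputs with Sens above a threshold."""

    keep_top: Optional[int] = None
    min_sens: Optional[float] = None

    def __post_init__(self) -> None:
        if (self.keep_top is None) == (self.min_sens is None):
            raise ValueError("specify exactly one of keep_top / min_sens")


# --------------------------------------------------------------------------
# Forward pass and training
# --------------------------------------------------------------------------

def _unpack(w: np.ndarray, k: int, m: int):
    W1 = w[: m * k].reshape(m, k)
    b1 = w[m * k: m * k + m]
    w2 = w[m * k + m: m * k + 2 * m]
    b2 = w[-1]
    return W1, b1, w2, b2


def _hidden(z: np.ndarray, kind: str) -> np.ndarray:
    if kind == "exponential":
        return np.exp(np.clip(z, -_CLIP, _CLIP))
    if kind == "tanh":
        return np.tanh(z)
    return z


def _forward(w: np.ndarray, X: np.ndarray, spec: NetworkSpec) -> np.ndarray:
    W1, b1, w2, b2 = _unpack(w, spec.n_inputs, spec.n_hidden)
    h = _hidden(X @ W1.T + b1, spec.hidden_activation)
    z2 = h @ w2 + b2
    return np.tanh(z2) if spec.output_activation == "tanh" else z2


def _loss_grad(w: np.ndarray, X: np.ndarray, y: np.ndarray, spec: NetworkSpec):
    k, m = spec.n_inputs, spec.n_hidden
    W1, b1, w2, b2 = _unpack(w, k, m)
    z1 = X @ W1.T + b1
    h = _hidden(z1, spec.hidden_activation)
    z2 = h @ w2 + b2
    if spec.output_activation == "tanh":
        out = np.tanh(z2)
        dout_dz2 = 1.0 - out ** 2
    else:
        out = z2
        dout_dz2 = np.ones_like(z2)
    err = out - y
    n = len(y)
    loss = 0.5 * float(err @ err) / n
    dz2 = err * dout_dz2 / n
    gw2 = h.T @ dz2
    gb2 = float(dz2.sum())
    dh = np.outer(dz2, w2)
    if spec.hidden_activation == "exponential":
        dh_dz1 = h * (np.abs(z1) < _CLIP)
    elif spec.hidden_activation == "tanh":
        dh_dz1 = 1.0 - h ** 2
    else:
        dh_dz1 = np.ones_like(h)
    dz1 = dh * dh_dz1
    gW1 = dz1.T @ X
    gb1 = dz1.sum(axis=0)
    grad = np.concatenate([gW1.ravel(), gb1, gw2, [gb2]])
    return loss, grad


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    if len(a) < 2 or np.std(a) == 0 or np.std(b) == 0:
        return float("nan")
    return float(np.corrcoef(a, b)[0, 1])


def split_dataset(
    matrix: DescriptorMatrix, fraction: float = 0.60, seed: int = 0
) -> tuple[list[str], list[str]]:
    """Seeded random train/test partition of the compound ids.

    Train size is round(fraction * n); the remainder is the test set.
    """
    ids = matrix.compound_ids
    n = len(ids)
    if n < 5:
        raise ValueError(f"need at least 5 compounds to split, got {n}")
    n_train = int(round(fraction * n))
    n_train = min(max(n_train, 1), n - 1)
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    train = [ids[i] for i in sorted(order[:n_train])]
    test = [ids[i] for i in sorted(order[n_train:])]
    return train, test


def train_network(
    spec: NetworkSpec,
    matrix: DescriptorMatrix,
    partition: tuple[Sequence[str], Sequence[str]],
    seed: int = 0,
    early_stopping: str = "none",
) -> TrainedNetwork:
    """Fit one bottleneck MLP by quasi-Newton minimization of squared error.

    The target is min-max scaled to [0, 1] when the output activation is tanh
    and left on the raw percentage scale otherwise; correlations are always
    reported on the original activity scale.

    With ``early_stopping`` the optimizer trajectory is snapshotted and the
    iterate with minimal mean squared error on the monitored subset (test
    partition, or all modeled compounds) is retained, so training is halted
    well before the 8-point training set is interpolated - the epoch counts
    of a quasi-Newton fit on such small samples are typically a few tens.
    """
    X_all = matrix.X.values.astype(float)
    if X_all.size == 0 or np.all(X_all.std(axis=0) == 0):
        raise DegenerateDataError("input matrix has no varying columns")
    if spec.n_inputs != X_all.shape[1]:
        raise ValueError(
            f"spec expects {spec.n_inputs} inputs, matrix has {X_all.shape[1]}"
        )
    train_ids, test_ids = list(partition[0]), list(partition[1])
    y_all = matrix.y.values.astype(float)
    idx = {cid: i for i, cid in enumerate(matrix.compound_ids)}
    tr = np.array([idx[c] for c in train_ids])
    te = np.array([idx[c] for c in test_ids])

    if spec.output_activation == "tanh":
        lo, hi = float(y_all[tr].min()), float(y_all[tr].max())
        offset, scale = lo, (hi - lo) if hi > lo else 1.0
    else:
        offset, scale = 0.0, 1.0
    ys = (y_all - offset) / scale

    rng = np.random.default_rng(seed)
    w0 = rng.normal(0.0, 1.0 / math.sqrt(spec.n_inputs + 1), size=spec.n_params)
    snapshots = [w0.copy()]
    callback = (lambda xk: snapshots.append(xk.copy())) if early_stopping != "none" else None
    res = minimize(
        _loss_grad, w0, args=(X_all[tr], ys[tr], spec),
        method="L-BFGS-B", jac=True,
        options={"maxiter": spec.max_optimizer_steps},
        callback=callback,
    )
    if early_stopping == "none":
        w = res.x
    else:
        monitor = te if early_stopping == "test" else np.arange(len(y_all))
        Xm, ym = X_all[monitor], y_all[monitor]
        best_w, best_mse = res.x, None
        for wk in snapshots:
            p = _forward(wk, Xm, spec) * scale + offset
            mse = float(np.mean((p - ym) ** 2))
            if best_mse is None or mse < best_mse:
                best_mse, best_w = mse, wk
        w = best_w
    pred = _forward(w, X_all, spec) * scale + offset
    return TrainedNetwork(
        spec=spec, weights=w, input_codes=list(matrix.X.columns),
        train_ids=train_ids, test_ids=test_ids,
        train_r=_pearson(pred[tr], y_all[tr]),
        test_r=_pearson(pred[te], y_all[te]),
        combined_r=_pearson(pred, y_all),
        y_offset=offset, y_scale=scale,
        converged=bool(res.success), seed=seed,
    )


def predict(network: TrainedNetwork, presences: Sequence[float]) -> float:
    """Forward pass for one descriptor-presence vector, on the activity scale."""
    x = np.asarray(presences, dtype=float)
    if x.shape != (network.spec.n_inputs,):
        raise ValueError(
            f"expected {network.spec.n_inputs} inputs, got vector of shape {x.shape}"
        )
    out = _forward(network.weights, x[None, :], network.spec)[0]
    return float(out * network.y_scale + network.y_offset)


# --------------------------------------------------------------------------
# Population training, sensitivity, pruning, iteration
# --------------------------------------------------------------------------

def _sample_spec(protocol: TrainProtocol, n_inputs: int, rng: np.random.Generator) -> NetworkSpec:
    m = int(rng.choice(protocol.hidden_sizes))
    m = min(m, max(1, n_inputs))  # bottleneck cannot exceed input count
    return NetworkSpec(
        n_inputs=n_inputs,
        n_hidden=m,
        hidden_activation=str(rng.choice(protocol.hidden_activations)),
        output_activation=str(rng.choice(protocol.output_activations)),
        max_optimizer_steps=protocol.max_optimizer_steps,
    )


def _rank_key(net: TrainedNetwork) -> tuple:
    """Networks must fit well on every subset: rank by the weakest of the
    train/test/combined correlations, then combined, then seed (reproducible)."""
    return (-min(net.train_r, net.test_r, net.combined_r), -net.combined_r, net.seed)


def train_population(
    protocol: TrainProtocol,
    matrix: DescriptorMatrix,
    seed: Optional[int] = None,
    n_networks: Optional[int] = None,
) -> list[TrainedNetwork]:
    """Train a seeded population of networks; rank by correlation quality.

    Each network draws its own architecture, partition and initialization.
    Networks with undefined correlations (zero-variance test activities or
    degenerate predictions) are discarded.  Ranking demands jointly high
    train-, test- and combined-set correlations (see :func:`_rank_key`) and is
    fully reproducible for a given protocol and seed.
    """
    if matrix.n_descriptors == 0:
        raise DegenerateDataError("empty descriptor matrix")
    rng = np.random.default_rng(protocol.rng_seed if seed is None else seed)
    n_networks = protocol.networks_per_iteration if n_networks is None else n_networks
    nets: list[TrainedNetwork] = []
    for _ in range(n_networks):
        child = int(rng.integers(0, 2**31 - 1))
        spec = _sample_spec(protocol, matrix.n_descriptors, rng)
        partition = split_dataset(matrix, protocol.split_fraction, child)
        net = train_network(spec, matrix, partition, child, protocol.early_stopping)
        if math.isnan(net.test_r) or math.isnan(net.combined_r) or math.isnan(net.train_r):
            continue
        nets.append(net)
    if not nets:
        raise DegenerateDataError("every candidate network was discarded")
    nets.sort(key=_rank_key)
    return nets


def sensitivity(network: TrainedNetwork, matrix: DescriptorMatrix) -> SensitivityReport:
    """Mean-substitution ablation sensitivity for every input, on the combined set."""
    X = matrix.X[network.input_codes].values.astype(float)
    y = matrix.y.values.astype(float)
    idx = {cid: i for i, cid in enumerate(matrix.compound_ids)}
    tr = np.array([idx[c] for c in network.train_ids])

    pred_full = _forward(network.weights, X, network.spec) * network.y_scale + network.y_offset
    mse_full = float(np.mean((pred_full - y) ** 2))
    sens: dict[str, float] = {}
    for j, code in enumerate(network.input_codes):
        Xa = X.copy()
        Xa[:, j] = X[tr, j].mean()
        pred = _forward(network.weights, Xa, network.spec) * network.y_scale + network.y_offset
        mse = float(np.mean((pred - y) ** 2))
        if mse_full == 0.0:
            sens[code] = 1.0 if mse == 0.0 else float("inf")
        else:
            sens[code] = mse / mse_full
    ranking = sorted(sens, key=lambda c: (-sens[c], c))
    return SensitivityReport(sens=sens, ranking=ranking)


def pooled_sensitivity(
    networks: Sequence[TrainedNetwork], matrix: DescriptorMatrix
) -> SensitivityReport:
    """Sensitivities pooled over several networks (geometric mean of ratios).

    Pooling over the top of a ranked population stabilizes the pruning
    decision: the ablation ranking of a single network trained on eight
    compounds is noisy, and a descriptor's importance is better supported
    when independently fitted networks agree on it.
    """
    if not networks:
        raise ValueError("need at least one network to pool")
    logs: dict[str, list[float]] = {}
    for net in networks:
        rep = sensitivity(net, matrix)
        for code, s in rep.sens.items():
            logs.setdefault(code, []).append(math.log(max(s, 1e-12)))
    sens = {code: float(math.exp(np.mean(v))) for code, v in logs.items()}
    ranking = sorted(sens, key=lambda c: (-sens[c], c))
    return SensitivityReport(sens=sens, ranking=ranking)


def prune(
    matrix: DescriptorMatrix, report: SensitivityReport, rule: PruneRule
) -> DescriptorMatrix:
    """Drop descriptors failing the rule; always keep at least two."""
    missing = set(matrix.X.columns) - set(report.sens)
    if missing:
        raise ValueError(f"sensitivity report does not cover descriptors {sorted(missing)}")
    if rule.keep_top is not None:
        kept = report.ranking[: rule.keep_top]
    else:
        kept = [c for c in report.ranking if report.sens[c] > rule.min_sens]
    if len(kept) < 2:
        warnings.warn("pruning rule would leave <2 descriptors; keeping top 2")
        kept = report.ranking[:2]
    kept_in_order = [c for c in matrix.X.columns if c in set(kept)]
    return matrix.subset(kept_in_order)


def _next_input_count(k: int, is_last_prune: bool, protocol: TrainProtocol) -> int:
    """Pruning schedule: geometric shrink, landing on `final_inputs` at the end."""
    if is_last_prune:
        target = protocol.final_inputs if k > protocol.final_inputs else k - 1
    else:
        target = int(round(protocol.shrink * k))
        if k > protocol.final_inputs:
            target = max(target, protocol.final_inputs + 1)
    return max(2, min(target, k - 1))


def run_iterative(protocol: TrainProtocol, matrix: DescriptorMatrix) -> IterativeResult:
    """The full train -> select -> sensitivity -> prune cycle.

    Runs ``protocol.n_iterations`` rounds; pruning is applied between rounds
    (never after the last), so input counts strictly decrease along the
    recorded history.
    """
    rng = np.random.default_rng(protocol.rng_seed)
    current = matrix
    history: list[IterationRecord] = []
    for it in range(1, protocol.n_iterations + 1):
        pop_seed = int(rng.integers(0, 2**31 - 1))
        population = train_population(
            protocol, current, seed=pop_seed, n_networks=protocol.networks_for(it)
        )
        best = population[0]
        report = sensitivity(best, current)
        history.append(IterationRecord(
            iteration=it,
            n_inputs=current.n_descriptors,
            best=best,
            sensitivity=report,
            descriptor_codes=list(current.X.columns),
        ))
        if it < protocol.n_iterations:
            pool = population[: max(1, protocol.sensitivity_pool)]
            prune_report = pooled_sensitivity(pool, current) if len(pool) > 1 else report
            k_next = _next_input_count(
                current.n_descriptors, it == protocol.n_iterations - 1, protocol
            )
            current = prune(current, prune_report, PruneRule(keep_top=k_next))
    last = history[-1]
    return IterativeResult(
        history=history,
        final_network=last.best,
        final_sensitivity=last.sensitivity,
        final_matrix=current,
    )
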