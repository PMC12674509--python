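"""Damage-aggregation ("bridge") models between TK and TD.

The bridge maps the vector of scaled internal concentrations C(t) to the
scalar latent damage D(t). Supported aggregation models:

    n                               D = b + sum_i a_i C_i          (linear)
    n_exp                           D = exp(b + sum_i a_i C_i)
    nn_n_exp                        z1 = W1 C + b1;        D = exp(sum a_i z1_i)
    nn_ReLU_n_exp                   z1 = max(W1 C + b1,0); D = exp(sum a_i z1_i)
    nn_ReLU_nn_ReLU_n_exp           two ReLU layers before the exp output
    nn_ReLU_nn_ReLU_nn_ReLU_n_exp   three ReLU layers

Every layer is n x n where n is the number of active ingredients; the
exponential output keeps D(t) strictly positive. The split-alpha variant
reuses the same function (same parameter values) to aggregate per-substance
median thresholds alpha_i into a single effective alpha.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data_model import split_label
from .errors import DomainError, UsageError

_N_LAYERS = {
    "n": 0,
    "n_exp": 0,
    "nn_n_exp": 1,
    "nn_ReLU_n_exp": 1,
    "nn_ReLU_nn_ReLU_n_exp": 2,
    "nn_ReLU_nn_ReLU_nn_ReLU_n_exp": 3,
}

_ACTIVATIONS = {
    "n": (),
    "n_exp": (),
    "nn_n_exp": ("identity",),
    "nn_ReLU_n_exp": ("relu",),
    "nn_ReLU_nn_ReLU_n_exp": ("relu", "relu"),
    "nn_ReLU_nn_ReLU_nn_ReLU_n_exp": ("relu", "relu", "relu"),
}


@dataclass
class Layer:
    """One perceptron layer: z -> sigma(W z + b)."""

    W: np.ndarray
    b: np.ndarray
    activation: str  # "identity" | "relu"

    def __post_init__(self):
        self.W = np.asarray(self.W, dtype=float)
        self.b = np.asarray(self.b, dtype=float)
        if self.activation not in ("identity", "relu"):
            raise DomainError(f"unknown activation {self.activation!r}")


@dataclass
class BridgeSpec:
    """A fully parameterized bridge model.

    ``output_bias`` is used only by the ``n`` and ``n_exp`` labels (the NN
    labels have no output bias). ``split`` marks the split-alpha variant.
    """

    label: str
    n_substances: int
    output_coeffs: np.ndarray
    output_bias: float = 0.0
    layers: list[Layer] = field(default_factory=list)
    split: bool = False

    def __post_init__(self):
        base, suffixed = split_label(self.label)
        self.label = base
        self.split = bool(self.split or suffixed)
        n = self.n_substances
        if n < 1:
            raise DomainError("n_substances must be >= 1")
        self.output_coeffs = np.asarray(self.output_coeffs, dtype=float)
        if self.output_coeffs.shape != (n,):
            raise DomainError("output_coeffs must have length n_substances")
        expected = _N_LAYERS[base]
        if len(self.layers) != expected:
            raise DomainError(
                f"label {base!r} needs {expected} layers, got {len(self.layers)}"
            )
        for k, (layer, act) in enumerate(zip(self.layers, _ACTIVATIONS[base])):
            if layer.W.shape != (n, n) or layer.b.shape != (n,):
                raise DomainError(f"layer {k + 1}: expected W {n}x{n}, b len {n}")
            if layer.activation != act:
                raise DomainError(
                    f"layer {k + 1}: label {base!r} expects activation {act!r}"
                )
        if self.split and base == "n":
            raise UsageError("split-alpha requires an exponential-output label")

    @property
    def exponential_output(self) -> bool:
        return self.label != "n"

    @property
    def model_label(self) -> str:
        return self.label + ("_split" if self.split else "")


def bridge_function(
    label: str,
    C: np.ndarray,
    weights: list[np.ndarray],
    biases: list[np.ndarray],
    a: np.ndarray,
    b: float | np.ndarray = 0.0,
) -> np.ndarray:
    """Batched evaluation of a bridge model.

    C: (..., n) input vectors; weights[k]: (..., n, n); biases[k]: (..., n);
    a: (..., n); b scalar or (...,). Leading batch dimensions broadcast.
    Returns D with shape (...,).
    """
    base, _ = split_label(label)
    z = C
    for W, bk, act in zip(weights, biases, _ACTIVATIONS[base]):
        z = np.einsum("...ij,...j->...i", W, z) + bk
        if act == "relu":
            z = np.maximum(z, 0.0)
    lin = np.einsum("...i,...i->...", a, z)
    if base == "n":
        return lin + b
    with np.errstate(over="ignore"):
        if base == "n_exp":
            return np.exp(lin + b)
        return np.exp(lin)


@dataclass
class DamageTrajectory:
    """Damage D(t) on a time grid with its running maximum."""

    times: np.ndarray
    values: np.ndarray
    running_max: np.ndarray

    @classmethod
    def from_values(cls, times, values) -> "DamageTrajectory":
        times = np.asarray(times, dtype=float)
        values = np.asarray(values, dtype=float)
        return cls(times, values, np.maximum.accumulate(values))


def evaluate_bridge(spec: BridgeSpec, times, C: np.ndarray) -> DamageTrajectory:
    """Map internal concentrations to a damage trajectory.

    C: (T, n_substances) internal concentrations on the grid ``times``.
    Exponential-output labels return strictly positive damage; the plain
    ``n`` label may go negative (the survival stage clamps non-positive
    running maxima to "no effect").
    """
    C = np.atleast_2d(np.asarray(C, dtype=float))
    if C.shape[1] != spec.n_substances:
        raise DomainError(
            f"C has {C.shape[1]} columns, spec expects {spec.n_substances}"
        )
    D = bridge_function(
        spec.label,
        C,
        [l.W for l in spec.layers],
        [l.b for l in spec.layers],
        spec.output_coeffs,
        spec.output_bias,
    )
    return DamageTrajectory.from_values(times, D)


def effective_alpha(spec: BridgeSpec, marginal_alphas) -> float:
    """Aggregate per-substance threshold medians with the damage bridge.

    The split-alpha variant expresses the global median threshold as the
    bridge function applied to the marginal alpha_i, sharing the parameter
    values of the damage aggregation.
    """
    if not spec.split:
        raise UsageError("effective_alpha requires a split-variant spec")
    alphas = np.asarray(marginal_alphas, dtype=float)
    if alphas.shape != (spec.n_substances,):
        raise DomainError("marginal_alphas must have length n_substances")
    if np.any(alphas <= 0):
        raise DomainError("marginal alphas must be > 0")
    return float(
        bridge_function(
            spec.label,
            alphas,
            [l.W for l in spec.layers],
            [l.b for l in spec.layers],
            spec.output_coeffs,
            spec.output_bias,
        )
    )


def count_parameters(label: str, n_substances: int) -> int:
    """Number of free bridge scalars (weights + biases + output terms)."""
    base, _ = split_label(label)
    n = n_substances
    n_layer = _N_LAYERS[base] * (n * n + n)
    if base in ("n", "n_exp"):
        return n_layer + n + 1  # a_i plus output bias b
    return n_layer + n


def spec_to_table(spec: BridgeSpec) -> pd.DataFrame:
    """Serialize a BridgeSpec to a flat named-parameter table."""
    rows = []
    for k, layer in enumerate(spec.layers, start=1):
        for i in range(spec.n_substances):
            for j in range(spec.n_substances):
                rows.append((f"W{k}_{i + 1}_{j + 1}", k, i + 1, j + 1,
                             layer.W[i, j]))
            rows.append((f"b{k}_{i + 1}", k, i + 1, 0, layer.b[i]))
    for i in range(spec.n_substances):
        rows.append((f"a_{i + 1}", 0, i + 1, 0, spec.output_coeffs[i]))
    if spec.label in ("n", "n_exp"):
        rows.append(("b", 0, 0, 0, spec.output_bias))
    return pd.DataFrame(rows, columns=["name", "layer", "row", "col", "value"])


def spec_from_table(
    label: str, n_substances: int, table: pd.DataFrame
) -> BridgeSpec:
    """Rebuild a BridgeSpec from its flat named-parameter table."""
    base, is_split = split_label(label)
    values = dict(zip(table["name"], table["value"]))
    n = n_substances
    layers = []
    for k, act in enumerate(_ACTIVATIONS[base], start=1):
        W = np.array(
            [[values[f"W{k}_{i + 1}_{j + 1}"] for j in range(n)]
             for i in range(n)]
        )
        b = np.array([values[f"b{k}_{i + 1}"] for i in range(n)])
        layers.append(Layer(W, b, act))
    a = np.array([values[f"a_{i + 1}"] for i in range(n)])
    bias = float(values.get("b", 0.0))
    return BridgeSpec(
        label=base,
        n_substances=n,
        output_coeffs=a,
        output_bias=bias,
        layers=layers,
        split=is_split,
    )
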