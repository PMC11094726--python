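"""Integrated gradients for input features and for hidden-layer neurons.

Attributions are path integrals of gradients along the straight line
x' + beta (x - x'), beta in [0, 1], from an all-zeros baseline x' to the
input x, approximated by an m-point quadrature (see :class:`IGConfig` for the
choice of rule).  The completeness property — attributions sum to
F(x) - F(x') — is the built-in sanity check and holds in the limit m -> inf.

Input-level attributions are the textbook form
    a_i = (x_i - x'_i) * sum_k w_k dF/dx_i(x' + beta_k (x - x')).

Layer-level attributions treat the hidden activations h(beta) along the same
input-space path as the differentiation surface:
    a_j = sum_k  w_k * dF/dh_j(beta_k) * dh_j/dbeta(beta_k),
where dh/dbeta is propagated forward analytically through the ReLU layers.
Summing over j telescopes the chain rule to the output difference, which is
why this exact form is used instead of an averaged-gradient times
activation-difference shortcut.

By default F is the model's output probability; differentiating the
pre-logistic output (logit space) is available as an option.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np

from .network import TrainedModel, _as_matrix

__all__ = ["IGConfig", "AttributionVector", "ig_input", "ig_layer"]


@dataclass
class IGConfig:
    """Path discretization: number of steps ``m`` and the baseline vector
    (all-zeros when None, i.e. the empty fingerprint).

    ``method`` selects the quadrature:

    * ``segmented`` (default): along the straight path every ReLU
      pre-activation is piecewise linear in beta, so the kink locations can be
      found analytically; the integrand is smooth between kinks and per-segment
      Gauss-Legendre drives the completeness gap to near machine precision at
      modest m.
    * ``gausslegendre``: single global Gauss-Legendre rule with m nodes (the
      rule mainstream attribution libraries default to).
    * ``right``: the textbook right-endpoint sum at beta = k/m, k = 1..m,
      whose error decays only like 1/m.
    """

    m: int = 50
    baseline: np.ndarray | None = None
    output: Literal["proba", "logit"] = "proba"
    method: Literal["segmented", "gausslegendre", "right"] = "segmented"

    def __post_init__(self):
        if self.m < 1:
            raise ValueError("m must be >= 1")


@dataclass
class AttributionVector:
    values: np.ndarray
    scope: str  # "input" or "layer-k"

    @property
    def total(self) -> float:
        return float(self.values.sum())

    def to_json_dict(self) -> dict:
        return {"scope": self.scope, "values": [float(v) for v in self.values]}


def _relu_kinks(model: TrainedModel, x: np.ndarray, baseline: np.ndarray) -> np.ndarray:
    """Sorted path parameters where some hidden pre-activation crosses zero."""
    d = x - baseline
    kinks: list[float] = []
    # layer 1 pre-activations are globally linear in beta
    c = baseline @ model.weights[0] + model.biases[0]
    e = d @ model.weights[0]
    with np.errstate(divide="ignore", invalid="ignore"):
        roots = -c / e
    kinks.extend(float(r) for r in roots[np.isfinite(roots)] if 0.0 < r < 1.0)
    if model.n_layers > 2:
        # within each layer-1 segment the layer-2 pre-activations are linear too
        bounds = sorted({0.0, 1.0, *kinks})
        for a, b in zip(bounds[:-1], bounds[1:]):
            mid = 0.5 * (a + b)
            active = (c + mid * e) > 0
            c2 = (np.where(active, c, 0.0) @ model.weights[1]) + model.biases[1]
            e2 = np.where(active, e, 0.0) @ model.weights[1]
            with np.errstate(divide="ignore", invalid="ignore"):
                roots2 = -c2 / e2
            kinks.extend(float(r) for r in roots2[np.isfinite(roots2)] if a < r < b)
    return np.array(sorted(set(kinks)))


def _quadrature(
    cfg: IGConfig,
    model: TrainedModel | None = None,
    x: np.ndarray | None = None,
    baseline: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """(betas, weights) for integrating over the path parameter in [0, 1]."""
    if cfg.method == "right":
        return np.arange(1, cfg.m + 1) / cfg.m, np.full(cfg.m, 1.0 / cfg.m)
    if cfg.method == "gausslegendre" or model is None:
        nodes, weights = np.polynomial.legendre.leggauss(cfg.m)
        return (nodes + 1.0) / 2.0, weights / 2.0
    # segmented: per-segment Gauss-Legendre between analytically located kinks
    bounds = np.concatenate([[0.0], _relu_kinks(model, x, baseline), [1.0]])
    n_seg = len(bounds) - 1
    per_seg = max(2, int(np.ceil(cfg.m / n_seg)))
    nodes, weights = np.polynomial.legendre.leggauss(per_seg)
    betas, qw = [], []
    for a, b in zip(bounds[:-1], bounds[1:]):
        half = 0.5 * (b - a)
        betas.append(a + half * (nodes + 1.0))
        qw.append(weights * half)
    return np.concatenate(betas), np.concatenate(qw)


def _path_points(x: np.ndarray, baseline: np.ndarray, betas: np.ndarray) -> np.ndarray:
    return baseline[None, :] + betas[:, None] * (x - baseline)[None, :]


def _resolve(model: TrainedModel, x, cfg: IGConfig) -> tuple[np.ndarray, np.ndarray]:
    xv = _as_matrix(x)[0]
    baseline = np.zeros_like(xv) if cfg.baseline is None else np.asarray(cfg.baseline, float)
    if baseline.shape != xv.shape:
        raise ValueError("baseline length does not match input length")
    return xv, baseline


def _output_and_grad_seed(model: TrainedModel, fwd: dict, output: str) -> np.ndarray:
    """d output / d z_out per path point (column vector)."""
    if output == "logit":
        return np.ones_like(fwd["pre"][-1])
    p = fwd["act"][-1]
    return p * (1.0 - p)


def model_output(model: TrainedModel, x, cfg: IGConfig) -> float:
    fwd = model.forward(x)
    return float(fwd["logit"][0] if cfg.output == "logit" else fwd["proba"][0])


def ig_input(model: TrainedModel, x, cfg: IGConfig | None = None) -> AttributionVector:
    """Per-input-feature integrated gradients along the straight path."""
    cfg = cfg or IGConfig()
    xv, baseline = _resolve(model, x, cfg)
    betas, qw = _quadrature(cfg, model, xv, baseline)
    points = _path_points(xv, baseline, betas)
    fwd = model.forward(points)
    # backprop d output / d input for all path points at once
    delta = _output_and_grad_seed(model, fwd, cfg.output)
    for l in range(model.n_layers - 1, 0, -1):
        delta = (delta @ model.weights[l].T) * (fwd["pre"][l - 1] > 0)
    grads = delta @ model.weights[0].T  # m x n_inputs
    values = (xv - baseline) * (qw[:, None] * grads).sum(axis=0)
    return AttributionVector(values=values, scope="input")


def ig_layer(model: TrainedModel, x, layer: int, cfg: IGConfig | None = None) -> AttributionVector:
    """Per-hidden-neuron integrated gradients along the input-space path.

    ``layer`` is 1-based and must index a hidden layer.
    """
    cfg = cfg or IGConfig()
    n_hidden = model.n_layers - 1
    if not 1 <= layer <= n_hidden:
        raise ValueError(f"layer must be in 1..{n_hidden}")
    xv, baseline = _resolve(model, x, cfg)
    betas, qw = _quadrature(cfg, model, xv, baseline)
    points = _path_points(xv, baseline, betas)
    fwd = model.forward(points)
    # forward-mode derivative of hidden activations w.r.t. beta
    d = xv - baseline
    dh = np.broadcast_to(d, points.shape)
    for l in range(layer):
        dh = (dh @ model.weights[l]) * (fwd["pre"][l] > 0)
    # reverse-mode derivative of the output w.r.t. the layer activations
    delta = _output_and_grad_seed(model, fwd, cfg.output)
    for l in range(model.n_layers - 1, layer, -1):
        delta = (delta @ model.weights[l].T) * (fwd["pre"][l - 1] > 0)
    grads = delta @ model.weights[layer].T  # m x hidden_size
    values = (qw[:, None] * grads * dh).sum(axis=0)
    return AttributionVector(values=values, scope=f"layer-{layer}")
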