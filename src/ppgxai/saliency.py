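"""Attribution methods and the post-processing that turns them into
attention maps.

Three attribution routes are provided, matching the three saliency families
the metrics are designed to compare:

* :func:`integrated_gradients` — gradients averaged along the straight path
  from a baseline to the input (midpoint quadrature), scaled by the input
  difference; satisfies the completeness axiom
  ``sum_j attr_j ~= F(x) - F(baseline)``.
* :func:`guided_backprop` — a single backward pass where each ReLU zeroes
  both positions with negative forward pre-activation and negative incoming
  backward signal; the resulting map is clamped at zero, so it is
  nonnegative by construction.
* :func:`reference_attribution` — expected gradients: integrated gradients
  averaged over a background of reference inputs. It honors the same
  summation-to-delta property as difference-from-reference methods
  (``sum_j attr_j ~= F(x) - mean_ref F(ref)``).

An attention map is the elementwise absolute value of an attribution
(guided maps pass through unchanged); 2D attributions are reduced to 1D by
taking the maximum absolute attribution over the rows of each column.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

__all__ = [
    "Attribution",
    "UnsupportedModelError",
    "integrated_gradients",
    "guided_backprop",
    "reference_attribution",
    "to_attention",
    "reduce_columns",
    "attention_map",
    "AttentionExtractor",
    "METHODS",
]

#: Canonical method names; "deepshap" is accepted as an alias for the
#: expected-gradients reference method.
METHODS = ("integrated_gradients", "guided", "expected_gradients")
_ALIASES = {"deepshap": "expected_gradients", "reference": "expected_gradients"}

_GRAD_CHUNK = 64  # rows per backward batch, bounds im2col memory


class UnsupportedModelError(TypeError):
    """The model does not meet an attribution method's architectural contract."""


@dataclass
class Attribution:
    """A signed per-input-element importance map.

    ``values`` has the same shape as the model input it explains (1D signal
    or 2D image); ``baseline_descriptor`` documents the reference input(s).
    """

    values: np.ndarray
    method: str
    baseline_descriptor: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if not np.all(np.isfinite(self.values)):
            raise ValueError("attribution contains non-finite values")


def _probability(model, X: np.ndarray) -> np.ndarray:
    p = model.predict_proba(np.atleast_2d(X))
    p = np.asarray(p, dtype=float)
    if p.ndim == 2:
        if p.shape[1] != 2:
            raise UnsupportedModelError("model output must be a single probability")
        p = p[:, 1]
    return p


def _input_gradient(model, X: np.ndarray, guided: bool = False) -> np.ndarray:
    if not hasattr(model, "input_gradient"):
        raise UnsupportedModelError(
            "model must expose input gradients of its scalar output "
            "(an `input_gradient(X)` method)"
        )
    return np.asarray(model.input_gradient(np.atleast_2d(X), guided=guided))


def _batched_gradients(model, points: np.ndarray) -> np.ndarray:
    out = np.empty_like(points)
    for start in range(0, points.shape[0], _GRAD_CHUNK):
        out[start : start + _GRAD_CHUNK] = _input_gradient(
            model, points[start : start + _GRAD_CHUNK]
        )
    return out


def integrated_gradients(
    model,
    x: np.ndarray,
    baseline: np.ndarray | None = None,
    steps: int = 64,
) -> Attribution:
    """Integrated gradients of the model's probability output at ``x``.

    ``attr_j = (x_j - baseline_j) * mean_k dF/dx_j`` evaluated at midpoints
    ``baseline + (k - 1/2)/steps * (x - baseline)``, ``k = 1..steps``.
    The default baseline is the all-zero signal.
    """
    if steps < 1:
        raise ValueError("steps must be >= 1")
    x = np.asarray(x, dtype=float).ravel()
    baseline = np.zeros_like(x) if baseline is None else np.asarray(baseline, dtype=float).ravel()
    if baseline.shape != x.shape:
        raise ValueError("baseline must have the same shape as the input")
    alphas = (np.arange(1, steps + 1) - 0.5) / steps
    points = baseline[None, :] + alphas[:, None] * (x - baseline)[None, :]
    grads = _batched_gradients(model, points)
    values = (x - baseline) * grads.mean(axis=0)
    return Attribution(values, "integrated_gradients", f"zeros-path, {steps} midpoint steps")


def guided_backprop(model, x: np.ndarray) -> Attribution:
    """Guided-backprop saliency: one modified backward pass, clamped at 0."""
    activation = getattr(model, "activation", None)
    if activation is None:
        activation = getattr(getattr(model, "model_", None), "activation", "relu")
    if activation != "relu":
        raise UnsupportedModelError(
            f"guided backprop requires ReLU-family nonlinearities, got {activation!r}"
        )
    x = np.asarray(x, dtype=float).ravel()
    grad = _input_gradient(model, x, guided=True)[0]
    return Attribution(np.maximum(grad, 0.0), "guided", "none (single backward pass)")


def default_background(
    n: int, n_references: int = 16, jitter: float = 0.01, seed: int = 0
) -> np.ndarray:
    """All-zero reference signals plus small Gaussian jitter (seeded)."""
    rng = np.random.default_rng(seed)
    return jitter * rng.standard_normal((n_references, n))


def reference_attribution(
    model,
    x: np.ndarray,
    background: np.ndarray | None = None,
    seed: int = 0,
    steps: int = 32,
) -> Attribution:
    """Expected-gradients attribution against a background of references.

    Averages :func:`integrated_gradients` over every reference, so the
    attributions sum to ``F(x) - mean_ref F(ref)`` (summation-to-delta).
    """
    x = np.asarray(x, dtype=float).ravel()
    if background is None:
        background = default_background(x.size, seed=seed)
    background = np.atleast_2d(np.asarray(background, dtype=float))
    if background.shape[0] == 0:
        raise ValueError("background must contain at least one reference input")
    total = np.zeros_like(x)
    for ref in background:
        total += integrated_gradients(model, x, baseline=ref, steps=steps).values
    values = total / background.shape[0]
    return Attribution(
        values,
        "expected_gradients",
        f"{background.shape[0]} references, {steps} midpoint steps each",
    )


def to_attention(attr: Attribution | np.ndarray) -> np.ndarray:
    """Nonnegative attention map: elementwise absolute attribution.

    Guided maps are already nonnegative and pass through unchanged. The
    input must be 1D; reduce 2D maps with :func:`reduce_columns` first.
    """
    values = attr.values if isinstance(attr, Attribution) else np.asarray(attr, dtype=float)
    if values.ndim != 1:
        raise ValueError("attention requires a 1D attribution; apply reduce_columns first")
    return np.abs(values)


def reduce_columns(attr2d: Attribution | np.ndarray, n: int | None = None) -> np.ndarray:
    """Reduce a 2D (H x W) attribution to a length-``n`` attention profile.

    Takes the maximum absolute attribution over the rows of each column,
    then maps the length-W profile onto ``n`` samples by nearest-neighbor
    index scaling when ``W != n``.
    """
    values = attr2d.values if isinstance(attr2d, Attribution) else np.asarray(attr2d, dtype=float)
    if values.ndim != 2 or values.size == 0:
        raise ValueError("reduce_columns requires a non-empty 2D attribution")
    profile = np.abs(values).max(axis=0)
    W = profile.size
    if n is None or n == W:
        return profile
    src = np.minimum((np.arange(n) * W / n + 0.5).astype(int), W - 1)
    return profile[src]


def attention_map(
    model,
    x: np.ndarray,
    method: str = "integrated_gradients",
    *,
    steps: int = 64,
    baseline: np.ndarray | None = None,
    background: np.ndarray | None = None,
    seed: int = 0,
) -> np.ndarray:
    """Compute the attention map of ``model`` on one segment with ``method``."""
    method = _ALIASES.get(method, method)
    if method == "integrated_gradients":
        attr = integrated_gradients(model, x, baseline=baseline, steps=steps)
    elif method == "guided":
        attr = guided_backprop(model, x)
    elif method == "expected_gradients":
        attr = reference_attribution(model, x, background=background, seed=seed, steps=steps)
    else:
        raise ValueError(f"unknown saliency method {method!r}; choose from {METHODS}")
    return to_attention(attr)


class AttentionExtractor(TransformerMixin, BaseEstimator):
    """Transformer turning segments into attention maps for a fixed model.

    Parameters
    ----------
    model : fitted classifier exposing ``predict_proba`` and ``input_gradient``
    method : {"integrated_gradients", "guided", "expected_gradients", "deepshap"}
    steps : int
        Path steps for the gradient-integration methods.
    n_references : int
        Background size for expected gradients.
    seed : int
        Seeds the jittered background references.
    """

    def __init__(
        self,
        model=None,
        method: str = "integrated_gradients",
        steps: int = 64,
        n_references: int = 16,
        seed: int = 0,
    ):
        self.model = model
        self.method = method
        self.steps = steps
        self.n_references = n_references
        self.seed = seed

    def fit(self, X=None, y=None):
        if self.model is None:
            raise ValueError("AttentionExtractor requires a fitted model")
        if _ALIASES.get(self.method, self.method) not in METHODS:
            raise ValueError(f"unknown saliency method {self.method!r}")
        return self

    def transform(self, X) -> np.ndarray:
        """Attention maps for each row of ``X``; shape (n_records, n)."""
        self.fit()
        X = np.atleast_2d(np.asarray(X, dtype=float))
        method = _ALIASES.get(self.method, self.method)
        background = None
        if method == "expected_gradients":
            background = default_background(
                X.shape[1], n_references=self.n_references, seed=self.seed
            )
        return np.stack(
            [
                attention_map(
                    self.model, row, method, steps=self.steps, background=background,
                    seed=self.seed,
                )
                for row in X
            ]
        )
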