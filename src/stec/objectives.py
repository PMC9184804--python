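"""The spatio-temporally efficient coding objective and its gradients.

Two objectives are combined, ``L = L_temporal + lambda * L_spatial``:

- **Temporal difference** (``L_temporal``): with the image clamped, the squared
  component-wise difference between the network state reached after ``t``
  steps and the state reached after ``t + 1`` steps, summed over the minibatch
  and over every anchor ``t`` for which both compositions fit inside the
  processing window.  At the image layer, the deeper composition is *defined*
  as the presented image itself, so the term compares the top-down
  reconstruction against the true image and embeds reconstruction error.

- **Negative entropy** (``L_spatial``): the summed log pre-normalised density
  ``log P(x) = log Q(x) - log Q'(x)`` of the minibatch responses of each
  hierarchy.  ``Q`` is a Gaussian kernel density estimate (partition constant
  omitted) whose default scope is *per-unit marginal* — each unit's batch of
  scalar responses gets a 1-D density with kernel width
  ``0.1 = 0.1 * sqrt(1)`` — so maximising entropy means driving every unit's
  response distribution toward uniform, Laughlin-style; a joint
  full-dimensional estimate (width ``0.1 * sqrt(dim)``) is available as an
  option.  By default the window's steps are pooled into one sample set, so a
  response that merely repeats over time raises its own density: the entropy
  term genuinely opposes the temporal term, which is what makes the balance
  parameter meaningful.  ``Q'`` is the same estimate over pseudo-uniform
  samples of the response domain ``[0, 1]^dim`` and divides out the
  boundary-induced depression of ``Q``; under the sparseness constraint its
  samples are drawn on ``[-1, 1]^dim``, which favours responses near zero.
  Minimising ``L_spatial`` maximises the response entropy.

Gradients are computed by backpropagation through time over the whole
processing window, with respect to every weight matrix and bias.  Gradients
flow through the KDE both as query and as sample; the ``Q'`` samples are
constants.  The structural zero-mask of the image -> hierarchy-1 matrix is
applied to its gradient.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

from .model import (
    ModelParams,
    NetworkState,
    Trajectory,
    initial_state,
    rollout,
    _flatten_images,
)

_TINY = 1e-300


@dataclass(frozen=True)
class ObjectiveConfig:
    """Configuration of the combined objective.

    ``lambda_reg`` balances the two terms (0 = pure temporal smoothing,
    large = pure entropy maximisation); ``kernel_width_factor`` scales the KDE
    bandwidth ``factor * sqrt(dim)``; ``sparse_constraint`` draws the
    compensation samples on ``[-1, 1]^dim``; ``spatial_time_steps`` selects
    which window steps (1-based) enter the entropy term (``None`` = every step
    from 2 to the window end); ``leave_one_out`` excludes the query point from
    its own density estimate; ``kde_mode`` chooses per-unit marginal densities
    (default) or one joint full-dimensional density; ``pool_time_steps`` pools
    the selected steps into a single sample set instead of estimating one
    density per step; ``temporal_reduction`` reduces each hierarchy's temporal
    term by component sum (default) or component mean.
    """

    lambda_reg: float = 10.0
    kernel_width_factor: float = 0.1
    sparse_constraint: bool = False
    n_compensation_samples: int = 200
    spatial_time_steps: tuple | None = None
    leave_one_out: bool = False
    kde_mode: str = "marginal"
    pool_time_steps: bool = True
    temporal_reduction: str = "sum"

    def __post_init__(self) -> None:
        if self.lambda_reg < 0:
            raise ValueError("lambda_reg must be >= 0")
        if self.kernel_width_factor <= 0:
            raise ValueError("kernel_width_factor must be > 0")
        if self.n_compensation_samples < 2:
            raise ValueError("n_compensation_samples must be >= 2")
        if self.kde_mode not in ("marginal", "joint"):
            raise ValueError("kde_mode must be 'marginal' or 'joint'")
        if self.temporal_reduction not in ("mean", "sum"):
            raise ValueError("temporal_reduction must be 'mean' or 'sum'")

    def kernel_width(self, dim: int) -> float:
        return self.kernel_width_factor * np.sqrt(dim)


@dataclass
class ObjectiveReport:
    """Objective values for one minibatch window."""

    l_temporal: float
    l_spatial: float
    l_total: float
    per_hierarchy_temporal: list
    per_hierarchy_spatial: list

    def to_json(self) -> str:
        return json.dumps(
            {
                "l_temporal": self.l_temporal,
                "l_spatial": self.l_spatial,
                "l_total": self.l_total,
                "per_hierarchy_temporal": list(self.per_hierarchy_temporal),
                "per_hierarchy_spatial": list(self.per_hierarchy_spatial),
            }
        )


# ---------------------------------------------------------------------------
# Kernel density estimation


def kde_density(samples: np.ndarray, queries: np.ndarray, width: float) -> np.ndarray:
    """Unnormalised Gaussian KDE: mean over samples of ``exp(-||q-s||^2/(2 w^2))``.

    The partition constant is omitted consistently, so the density at a sample
    point with a single-sample estimate is exactly 1 (the kernel peak).
    """
    samples = np.atleast_2d(np.asarray(samples, dtype=float))
    queries = np.atleast_2d(np.asarray(queries, dtype=float))
    if samples.shape[0] == 0:
        raise ValueError("samples must be nonempty")
    if width <= 0:
        raise ValueError("width must be > 0")
    sq = cdist(queries, samples, metric="sqeuclidean")
    return np.exp(-sq / (2.0 * width**2)).mean(axis=1)


def compensation_samples(
    dim: int, config: ObjectiveConfig, rng: np.random.Generator
) -> np.ndarray:
    """Pseudo-uniform samples of the response domain used for ``Q'``."""
    if dim < 1:
        raise ValueError("dim must be >= 1")
    lo = -1.0 if config.sparse_constraint else 0.0
    return rng.uniform(lo, 1.0, size=(config.n_compensation_samples, dim))


def compensation_density(
    queries: np.ndarray, dim: int, config: ObjectiveConfig, seed: int
) -> np.ndarray:
    """The compensation density ``Q'`` at each query point.

    ``Q'`` captures the intrinsic, boundary-induced non-uniformity of the raw
    KDE on a bounded domain; dividing by it corrects the depression of ``Q``
    near the edges of ``[0, 1]^dim``.
    """
    rng = np.random.default_rng(seed)
    u = compensation_samples(dim, config, rng)
    q = kde_density(u, queries, config.kernel_width(dim))
    return np.maximum(q, _TINY)


# ---------------------------------------------------------------------------
# Temporal objective


def _temporal_anchors(window: int) -> range:
    """Anchor times t (1-based) with both compositions inside the window."""
    if window < 3:
        raise ValueError("window too short for the temporal objective (need >= 3 steps)")
    return range(2, window)


def temporal_objective(trajectory: Trajectory, images: np.ndarray, reduction: str = "sum"):
    """Temporal-difference objective of one clamped-image window.

    Returns ``(value, per_hierarchy)`` where ``per_hierarchy[0]`` is the
    reconstruction-vs-image term and ``per_hierarchy[h]`` the consecutive-state
    term of hierarchy ``h``.  The batch and anchor sums are plain sums; with
    ``reduction="sum"`` (default) components are summed as well, while
    ``reduction="mean"`` gives each hierarchy the mean over its components so
    layers of very different size (6144 pixels vs 64 units) carry equal
    weight.
    """
    T = len(trajectory)
    anchors = _temporal_anchors(T)
    H = len(trajectory.states[0].responses) - 1
    images = np.atleast_2d(np.asarray(images, dtype=float))
    if images.shape != trajectory.states[0].responses[0].shape:
        images = images.reshape(trajectory.states[0].responses[0].shape)
    per_h = np.zeros(H + 1)
    for t in anchors:
        s_t = trajectory.states[t - 1]
        s_t1 = trajectory.states[t]
        for h in range(1, H + 1):
            d = s_t.responses[h] - s_t1.responses[h]
            per_h[h] += float(np.sum(d * d)) / (d.shape[1] if reduction == "mean" else 1)
        dr = s_t.reconstruction - images
        per_h[0] += float(np.sum(dr * dr)) / (dr.shape[1] if reduction == "mean" else 1)
    return float(per_h.sum()), per_h.tolist()


# ---------------------------------------------------------------------------
# Spatial (entropy) objective


def _spatial_value_and_grad(
    x: np.ndarray, u: np.ndarray, width: float, leave_one_out: bool, want_grad: bool
):
    """``sum_n log(Q(x_n)/Q'(x_n))`` over a minibatch, and its gradient wrt x."""
    n = x.shape[0]
    if n < 2:
        raise ValueError("spatial objective needs at least 2 responses")
    w2 = width**2
    k = np.exp(-cdist(x, x, metric="sqeuclidean") / (2.0 * w2))
    if leave_one_out:
        np.fill_diagonal(k, 0.0)
        q = np.maximum(k.sum(axis=1) / (n - 1), _TINY)
        denom = n - 1
    else:
        q = np.maximum(k.mean(axis=1), _TINY)
        denom = n
    ku = np.exp(-cdist(x, u, metric="sqeuclidean") / (2.0 * w2))
    qp = np.maximum(ku.mean(axis=1), _TINY)
    value = float(np.sum(np.log(q) - np.log(qp)))
    if not want_grad:
        return value, None
    # d/dx_n of sum_k log Q(x_k): the kernel is symmetric, so pair (n, k)
    # contributes K_nk (x_k - x_n) (1/Q_n + 1/Q_k) / (denom w^2).
    c = k * (1.0 / q[:, None] + 1.0 / q[None, :])
    grad = (c @ x - c.sum(axis=1)[:, None] * x) / (denom * w2)
    # d/dx_n of -sum_n log Q'(x_n); the Q' samples are constants.
    b = ku / qp[:, None]
    m = u.shape[0]
    grad += (b.sum(axis=1)[:, None] * x - b @ u) / (m * w2)
    return value, grad


def _spatial_value_and_grad_marginal(
    x: np.ndarray, u: np.ndarray, width: float, leave_one_out: bool, want_grad: bool
):
    """Per-unit marginal KDE entropy term, summed over units and batch.

    Each unit's batch of scalar responses gets its own 1-D density estimate
    ``Q`` (kernel width ``width``) and 1-D compensation density ``Q'`` from
    the matching column of the pseudo-uniform samples ``u``.
    """
    n, d = x.shape
    if n < 2:
        raise ValueError("spatial objective needs at least 2 responses")
    w2 = width**2
    diff = x[:, None, :] - x[None, :, :]  # (n, n, d)
    k = np.exp(-(diff**2) / (2.0 * w2))
    if leave_one_out:
        k[np.arange(n), np.arange(n), :] = 0.0
        q = np.maximum(k.sum(axis=1) / (n - 1), _TINY)
        denom = n - 1
    else:
        q = np.maximum(k.mean(axis=1), _TINY)
        denom = n
    du = x[:, None, :] - u[None, :, :]  # (n, m, d)
    ku = np.exp(-(du**2) / (2.0 * w2))
    qp = np.maximum(ku.mean(axis=1), _TINY)
    value = float(np.sum(np.log(q) - np.log(qp)))
    if not want_grad:
        return value, None
    c = k * (1.0 / q[:, None, :] + 1.0 / q[None, :, :])
    grad = -(c * diff).sum(axis=1) / (denom * w2)
    b = ku / qp[:, None, :]
    grad += (b * du).sum(axis=1) / (u.shape[0] * w2)
    return value, grad


def _spatial_term(x, u, config: ObjectiveConfig, want_grad: bool):
    if config.kde_mode == "marginal":
        return _spatial_value_and_grad_marginal(
            x, u, config.kernel_width(1), config.leave_one_out, want_grad
        )
    return _spatial_value_and_grad(
        x, u, config.kernel_width(x.shape[1]), config.leave_one_out, want_grad
    )


def spatial_objective(
    responses_per_hierarchy: list, config: ObjectiveConfig, seed: int
):
    """Negative-entropy estimate summed over hierarchies.

    ``responses_per_hierarchy[i]`` is an ``(n, dim)`` array of one hierarchy's
    minibatch responses at one time step (or an average is taken by the caller
    over steps).  Returns ``(value, per_hierarchy)``.
    """
    rng = np.random.default_rng(seed)
    per_h = []
    for x in responses_per_hierarchy:
        x = np.atleast_2d(np.asarray(x, dtype=float))
        u = compensation_samples(x.shape[1], config, rng)
        v, _ = _spatial_term(x, u, config, want_grad=False)
        per_h.append(v)
    return float(np.sum(per_h)), per_h


# ---------------------------------------------------------------------------
# Combined objective with backpropagation through time


def _spatial_steps(config: ObjectiveConfig, window: int) -> tuple:
    if config.spatial_time_steps is not None:
        steps = tuple(config.spatial_time_steps)
        if any(t < 1 or t > window for t in steps):
            raise ValueError("spatial_time_steps outside the window")
        return steps
    return tuple(range(2, window + 1))


def objective_and_gradients(
    params: ModelParams,
    images: np.ndarray,
    config: ObjectiveConfig,
    seed: int,
    initial: NetworkState | None = None,
    window: int = 5,
    want_grad: bool = True,
):
    """Run one clamped-image window and return ``(report, grads, final_state)``.

    ``grads`` is a :class:`ModelParams`-shaped container of gradients of
    ``l_total`` (or ``None`` when ``want_grad`` is False).  The carried-in
    initial responses are treated as constants (gradients are truncated at the
    window boundary); the image is clamped from step 0, so the first update
    already sees the presented image.
    """
    cfg = params.config
    H = cfg.depth
    images = _flatten_images(cfg, images)
    n = images.shape[0]
    if initial is None:
        initial = initial_state(cfg, n)
    # The initial state's image slot is used as-is for the first bottom-up
    # step: under state carry-over it still holds the previous window's image,
    # the literal reading of "the image presented at time t".
    traj = rollout(params, initial, images, window)
    x0_init = initial.responses[0]

    # Responses stacked over time: r[h][t] for t = 0 (initial) .. window.
    r = [None] * (H + 1)
    for h in range(1, H + 1):
        r[h] = np.concatenate(
            [initial.responses[h][None], traj.responses(h)], axis=0
        )

    l_temporal, per_h_temporal = temporal_objective(traj, images, config.temporal_reduction)

    rng = np.random.default_rng(seed)
    steps = _spatial_steps(config, window)
    u_per_h = {}
    for h in range(1, H + 1):
        u_per_h[h] = compensation_samples(cfg.dims[h], config, rng)

    # Gradient of the loss with respect to each response, accumulated per time.
    gx = [None] + [np.zeros_like(r[h]) for h in range(1, H + 1)]
    grecon = {t: None for t in _temporal_anchors(window)}

    # With lambda = 0 the entropy term is reported but cannot influence the
    # gradient, so skip its (expensive) gradient path.
    spatial_grad = want_grad and config.lambda_reg > 0
    per_h_spatial = [0.0] * (H + 1)
    for h in range(1, H + 1):
        if config.pool_time_steps:
            # One density over the whole window: repeated (static) responses
            # raise their own density, so entropy maximisation also rewards
            # exploring the response space across time -- the genuine
            # antagonist of the temporal-difference term.
            x_pool = np.concatenate([r[h][t] for t in steps], axis=0)
            v, g = _spatial_term(x_pool, u_per_h[h], config, spatial_grad)
            per_h_spatial[h] = v / len(steps)
            if spatial_grad:
                for i, t in enumerate(steps):
                    gx[h][t] += (config.lambda_reg / len(steps)) * g[i * n : (i + 1) * n]
        else:
            acc = 0.0
            for t in steps:
                v, g = _spatial_term(r[h][t], u_per_h[h], config, spatial_grad)
                acc += v
                if spatial_grad:
                    gx[h][t] += (config.lambda_reg / len(steps)) * g
            per_h_spatial[h] = acc / len(steps)
    l_spatial = float(np.sum(per_h_spatial))
    l_total = l_temporal + config.lambda_reg * l_spatial

    report = ObjectiveReport(
        l_temporal=l_temporal,
        l_spatial=l_spatial,
        l_total=l_total,
        per_hierarchy_temporal=per_h_temporal,
        per_hierarchy_spatial=per_h_spatial,
    )
    final_state = traj.states[-1]
    if not want_grad:
        return report, None, final_state

    # Temporal loss gradients with respect to states and reconstructions
    # (per-hierarchy component means, matching temporal_objective).
    for t in _temporal_anchors(window):
        for h in range(1, H + 1):
            dnorm = cfg.dims[h] if config.temporal_reduction == "mean" else 1
            d = (2.0 / dnorm) * (r[h][t] - r[h][t + 1])
            gx[h][t] += d
            gx[h][t + 1] -= d
        rnorm = cfg.dims[0] if config.temporal_reduction == "mean" else 1
        grecon[t] = (2.0 / rnorm) * (traj.states[t - 1].reconstruction - images)

    grads = params.zeros_like()
    # Backpropagation through time.  Processing times descending guarantees
    # every contribution into t-1 lands before t-1 itself is processed.
    for t in range(window, 0, -1):
        prev = [images if t > 1 else x0_init] + [r[h][t - 1] for h in range(1, H + 1)]
        for h in range(1, H + 1):
            x = r[h][t]
            delta = gx[h][t] * x * (1.0 - x)
            grads.bottom_up[h] += prev[h - 1].T @ delta
            grads.recurrent[h] += prev[h].T @ delta
            if h < H:
                grads.top_down[h] += prev[h + 1].T @ delta
            grads.bias[h] += delta.sum(axis=0)
            gx[h][t - 1] += delta @ params.recurrent[h].T
            if h < H:
                gx[h + 1][t - 1] += delta @ params.top_down[h].T
            if h > 1:
                gx[h - 1][t - 1] += delta @ params.bottom_up[h].T
        if t in grecon and grecon[t] is not None:
            recon = traj.states[t - 1].reconstruction
            dr = grecon[t] * recon * (1.0 - recon)
            grads.top_down[0] += prev[1].T @ dr
            grads.bias[0] += dr.sum(axis=0)
            gx[1][t - 1] += dr @ params.top_down[0].T
    grads.bottom_up[1][~params.input_mask] = 0.0
    return report, grads, final_state


def total_objective(
    params: ModelParams,
    images: np.ndarray,
    config: ObjectiveConfig,
    seed: int,
    initial: NetworkState | None = None,
    window: int = 5,
) -> ObjectiveReport:
    """Objective values only (no gradients) for one minibatch window."""
    report, _, _ = objective_and_gradients(
        params, images, config, seed, initial=initial, window=window, want_grad=False
    )
    return report
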