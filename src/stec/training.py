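"""Optimisation loop: Adam over windows of clamped-image temporal processing.

Each iteration samples a minibatch of images, runs one processing window of
``window_length`` steps from the carried-over network state, computes the
combined objective and its gradients by backpropagation through time, and
applies one Adam update.  The final responses of the window seed the next
window (state carry-over per minibatch slot).  Training is organised in
repetitions: at each repetition boundary the optimiser moments and step
counter are reset (warm restart) while the weights persist.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field, replace

import numpy as np

from .model import HierarchyConfig, ModelParams, init_params, initial_state
from .objectives import ObjectiveConfig, objective_and_gradients


class TrainingDivergedError(RuntimeError):
    """Raised when the objective becomes non-finite; carries the last good params."""

    def __init__(self, message: str, params: ModelParams | None = None):
        super().__init__(message)
        self.params = params


@dataclass(frozen=True)
class TrainingConfig:
    """Schedule and optimiser settings.

    Defaults follow the reference schedule: Adam with
    ``alpha=0.001, beta1=0.9, beta2=0.999, eps=1e-8``, windows of 5 steps,
    minibatches of 40 images, 10^4 iterations per repetition and 5
    repetitions.  ``lambda_reg`` optionally overrides the objective's balance
    parameter.  ``restart_mode`` selects what a repetition boundary resets:
    ``"optimizer"`` (default; weights persist, Adam state resets) or
    ``"full"`` (weights re-initialised, best repetition kept).
    """

    iterations_per_repetition: int = 10_000
    repetitions: int = 5
    window_length: int = 5
    minibatch_size: int = 40
    adam_alpha: float = 0.001
    adam_beta1: float = 0.9
    adam_beta2: float = 0.999
    adam_epsilon: float = 1e-8
    seed: int = 0
    lambda_reg: float | None = None
    restart_mode: str = "optimizer"
    reset_state_each_window: bool = False

    def __post_init__(self) -> None:
        for name in ("iterations_per_repetition", "repetitions", "window_length", "minibatch_size"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.restart_mode not in ("optimizer", "full"):
            raise ValueError("restart_mode must be 'optimizer' or 'full'")

    def snapshot(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class TrainingLog:
    """Per-iteration objective traces plus the configuration snapshot."""

    l_temporal: list = field(default_factory=list)
    l_spatial: list = field(default_factory=list)
    l_total: list = field(default_factory=list)
    repetition_boundaries: list = field(default_factory=list)
    seed: int = 0
    config_snapshot: dict = field(default_factory=dict)

    def append(self, report) -> None:
        self.l_temporal.append(report.l_temporal)
        self.l_spatial.append(report.l_spatial)
        self.l_total.append(report.l_total)

    def to_json_lines(self) -> str:
        lines = []
        for i in range(len(self.l_total)):
            lines.append(
                json.dumps(
                    {
                        "iteration": i,
                        "l_temporal": self.l_temporal[i],
                        "l_spatial": self.l_spatial[i],
                        "l_total": self.l_total[i],
                    }
                )
            )
        return "\n".join(lines)


@dataclass
class AdamState:
    """First/second moment estimates and step counter, one slot per parameter."""

    m: dict
    v: dict
    t: int = 0

    @classmethod
    def for_params(cls, params: ModelParams) -> "AdamState":
        return cls(
            m={k: np.zeros_like(a) for k, a in params.named_arrays()},
            v={k: np.zeros_like(a) for k, a in params.named_arrays()},
            t=0,
        )


def adam_update(
    params: ModelParams, grads: ModelParams, moments: AdamState, config: TrainingConfig
) -> None:
    """One in-place Adam step with bias-corrected moments.

    The structural zero-mask of the image -> hierarchy-1 matrix is re-applied
    after the step so masked connections stay exactly zero.
    """
    moments.t += 1
    b1, b2 = config.adam_beta1, config.adam_beta2
    bc1 = 1.0 - b1**moments.t
    bc2 = 1.0 - b2**moments.t
    for name, p in params.named_arrays():
        g = grads.get(name)
        if not np.all(np.isfinite(g)):
            raise TrainingDivergedError(f"non-finite gradient in {name}")
        m = moments.m[name]
        v = moments.v[name]
        m *= b1
        m += (1.0 - b1) * g
        v *= b2
        v += (1.0 - b2) * g * g
        p -= config.adam_alpha * (m / bc1) / (np.sqrt(v / bc2) + config.adam_epsilon)
    params.apply_mask()


def derived_seeds(seed: int) -> dict:
    """Sub-seeds (init / shuffle / compensation) fanned out from one training seed."""
    children = np.random.SeedSequence(seed).spawn(3)
    return {
        name: int(c.generate_state(1)[0] % 2**31)
        for name, c in zip(("init", "shuffle", "compensation"), children)
    }


class _BatchSampler:
    """Epoch-wise shuffling without replacement, spanning epochs as needed."""

    def __init__(self, n: int, rng: np.random.Generator):
        self.n = n
        self.rng = rng
        self._queue = []

    def next_batch(self, size: int) -> np.ndarray:
        while len(self._queue) < size:
            self._queue.extend(self.rng.permutation(self.n).tolist())
        batch, self._queue = self._queue[:size], self._queue[size:]
        return np.asarray(batch)


def train(
    dataset,
    model_cfg: HierarchyConfig,
    obj_cfg: ObjectiveConfig,
    train_cfg: TrainingConfig,
) -> tuple[ModelParams, TrainingLog]:
    """Train the hierarchy on a set of images.

    ``dataset`` is either a ``StimulusSet`` or an array of images
    ``(n, rows, cols)`` with values in ``[0, 1]``.  Returns the trained
    parameters and the full objective trace.  Fully deterministic under a
    fixed ``train_cfg.seed``.
    """
    images = getattr(dataset, "images", dataset)
    images = np.asarray(images, dtype=float)
    if images.ndim == 3:
        images = images.reshape(images.shape[0], -1)
    if images.shape[0] == 0:
        raise ValueError("dataset is empty")
    if train_cfg.window_length < 2 * model_cfg.depth + 1:
        raise ValueError(
            "window_length must cover a full round trip plus one step "
            f"(>= {2 * model_cfg.depth + 1})"
        )
    if train_cfg.lambda_reg is not None:
        obj_cfg = replace(obj_cfg, lambda_reg=train_cfg.lambda_reg)

    seeds = derived_seeds(train_cfg.seed)
    init_seed, shuffle_seed, comp_seed = seeds["init"], seeds["shuffle"], seeds["compensation"]
    params = init_params(model_cfg, init_seed)
    sampler = _BatchSampler(images.shape[0], np.random.default_rng(shuffle_seed))
    comp_rng = np.random.default_rng(comp_seed)

    log = TrainingLog(seed=train_cfg.seed, config_snapshot=train_cfg.snapshot())
    state = initial_state(model_cfg, train_cfg.minibatch_size)
    last_good = params.copy()
    best: tuple[float, ModelParams] | None = None

    for rep in range(train_cfg.repetitions):
        if rep > 0:
            log.repetition_boundaries.append(len(log.l_total))
            if train_cfg.restart_mode == "full":
                params = init_params(model_cfg, init_seed + rep)
                state = initial_state(model_cfg, train_cfg.minibatch_size)
        moments = AdamState.for_params(params)
        for _ in range(train_cfg.iterations_per_repetition):
            batch = images[sampler.next_batch(train_cfg.minibatch_size)]
            if train_cfg.reset_state_each_window:
                state = initial_state(model_cfg, train_cfg.minibatch_size)
            it_seed = int(comp_rng.integers(2**31))
            report, grads, state = objective_and_gradients(
                params, batch, obj_cfg, it_seed,
                initial=state, window=train_cfg.window_length,
            )
            if not np.isfinite(report.l_total):
                raise TrainingDivergedError(
                    f"objective diverged at iteration {len(log.l_total)}", params=last_good
                )
            adam_update(params, grads, moments, train_cfg)
            log.append(report)
            if len(log.l_total) % 100 == 0:
                last_good = params.copy()
        tail = np.mean(log.l_total[-min(50, len(log.l_total)):])
        if best is None or tail < best[0]:
            best = (float(tail), params.copy())

    if train_cfg.restart_mode == "full" and best is not None:
        return best[1], log
    return params, log
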