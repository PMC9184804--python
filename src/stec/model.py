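"""Bidirectional hierarchical network and its single-step inference dynamics.

The network is a stack of ``H`` hierarchies of sigmoid units above an image
layer (``h = 0``).  Every hierarchy ``h >= 1`` receives bottom-up input from
``h - 1``, recurrent input from itself and top-down input from ``h + 1``
(omitted at the top), all through dense weight matrices; the image layer is
clamped to the presented stimulus while the top-down inference into it is kept
as a separate *reconstruction* channel.

Responses live in ``(0, 1)`` (logistic sigmoid).  The lowest hierarchy is
connected to the image through a structurally sparse matrix: the image is
divided into overlapping corner-anchored patches and each patch drives its own
disjoint group of lower-hierarchy units.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit as sigmoid


class ConfigurationError(ValueError):
    """Raised for inconsistent architecture configurations."""


@dataclass(frozen=True)
class HierarchyConfig:
    """Architecture of the hierarchy.

    Parameters
    ----------
    depth:
        Number of hierarchies above the image layer (``H``).
    units:
        Units per hierarchy, ``units[h - 1]`` for hierarchy ``h``.
    image_shape:
        ``(rows, cols)`` of the input image in pixels.
    patch_shape:
        ``(rows, cols)`` of each image patch feeding hierarchy 1.
    patch_count:
        Number of patches; 4 gives the corner-anchored overlapping tiling,
        1 means the whole image is a single patch.
    """

    depth: int = 2
    units: tuple[int, ...] = (64, 64)
    image_shape: tuple[int, int] = (64, 96)
    patch_shape: tuple[int, int] = (38, 58)
    patch_count: int = 4

    def __post_init__(self) -> None:
        if self.depth < 1:
            raise ConfigurationError("depth must be >= 1")
        if len(self.units) != self.depth:
            raise ConfigurationError("units must list one count per hierarchy")
        if any(u < 1 for u in self.units):
            raise ConfigurationError("unit counts must be positive")
        if self.patch_count not in (1, 4):
            raise ConfigurationError("patch_count must be 1 or 4")
        if self.units[0] % self.patch_count:
            raise ConfigurationError(
                "lower-hierarchy units must divide evenly into patch groups"
            )
        rows, cols = self.image_shape
        pr, pc = self.patch_shape
        if self.patch_count == 1:
            if (pr, pc) != (rows, cols):
                raise ConfigurationError(
                    "with a single patch, patch_shape must equal image_shape"
                )
        else:
            # Corner-anchored patches must jointly cover the image (overlap).
            if not (pr <= rows and pc <= cols and 2 * pr >= rows and 2 * pc >= cols):
                raise ConfigurationError(
                    "patches must fit inside the image and overlap to cover it"
                )

    @property
    def n_pixels(self) -> int:
        return self.image_shape[0] * self.image_shape[1]

    @property
    def dims(self) -> tuple[int, ...]:
        """Dimension of each layer, index 0 = image."""
        return (self.n_pixels, *self.units)

    @property
    def units_per_patch(self) -> int:
        return self.units[0] // self.patch_count

    def patch_masks(self) -> np.ndarray:
        """Boolean pixel masks, one per patch, shape ``(patch_count, rows, cols)``."""
        rows, cols = self.image_shape
        pr, pc = self.patch_shape
        if self.patch_count == 1:
            return np.ones((1, rows, cols), dtype=bool)
        masks = np.zeros((4, rows, cols), dtype=bool)
        anchors = [(0, 0), (0, cols - pc), (rows - pr, 0), (rows - pr, cols - pc)]
        for p, (r0, c0) in enumerate(anchors):
            masks[p, r0 : r0 + pr, c0 : c0 + pc] = True
        return masks

    def input_mask(self) -> np.ndarray:
        """Connectivity mask of the image-to-hierarchy-1 matrix.

        ``mask[pixel, unit]`` is True iff the pixel belongs to the patch whose
        unit group contains the unit.
        """
        masks = self.patch_masks().reshape(self.patch_count, -1)
        mask = np.zeros((self.n_pixels, self.units[0]), dtype=bool)
        g = self.units_per_patch
        for p in range(self.patch_count):
            mask[masks[p], p * g : (p + 1) * g] = True
        return mask

    def to_json(self) -> str:
        return json.dumps(
            {
                "depth": self.depth,
                "units": list(self.units),
                "image_shape": list(self.image_shape),
                "patch_shape": list(self.patch_shape),
                "patch_count": self.patch_count,
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "HierarchyConfig":
        d = json.loads(text)
        return cls(
            depth=d["depth"],
            units=tuple(d["units"]),
            image_shape=tuple(d["image_shape"]),
            patch_shape=tuple(d["patch_shape"]),
            patch_count=d["patch_count"],
        )


@dataclass
class ModelParams:
    """All synaptic weight matrices and biases of the hierarchy.

    Matrices are stored source-major: a pathway matrix ``W`` of shape
    ``(dim_source, dim_dest)`` contributes ``X_source @ W`` to the
    pre-activation of the destination hierarchy.

    Indexing (with ``dims[0]`` the image layer):

    - ``top_down[h]``: from hierarchy ``h + 1`` down to ``h``; ``top_down[0]``
      is the image-reconstruction matrix.
    - ``recurrent[h]`` (``h >= 1``): within hierarchy ``h``.
    - ``bottom_up[h]`` (``h >= 1``): from ``h - 1`` up to ``h``;
      ``bottom_up[1]`` is structurally sparse (patch -> unit-group blocks).
    - ``bias[h]``: per-layer bias, including the image layer ``h = 0``.
    """

    config: HierarchyConfig
    top_down: list  # index h in 0..H-1; shape (dims[h+1], dims[h])
    recurrent: list  # index h in 0..H; [0] is None; shape (dims[h], dims[h])
    bottom_up: list  # index h in 0..H; [0] is None; shape (dims[h-1], dims[h])
    bias: list  # index h in 0..H; shape (dims[h],)
    _mask: np.ndarray = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if self._mask is None:
            self._mask = self.config.input_mask()
        self.validate()

    def validate(self) -> None:
        dims = self.config.dims
        H = self.config.depth
        for h in range(H):
            if self.top_down[h].shape != (dims[h + 1], dims[h]):
                raise ConfigurationError(f"top_down[{h}] has wrong shape")
        for h in range(1, H + 1):
            if self.recurrent[h].shape != (dims[h], dims[h]):
                raise ConfigurationError(f"recurrent[{h}] has wrong shape")
            if self.bottom_up[h].shape != (dims[h - 1], dims[h]):
                raise ConfigurationError(f"bottom_up[{h}] has wrong shape")
        for h in range(H + 1):
            if self.bias[h].shape != (dims[h],):
                raise ConfigurationError(f"bias[{h}] has wrong shape")

    @property
    def input_mask(self) -> np.ndarray:
        return self._mask

    def apply_mask(self) -> None:
        """Re-impose the structural zeros of the image -> hierarchy-1 matrix."""
        self.bottom_up[1][~self._mask] = 0.0

    def named_arrays(self):
        """Yield ``(name, array)`` for every trainable parameter, fixed order."""
        H = self.config.depth
        for h in range(H):
            yield f"top_down_{h}", self.top_down[h]
        for h in range(1, H + 1):
            yield f"recurrent_{h}", self.recurrent[h]
            yield f"bottom_up_{h}", self.bottom_up[h]
        for h in range(H + 1):
            yield f"bias_{h}", self.bias[h]

    def get(self, name: str) -> np.ndarray:
        kind, h = name.rsplit("_", 1)
        return getattr(self, kind)[int(h)]

    def set(self, name: str, value: np.ndarray) -> None:
        kind, h = name.rsplit("_", 1)
        getattr(self, kind)[int(h)] = value

    def copy(self) -> "ModelParams":
        H = self.config.depth
        return ModelParams(
            config=self.config,
            top_down=[w.copy() for w in self.top_down],
            recurrent=[None] + [self.recurrent[h].copy() for h in range(1, H + 1)],
            bottom_up=[None] + [self.bottom_up[h].copy() for h in range(1, H + 1)],
            bias=[b.copy() for b in self.bias],
            _mask=self._mask,
        )

    def zeros_like(self) -> "ModelParams":
        H = self.config.depth
        return ModelParams(
            config=self.config,
            top_down=[np.zeros_like(w) for w in self.top_down],
            recurrent=[None] + [np.zeros_like(self.recurrent[h]) for h in range(1, H + 1)],
            bottom_up=[None] + [np.zeros_like(self.bottom_up[h]) for h in range(1, H + 1)],
            bias=[np.zeros_like(b) for b in self.bias],
            _mask=self._mask,
        )

    def save(self, path) -> None:
        arrays = {name: a for name, a in self.named_arrays()}
        arrays["config_json"] = np.array(self.config.to_json())
        np.savez(path, **arrays)

    @classmethod
    def load(cls, path) -> "ModelParams":
        with np.load(path, allow_pickle=False) as data:
            config = HierarchyConfig.from_json(str(data["config_json"]))
            H = config.depth
            params = cls(
                config=config,
                top_down=[data[f"top_down_{h}"] for h in range(H)],
                recurrent=[None] + [data[f"recurrent_{h}"] for h in range(1, H + 1)],
                bottom_up=[None] + [data[f"bottom_up_{h}"] for h in range(1, H + 1)],
                bias=[data[f"bias_{h}"] for h in range(H + 1)],
            )
        return params


def init_params(config: HierarchyConfig, seed: int) -> ModelParams:
    """Initialise weights small and random, biases zero.

    Each matrix entry is uniform on ``(-1/sqrt(fan_in), 1/sqrt(fan_in))``
    where ``fan_in`` counts the nonzero inputs of the destination unit, which
    keeps initial pre-activations well inside the linear range of the sigmoid.
    The structural sparsity of the image -> hierarchy-1 matrix is imposed at
    creation.
    """
    rng = np.random.default_rng(seed)
    dims = config.dims
    H = config.depth

    def uniform(shape, fan_in):
        a = 1.0 / np.sqrt(fan_in)
        return rng.uniform(-a, a, size=shape)

    top_down = [uniform((dims[h + 1], dims[h]), dims[h + 1]) for h in range(H)]
    recurrent = [None] + [uniform((dims[h], dims[h]), dims[h]) for h in range(1, H + 1)]
    patch_pixels = config.patch_shape[0] * config.patch_shape[1]
    bottom_up = [None]
    for h in range(1, H + 1):
        fan_in = patch_pixels if h == 1 else dims[h - 1]
        bottom_up.append(uniform((dims[h - 1], dims[h]), fan_in))
    bias = [np.zeros(dims[h]) for h in range(H + 1)]
    params = ModelParams(
        config=config, top_down=top_down, recurrent=recurrent, bottom_up=bottom_up, bias=bias
    )
    params.apply_mask()
    return params


@dataclass
class NetworkState:
    """Responses of every hierarchy at one time step, plus the clamped image.

    ``responses[0]`` holds the presented image (flattened, one row per batch
    element); ``responses[h]`` for ``h >= 1`` are the unit responses, each in
    ``(0, 1)``.  ``reconstruction`` is the top-down inference into the image
    layer produced by the step that created this state (``None`` for initial
    states).
    """

    responses: list  # index h in 0..H; arrays (batch, dims[h])
    time_index: int = 0
    reconstruction: np.ndarray | None = None

    @property
    def image(self) -> np.ndarray:
        return self.responses[0]

    @property
    def batch_size(self) -> int:
        return self.responses[0].shape[0]


def _flatten_images(config: HierarchyConfig, image: np.ndarray) -> np.ndarray:
    image = np.asarray(image, dtype=float)
    if image.ndim == 2 and image.shape == config.image_shape:
        image = image.reshape(1, -1)
    elif image.ndim == 3 and image.shape[1:] == config.image_shape:
        image = image.reshape(image.shape[0], -1)
    elif image.ndim == 2 and image.shape[1] == config.n_pixels:
        pass
    elif image.ndim == 1 and image.shape[0] == config.n_pixels:
        image = image.reshape(1, -1)
    else:
        raise ValueError(f"image shape {image.shape} does not match {config.image_shape}")
    if not np.all(np.isfinite(image)):
        raise ValueError("image contains non-finite values")
    if image.min() < 0.0 or image.max() > 1.0:
        raise ValueError("image values must lie in [0, 1]")
    return image


def initial_state(
    config: HierarchyConfig, batch_size: int, image: np.ndarray | None = None, value: float = 0.5
) -> NetworkState:
    """Fresh state with all responses at ``value`` (default: sigmoid midpoint)."""
    responses = [np.zeros((batch_size, config.n_pixels))]
    if image is not None:
        responses[0] = _flatten_images(config, image)
        if responses[0].shape[0] != batch_size:
            raise ValueError("image batch does not match batch_size")
    responses += [np.full((batch_size, u), value) for u in config.units]
    return NetworkState(responses=responses, time_index=0)


def reconstruct(params: ModelParams, state: NetworkState) -> np.ndarray:
    """Top-down inference into the image layer from the current state."""
    return sigmoid(state.responses[1] @ params.top_down[0] + params.bias[0])


def step(params: ModelParams, state: NetworkState, image: np.ndarray) -> NetworkState:
    """One step of bidirectional inference with the image clamped.

    Every hierarchy ``h >= 1`` updates to
    ``sigmoid(top_down + recurrent + bottom_up + bias)`` computed from the
    *previous* state; the top-down term is omitted at the top hierarchy.  The
    returned state's image slot is the presented image; the top-down inference
    into the image layer is exposed as ``reconstruction``.
    """
    config = params.config
    H = config.depth
    image = _flatten_images(config, image)
    if image.shape[0] != state.batch_size:
        raise ValueError("image batch size does not match state")
    for h in range(1, H + 1):
        if not np.all(np.isfinite(state.responses[h])):
            raise ValueError(f"non-finite responses at hierarchy {h}")

    new_responses = [image]
    for h in range(1, H + 1):
        pre = state.responses[h - 1] @ params.bottom_up[h]
        pre += state.responses[h] @ params.recurrent[h]
        if h < H:
            pre += state.responses[h + 1] @ params.top_down[h]
        pre += params.bias[h]
        new_responses.append(sigmoid(pre))
    recon = reconstruct(params, state)
    return NetworkState(
        responses=new_responses, time_index=state.time_index + 1, reconstruction=recon
    )


@dataclass
class Trajectory:
    """A rollout: the sequence of states and the per-step reconstructions."""

    states: list  # NetworkState per step, time_index 1..steps
    initial: NetworkState

    def __len__(self) -> int:
        return len(self.states)

    def responses(self, h: int) -> np.ndarray:
        """Responses of hierarchy ``h`` stacked over time, ``(steps, batch, dim)``."""
        return np.stack([s.responses[h] for s in self.states])

    @property
    def reconstructions(self) -> np.ndarray:
        return np.stack([s.reconstruction for s in self.states])


def rollout(
    params: ModelParams, initial: NetworkState, image: np.ndarray, steps: int
) -> Trajectory:
    """Repeatedly apply :func:`step` with the image clamped."""
    if steps < 1:
        raise ValueError("steps must be >= 1")
    states = []
    state = initial
    for _ in range(steps):
        state = step(params, state, image)
        states.append(state)
    return Trajectory(states=states, initial=initial)
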