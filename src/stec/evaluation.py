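"""Analysis battery for trained hierarchies.

Covers reverse-correlation receptive fields, representation geometry (local
similarity and discriminability against a global image descriptor),
stabilisation (confusion index), neuronal noise (shifted conditional entropy),
population decoding over time, orientation preference from drifting-bar
stimuli, synaptic-strength norms, and response distributions.

Unless noted otherwise, stimuli are presented as consecutive clamped-image
episodes with state carry-over between images, matching how the network is
trained; for throughput the image sequence is split across a small number of
parallel streams, each of which is a faithful sequential presentation.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .model import ModelParams, initial_state, rollout, step
from .stimuli import BAR_ORIENTATIONS, StimulusSet, generate_bar_sequence

_TINY = 1e-300


def _image_array(images) -> np.ndarray:
    images = getattr(images, "images", images)
    return np.asarray(images, dtype=float)


def sequential_responses(
    params: ModelParams, images, steps_per_image: int, n_streams: int = 40
) -> dict:
    """Present images consecutively with state carry-over; record every step.

    Returns ``{h: array (n_images, steps_per_image, dim_h)}``.  The dataset is
    split into at most ``n_streams`` parallel streams; within a stream the
    state carries from one image to the next, and each stream starts from the
    0.5 (sigmoid midpoint) state.
    """
    cfg = params.config
    images = _image_array(images)
    n = images.shape[0]
    flat = images.reshape(n, -1)
    n_streams = min(n_streams, n)
    n_chunks = int(np.ceil(n / n_streams))
    padded = n_chunks * n_streams
    order = np.arange(padded) % n  # pad by recycling; padded outputs discarded
    idx = order.reshape(n_chunks, n_streams)

    out = {h: np.empty((padded, steps_per_image, cfg.dims[h])) for h in range(1, cfg.depth + 1)}
    state = initial_state(cfg, n_streams)
    for k in range(n_chunks):
        batch = flat[idx[k]]
        for t in range(steps_per_image):
            state = step(params, state, batch)
            for h in range(1, cfg.depth + 1):
                out[h][k * n_streams : (k + 1) * n_streams, t] = state.responses[h]
    # output position p holds image p % n, so the first n rows are exactly
    # images 0..n-1 in dataset order
    return {h: out[h][:n] for h in out}


# ---------------------------------------------------------------------------
# Receptive fields


def receptive_field(params: ModelParams, probes: StimulusSet, window: int = 5) -> dict:
    """Probe-averaged receptive-field maps.

    For each unit, the map value at a pixel is the unit's mean final-step
    response over all probes whose bright block covers that pixel.  Pixels no
    probe covers are NaN and reported in ``coverage``.
    """
    cfg = params.config
    images = _image_array(probes)
    n = images.shape[0]
    flat = images.reshape(n, -1)
    state = initial_state(cfg, n)
    traj = rollout(params, state, flat, window)
    covered = flat > 0.5
    counts = covered.sum(axis=0).astype(float)
    maps = {}
    for h in range(1, cfg.depth + 1):
        resp = traj.states[-1].responses[h]  # (n, units)
        sums = covered.T @ resp  # (pixels, units)
        with np.errstate(invalid="ignore", divide="ignore"):
            m = (sums / counts[:, None]).T  # (units, pixels)
        m[:, counts == 0] = np.nan
        maps[h] = m.reshape(cfg.units[h - 1], *cfg.image_shape)
    return {"maps": maps, "coverage": counts.reshape(cfg.image_shape)}


# ---------------------------------------------------------------------------
# Global image descriptor and representation geometry


def gist_descriptor(
    image: np.ndarray,
    orientations: int = 4,
    scales: tuple[float, ...] = (0.08, 0.2),
    grid: tuple[int, int] = (4, 4),
) -> np.ndarray:
    """Holistic scene descriptor: oriented band-pass energy pooled on a grid.

    The image is filtered in the Fourier domain with log-Gaussian radial bands
    at the given centre frequencies crossed with cosine-lobed orientation
    bands; filter-output magnitudes are mean-pooled over a coarse spatial grid
    and the concatenated vector is L2-normalised.
    """
    image = np.asarray(image, dtype=float)
    rows, cols = image.shape
    F = np.fft.fft2(image - image.mean())
    fr = np.fft.fftfreq(rows)[:, None]
    fc = np.fft.fftfreq(cols)[None, :]
    f = np.sqrt(fr**2 + fc**2)
    phi = np.arctan2(fr, fc)
    gr, gc = grid
    rb = np.linspace(0, rows, gr + 1).astype(int)
    cb = np.linspace(0, cols, gc + 1).astype(int)
    feats = []
    with np.errstate(divide="ignore"):
        logf = np.log(np.where(f > 0, f, 1.0))
    for f0 in scales:
        radial = np.exp(-((logf - np.log(f0)) ** 2) / (2 * 0.55**2))
        radial[f == 0] = 0.0
        for k in range(orientations):
            phi0 = k * np.pi / orientations
            d = np.angle(np.exp(2j * (phi - phi0))) / 2.0  # distance mod pi
            ang = np.exp(-(d**2) / (2 * (np.pi / orientations / 1.5) ** 2))
            resp = np.abs(np.fft.ifft2(F * radial * ang))
            for a in range(gr):
                for b in range(gc):
                    feats.append(resp[rb[a] : rb[a + 1], cb[b] : cb[b + 1]].mean())
    v = np.asarray(feats)
    norm = np.linalg.norm(v)
    return v / norm if norm > 0 else v


def gist_descriptors(images) -> np.ndarray:
    images = _image_array(images)
    return np.stack([gist_descriptor(img) for img in images])


def global_feature_distance(a: np.ndarray, b: np.ndarray, descriptor: str = "gist") -> float:
    """Distance between two images' global descriptors (symmetric, >= 0)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("images must have the same shape")
    if descriptor == "gist":
        return float(np.linalg.norm(gist_descriptor(a) - gist_descriptor(b)))
    if descriptor == "pixel":
        return float(np.linalg.norm(a - b))
    raise ValueError("descriptor must be 'gist' or 'pixel'")


def image_distance_matrix(images, descriptor: str = "gist") -> np.ndarray:
    if descriptor == "gist":
        d = gist_descriptors(images)
    elif descriptor == "pixel":
        d = _image_array(images).reshape(len(_image_array(images)), -1)
    else:
        raise ValueError("descriptor must be 'gist' or 'pixel'")
    return squareform(pdist(d))


def nearest_neighbour_map(images, descriptor: str = "gist") -> np.ndarray:
    """Index of each image's nearest other image under the global descriptor."""
    d = image_distance_matrix(images, descriptor)
    np.fill_diagonal(d, np.inf)
    return d.argmin(axis=1)


def local_similarity(
    images, responses: np.ndarray, neighbour_fraction: float = 0.02,
    image_distances: np.ndarray | None = None,
) -> float:
    """Mean Pearson correlation of image vs response distances to neighbours.

    For each reference, image-space distances (global descriptor) to its
    nearest ``neighbour_fraction`` of images are correlated with the Euclidean
    response-space distances to the same images; references whose distance
    vectors have zero variance are skipped with a warning.
    """
    d_s = image_distance_matrix(images) if image_distances is None else image_distances
    x = np.asarray(responses, dtype=float)
    d_x = squareform(pdist(x))
    n = d_s.shape[0]
    k = int(round(neighbour_fraction * n))
    if k < 3:
        raise ValueError("need at least 3 neighbours at the chosen fraction")
    corrs = []
    for i in range(n):
        order = np.argsort(d_s[i])
        nb = order[order != i][:k]
        a, b = d_s[i, nb], d_x[i, nb]
        if a.std() < 1e-12 or b.std() < 1e-12:
            warnings.warn(f"reference {i}: zero-variance distances, skipped")
            continue
        corrs.append(np.corrcoef(a, b)[0, 1])
    return float(np.mean(corrs))


def discriminability(
    images, responses: np.ndarray, percentile: float = 99.0,
    image_distances: np.ndarray | None = None,
) -> np.ndarray:
    """Proportion of dissimilar responses among dissimilar images, per reference.

    Dissimilar means beyond the given percentile of the reference's distance
    distribution, in image space (global descriptor) and response space
    (Euclidean) respectively.
    """
    d_s = image_distance_matrix(images) if image_distances is None else image_distances
    d_x = squareform(pdist(np.asarray(responses, dtype=float)))
    n = d_s.shape[0]
    others = ~np.eye(n, dtype=bool)
    out = []
    for i in range(n):
        ds, dx = d_s[i, others[i]], d_x[i, others[i]]
        th_s = np.percentile(ds, percentile)
        th_x = np.percentile(dx, percentile)
        den = ds > th_s
        if not den.any():
            continue
        out.append(float(np.sum(den & (dx > th_x)) / den.sum()))
    return np.asarray(out)


# ---------------------------------------------------------------------------
# Stabilisation: confusion index


def confusion_from_responses(f: np.ndarray, nearest: np.ndarray, t_ref: int) -> np.ndarray:
    """Confusion index from response trajectories.

    ``f`` is ``(n_images, steps, dim)`` with steps 1-based up to >= ``t_ref``;
    index ``[i, t-1] = ||f_t(i) - f_ref(i)|| / ||f_ref(i) - f_ref(nearest_i)||``.
    Undefined entries (zero denominator) are NaN.
    """
    f_ref = f[:, t_ref - 1]
    denom = np.linalg.norm(f_ref - f_ref[nearest], axis=1)
    num = np.linalg.norm(f - f_ref[:, None, :], axis=2)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = num / denom[:, None]
    out[denom == 0] = np.nan
    return out


def confusion_index(
    params: ModelParams, images, nearest_map: np.ndarray | None = None,
    t_max: int = 9, t_ref: int = 10, n_streams: int = 40,
) -> dict:
    """Per-(image, time, hierarchy) confusion indices and their means.

    Values below 1 mean the trajectory sits closer to its own steady response
    than to the steady response of the most confusable (nearest) image.
    """
    images_arr = _image_array(images)
    if nearest_map is None:
        nearest_map = nearest_neighbour_map(images_arr)
    resp = sequential_responses(params, images_arr, t_ref, n_streams=n_streams)
    values = {}
    mean_per_time = {}
    for h, f in resp.items():
        v = confusion_from_responses(f, nearest_map, t_ref)
        values[h] = v
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", category=RuntimeWarning)
            mean_per_time[h] = np.nanmean(v, axis=0)
    return {"values": values, "mean_per_time": mean_per_time, "t_ref": t_ref, "t_max": t_max}


# ---------------------------------------------------------------------------
# Neuronal noise: shifted conditional entropy


def block_entropy(block: np.ndarray, width: float) -> float:
    """Shifted entropy of one within-stimulus response block.

    Negative mean log leave-one-out KDE density of the block's responses
    (partition constant omitted, density clipped to the kernel-peak ceiling of
    1 from above and 1e-12 from below).
    """
    k = np.exp(-squareform(pdist(block, metric="sqeuclidean")) / (2 * width**2))
    np.fill_diagonal(k, 0.0)
    q = k.sum(axis=1) / (block.shape[0] - 1)
    q = np.clip(q, 1e-12, 1.0)
    return float(-np.mean(np.log(q)))


def neuronal_noise(
    params: ModelParams, images, presentation_steps: int = 25, block: int = 5,
    width_factor: float = 0.1, n_streams: int = 40,
) -> dict:
    """Entropy of responses within fixed-stimulus time blocks, per hierarchy.

    Each image is presented for ``presentation_steps`` steps; responses are
    grouped into consecutive blocks of ``block`` steps and the leave-one-out
    KDE entropy of each block is averaged over images.  Values are comparable
    across conditions, not absolute entropies.  Blocks whose responses are all
    identical are flagged.
    """
    if presentation_steps % block:
        raise ValueError("presentation_steps must be divisible by block")
    resp = sequential_responses(params, images, presentation_steps, n_streams=n_streams)
    n_blocks = presentation_steps // block
    H = params.config.depth
    out = np.zeros((n_blocks, H))
    degenerate = np.zeros((n_blocks, H), dtype=int)
    for h, f in resp.items():
        width = width_factor * np.sqrt(f.shape[2])
        for b in range(n_blocks):
            vals = []
            for i in range(f.shape[0]):
                blk = f[i, b * block : (b + 1) * block]
                if np.ptp(blk, axis=0).max() < 1e-12:
                    degenerate[b, h - 1] += 1
                vals.append(block_entropy(blk, width))
            out[b, h - 1] = float(np.mean(vals))
    return {
        "entropy": out,
        "block_starts": [b * block for b in range(n_blocks)],
        "degenerate_counts": degenerate,
    }


# ---------------------------------------------------------------------------
# Decoding over time


def fit_gaussian_nb(train: np.ndarray, var_floor: float = 1e-3) -> dict:
    """Fit a Gaussian naive Bayes decoder, one class per image.

    ``train`` is ``(n_classes, n_samples, dim)``.  Per-class, per-unit
    variances are floored at ``var_floor`` to avoid the zero-variance
    degeneracy of two-sample classes.
    """
    mu = train.mean(axis=1)
    var = np.maximum(train.var(axis=1), var_floor)
    return {"mu": mu, "var": var}


def nb_predict(model: dict, x: np.ndarray, block: int = 256) -> np.ndarray:
    """Maximum-likelihood class per row (ties resolved to the lowest class).

    Samples are processed in blocks to keep the (samples x classes x dim)
    intermediate bounded for large class counts.
    """
    mu, var = model["mu"], model["var"]
    const = np.log(2 * np.pi * var).sum(axis=1)  # (n_classes,)
    out = np.empty(x.shape[0], dtype=int)
    for i in range(0, x.shape[0], block):
        xb = x[i : i + block]
        maha = (((xb[:, None, :] - mu[None, :, :]) ** 2) / var[None, :, :]).sum(axis=2)
        out[i : i + block] = (-0.5 * (const[None, :] + maha)).argmax(axis=1)
    return out


def decode_over_time(
    params: ModelParams, images, train_steps: tuple[int, ...] = (10, 11),
    test_steps: tuple[int, ...] = tuple(range(1, 10)), var_floor: float = 1e-3,
    n_streams: int = 40,
) -> dict:
    """Decode stimulus identity from responses at early steps.

    Each image is its own class; the decoder (Gaussian naive Bayes over the
    concatenated responses of all hierarchies) is trained on the late,
    steady-state steps and tested at each earlier step.  Chance level is
    ``1 / n_images``.
    """
    if len(train_steps) < 2:
        raise ValueError("need at least 2 training steps per class")
    steps_needed = max(max(train_steps), max(test_steps))
    resp = sequential_responses(params, images, steps_needed, n_streams=n_streams)
    f = np.concatenate([resp[h] for h in sorted(resp)], axis=2)  # (n, steps, dim)
    n = f.shape[0]
    train = np.stack([f[:, t - 1] for t in train_steps], axis=1)
    model = fit_gaussian_nb(train, var_floor=var_floor)
    labels = np.arange(n)
    accuracy = {}
    for t in test_steps:
        pred = nb_predict(model, f[:, t - 1])
        accuracy[t] = float(np.mean(pred == labels))
    return {"accuracy": accuracy, "n_classes": n, "chance": 1.0 / n}


# ---------------------------------------------------------------------------
# Orientation preference


def orientation_preference(
    params: ModelParams, bar_width: int = 4, window: int = 5,
    orientations: tuple[float, ...] = BAR_ORIENTATIONS,
) -> dict:
    """Preferred orientation per unit from drifting-bar responses.

    For each orientation the bar frames are presented as consecutive
    ``window``-step episodes with state carry-over; a unit's response to the
    orientation is its largest step-``window`` response over all bar
    positions, and its preferred orientation is the argmax over orientations
    (ties broken toward the lowest angle and counted).
    """
    cfg = params.config
    H = cfg.depth
    per_orient = {h: [] for h in range(1, H + 1)}
    for orient in orientations:
        frames = generate_bar_sequence(orient, shape=cfg.image_shape, bar_width=bar_width)
        state = initial_state(cfg, 1)
        best = {h: np.zeros(cfg.units[h - 1]) for h in range(1, H + 1)}
        for frame in frames.images:
            flat = frame.reshape(1, -1)
            for _ in range(window):
                state = step(params, state, flat)
            for h in range(1, H + 1):
                best[h] = np.maximum(best[h], state.responses[h][0])
        for h in range(1, H + 1):
            per_orient[h].append(best[h])
    out = {}
    for h in range(1, H + 1):
        r = np.stack(per_orient[h])  # (orientations, units)
        pref = r.argmax(axis=0)
        ties = (r == r.max(axis=0)).sum(axis=0) > 1
        hist = np.bincount(pref, minlength=len(orientations))
        angles = np.asarray(orientations)[pref]
        cardinal = float(np.mean(np.isclose(angles, 0.0) | np.isclose(angles, 90.0)))
        out[h] = {
            "preferred": angles,
            "histogram": hist,
            "cardinal_fraction": cardinal,
            "tie_count": int(ties.sum()),
            "responses": r,
        }
    return out


# ---------------------------------------------------------------------------
# Synaptic strength and response distributions


def synaptic_strength(params: ModelParams) -> dict:
    """L2 norm of incoming weights per destination unit, by pathway."""
    out = {}
    for name, w in params.named_arrays():
        if name.startswith("bias"):
            continue
        norms = np.sqrt((w**2).sum(axis=0))
        out[name] = {"norms": norms, "mean": float(norms.mean())}
    return out


def weight_balance_ratio(params: ModelParams) -> float:
    """Mean top-down norm into hierarchy 1 over mean bottom-up norm from the image."""
    s = synaptic_strength(params)
    return s["top_down_1"]["mean"] / s["bottom_up_1"]["mean"]


def response_distribution(
    params: ModelParams, stimuli, steps: int = 5, bins: int = 20
) -> dict:
    """Response histograms per (time step, hierarchy) plus a middle-mass summary.

    Images are presented from the fresh midpoint state for ``steps`` steps;
    histograms over [0, 1] are normalised to proportions.  ``middle_mass`` is
    the pooled fraction of responses in [0.25, 0.75] across steps, hierarchies
    and units -- high for learned inputs under balanced training, low when
    responses pile up at the extremes.
    """
    cfg = params.config
    images = _image_array(stimuli)
    flat = images.reshape(images.shape[0], -1)
    traj = rollout(params, initial_state(cfg, flat.shape[0]), flat, steps)
    edges = np.linspace(0.0, 1.0, bins + 1)
    hists = np.zeros((steps, cfg.depth, bins))
    middle_total = 0
    count_total = 0
    per_h_middle = np.zeros(cfg.depth)
    per_h_count = np.zeros(cfg.depth)
    for t, s in enumerate(traj.states):
        for h in range(1, cfg.depth + 1):
            r = s.responses[h].ravel()
            counts, _ = np.histogram(r, bins=edges)
            hists[t, h - 1] = counts / r.size
            mid = np.sum((r >= 0.25) & (r <= 0.75))
            middle_total += mid
            count_total += r.size
            per_h_middle[h - 1] += mid
            per_h_count[h - 1] += r.size
    return {
        "histograms": hists,
        "bin_edges": edges,
        "middle_mass": float(middle_total / count_total),
        "middle_mass_per_hierarchy": (per_h_middle / per_h_count),
    }


# ---------------------------------------------------------------------------
# Aggregate report


@dataclass
class MetricsReport:
    """Evaluation outputs, JSON-serialisable."""

    results: dict = field(default_factory=dict)

    def to_json(self) -> str:
        def convert(obj):
            if isinstance(obj, np.ndarray):
                return obj.tolist()
            if isinstance(obj, (np.floating, np.integer)):
                return obj.item()
            if isinstance(obj, dict):
                return {str(k): convert(v) for k, v in obj.items()}
            if isinstance(obj, (list, tuple)):
                return [convert(v) for v in obj]
            return obj

        return json.dumps(convert(self.results), indent=2)
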