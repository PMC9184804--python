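"""Synthetic visual stimuli and readers for external image datasets.

Four stimulus families are generated programmatically, all as grayscale
images in ``[0, 1]``:

- *naturalistic*: Gaussian noise shaped in the Fourier domain to a 1/f
  amplitude spectrum, the hallmark second-order statistic of natural scenes;
- *glyph*: sparse stroke-like figures on a dark background (digit-like
  "unlearned" inputs);
- *bar*: a white bar at one of eight orientations swept across the frame
  perpendicular to its orientation;
- *probe*: binary images with a single 16x16 block of ones at a random
  position, used for reverse-correlation receptive-field mapping.

Every generator is a pure function of its parameters and seed.  Readers for
raw 16-bit IML scenes and IDX (MNIST-format) digits downsize to the model's
image shape with anti-aliasing and rescale to ``[0, 1]``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage.draw import line as draw_line
from skimage.transform import resize
from scipy.ndimage import gaussian_filter

BAR_ORIENTATIONS = tuple(np.arange(8) * 22.5)  # degrees


@dataclass
class StimulusSet:
    """A batch of [0, 1] grayscale images with provenance labels."""

    images: np.ndarray  # (n, rows, cols)
    labels: list
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.images = np.asarray(self.images, dtype=float)
        if self.images.ndim != 3:
            raise ValueError("images must be (n, rows, cols)")
        if len(self.labels) != self.images.shape[0]:
            raise ValueError("one label per image required")
        if not np.all(np.isfinite(self.images)):
            raise ValueError("images contain non-finite values")
        if self.images.size and (self.images.min() < 0 or self.images.max() > 1):
            raise ValueError("pixel values must lie in [0, 1]")

    def __len__(self) -> int:
        return self.images.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        return self.images.shape[1:]


def rescale_unit(image: np.ndarray) -> np.ndarray:
    """Min-max rescale to [0, 1]; a constant image maps to 0.5."""
    lo, hi = float(image.min()), float(image.max())
    if hi - lo < 1e-12:
        return np.full_like(image, 0.5, dtype=float)
    return (image - lo) / (hi - lo)


def _check_shape(shape) -> tuple[int, int]:
    rows, cols = shape
    if rows < 2 or cols < 2:
        raise ValueError(f"degenerate image shape {shape}")
    return rows, cols


def generate_naturalistic(
    n: int, shape: tuple[int, int] = (64, 96), seed: int = 0, exponent: float = 1.0
) -> StimulusSet:
    """Images with 1/f-like amplitude spectra, min-max rescaled per image."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rows, cols = _check_shape(shape)
    rng = np.random.default_rng(seed)
    fr = np.fft.fftfreq(rows)[:, None]
    fc = np.fft.fftfreq(cols)[None, :]
    f = np.sqrt(fr**2 + fc**2)
    f[0, 0] = 1.0  # DC handled separately
    amp = f**-exponent
    amp[0, 0] = 0.0
    images = np.empty((n, rows, cols))
    for i in range(n):
        phase = np.fft.fft2(rng.standard_normal((rows, cols)))
        img = np.real(np.fft.ifft2(phase * amp))
        images[i] = rescale_unit(img)
    return StimulusSet(
        images=images,
        labels=["naturalistic"] * n,
        metadata={"seed": seed, "shape": tuple(shape), "exponent": exponent},
    )


def generate_glyphs(
    n: int, shape: tuple[int, int] = (64, 96), seed: int = 0,
    strokes: tuple[int, int] = (3, 6), blur_sigma: float = 1.2,
) -> StimulusSet:
    """Stroke-like bright glyphs on a dark background, blurred and rescaled.

    Each glyph is a short random polyline confined to a central box, drawn at
    full intensity and softened with a Gaussian blur -- statistically sparse
    and spectrally distinct from the 1/f naturalistic set.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rows, cols = _check_shape(shape)
    rng = np.random.default_rng(seed)
    r0, r1 = int(rows * 0.15), int(rows * 0.85)
    c0, c1 = int(cols * 0.15), int(cols * 0.85)
    images = np.zeros((n, rows, cols))
    for i in range(n):
        canvas = np.zeros((rows, cols))
        n_seg = int(rng.integers(strokes[0], strokes[1] + 1))
        r = int(rng.integers(r0, r1))
        c = int(rng.integers(c0, c1))
        for _ in range(n_seg):
            r2 = int(np.clip(r + rng.integers(-rows // 3, rows // 3 + 1), r0, r1 - 1))
            c2 = int(np.clip(c + rng.integers(-cols // 3, cols // 3 + 1), c0, c1 - 1))
            rr, cc = draw_line(r, c, r2, c2)
            canvas[rr, cc] = 1.0
            # thicken by one pixel
            canvas[np.clip(rr + 1, 0, rows - 1), cc] = 1.0
            r, c = r2, c2
        canvas = gaussian_filter(canvas, blur_sigma)
        images[i] = rescale_unit(canvas)
    return StimulusSet(
        images=images,
        labels=["glyph"] * n,
        metadata={"seed": seed, "shape": tuple(shape), "blur_sigma": blur_sigma},
    )


def generate_bar_sequence(
    orientation: float,
    shape: tuple[int, int] = (64, 96),
    bar_width: int = 4,
    n_positions: int | None = None,
    seed: int = 0,
) -> StimulusSet:
    """Frames of a white bar swept perpendicular to its orientation.

    ``orientation`` must be one of the eight angles 0, 22.5, ..., 157.5
    degrees; 0 degrees is a horizontal bar moving vertically.  Frames are
    binary (bar = 1 on black), ordered along the sweep, and jointly cover the
    frame.
    """
    if not np.any(np.isclose(orientation, BAR_ORIENTATIONS)):
        raise ValueError(f"orientation must be one of {BAR_ORIENTATIONS}")
    rows, cols = _check_shape(shape)
    theta = np.deg2rad(orientation)
    ii, jj = np.meshgrid(np.arange(rows), np.arange(cols), indexing="ij")
    # Signed perpendicular coordinate of each pixel; 0 deg -> row offset.
    q = (ii - (rows - 1) / 2.0) * np.cos(theta) - (jj - (cols - 1) / 2.0) * np.sin(theta)
    qmin, qmax = q.min(), q.max()
    if n_positions is None:
        n_positions = int(np.floor((qmax - qmin) / bar_width)) + 1
        offsets = qmin + bar_width / 2.0 + bar_width * np.arange(n_positions)
    else:
        offsets = np.linspace(qmin + bar_width / 2.0, qmax - bar_width / 2.0, n_positions)
    # half-open bands [o - w/2, o + w/2) tile the sweep axis exactly, so the
    # union of frames covers every pixel with no double-covered boundary rows
    frames = np.stack(
        [((q >= o - bar_width / 2.0) & (q < o + bar_width / 2.0)).astype(float) for o in offsets]
    )
    return StimulusSet(
        images=frames,
        labels=["bar"] * len(frames),
        metadata={
            "seed": seed, "shape": tuple(shape), "orientation": float(orientation),
            "bar_width": bar_width, "offsets": offsets.tolist(),
        },
    )


def generate_rf_probes(
    n: int, shape: tuple[int, int] = (64, 96), subregion: tuple[int, int] = (16, 16),
    seed: int = 0,
) -> StimulusSet:
    """Binary probes, each with one block of ones at a uniform random position."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rows, cols = _check_shape(shape)
    sr, sc = subregion
    if sr > rows or sc > cols:
        raise ValueError("subregion larger than image")
    rng = np.random.default_rng(seed)
    r0 = rng.integers(0, rows - sr + 1, size=n)
    c0 = rng.integers(0, cols - sc + 1, size=n)
    images = np.zeros((n, rows, cols))
    for i in range(n):
        images[i, r0[i] : r0[i] + sr, c0[i] : c0[i] + sc] = 1.0
    return StimulusSet(
        images=images,
        labels=["probe"] * n,
        metadata={"seed": seed, "shape": tuple(shape), "subregion": tuple(subregion)},
    )


# ---------------------------------------------------------------------------
# External dataset readers

IML_SHAPE = (1024, 1536)  # rows, cols of a raw scene file


def _downsize(image: np.ndarray, out_shape: tuple[int, int]) -> np.ndarray:
    return resize(image, out_shape, anti_aliasing=True, preserve_range=True)


def read_iml(path, out_shape: tuple[int, int] = (64, 96)) -> np.ndarray:
    """Read one raw 16-bit little-endian grayscale scene (IML format).

    The file holds ``1024 x 1536`` unsigned 16-bit pixels, row-major.  The
    image is downsized with anti-aliasing and min-max rescaled to ``[0, 1]``
    (a constant image maps to 0.5).
    """
    raw = np.fromfile(path, dtype="<u2")
    if raw.size != IML_SHAPE[0] * IML_SHAPE[1]:
        raise ValueError(
            f"{path}: expected {IML_SHAPE[0] * IML_SHAPE[1]} pixels, got {raw.size}"
        )
    img = raw.reshape(IML_SHAPE).astype(float)
    return rescale_unit(_downsize(img, out_shape))


def write_iml(path, image: np.ndarray) -> None:
    """Write a ``1024 x 1536`` array as a raw 16-bit little-endian scene file."""
    image = np.asarray(image)
    if image.shape != IML_SHAPE:
        raise ValueError(f"image must be {IML_SHAPE}")
    image.astype("<u2").tofile(path)


IDX_IMAGES_MAGIC = 2051


def read_idx(path, out_shape: tuple[int, int] = (64, 96)) -> StimulusSet:
    """Read an IDX image file (MNIST binary format) into a stimulus set.

    Images are resized with anti-aliasing to ``out_shape`` and rescaled to
    ``[0, 1]`` per image.
    """
    with open(path, "rb") as fh:
        header = np.frombuffer(fh.read(16), dtype=">u4")
        if header.size != 4 or header[0] != IDX_IMAGES_MAGIC:
            raise ValueError(f"{path}: not an IDX image file")
        n, rows, cols = (int(x) for x in header[1:])
        data = np.frombuffer(fh.read(n * rows * cols), dtype=np.uint8)
    if data.size != n * rows * cols:
        raise ValueError(f"{path}: truncated IDX file")
    raw = data.reshape(n, rows, cols).astype(float)
    images = np.stack([rescale_unit(_downsize(img, out_shape)) for img in raw])
    return StimulusSet(
        images=images, labels=["external"] * n, metadata={"source": str(path)}
    )


def write_idx(path, images: np.ndarray) -> None:
    """Write uint8 images ``(n, rows, cols)`` in the IDX binary format."""
    images = np.asarray(images, dtype=np.uint8)
    n, rows, cols = images.shape
    with open(path, "wb") as fh:
        fh.write(np.array([IDX_IMAGES_MAGIC, n, rows, cols], dtype=">u4").tobytes())
        fh.write(images.tobytes())


def spectral_slope(image: np.ndarray) -> float:
    """Slope of radially averaged log amplitude vs log spatial frequency.

    Around -1 for 1/f-like images; used to verify the naturalistic generator
    and to separate it statistically from the glyph set.
    """
    rows, cols = image.shape
    amp = np.abs(np.fft.fft2(image - image.mean()))
    fr = np.fft.fftfreq(rows)[:, None]
    fc = np.fft.fftfreq(cols)[None, :]
    f = np.sqrt(fr**2 + fc**2).ravel()
    a = amp.ravel()
    keep = (f > 0) & (f <= 0.5)
    bins = np.logspace(np.log10(f[keep].min()), np.log10(0.5), 16)
    idx = np.digitize(f[keep], bins)
    lf, la = [], []
    for b in range(1, len(bins)):
        sel = idx == b
        if sel.sum() >= 2:
            lf.append(np.log10(np.mean(f[keep][sel])))
            la.append(np.log10(np.mean(a[keep][sel]) + 1e-12))
    coef = np.polyfit(lf, la, 1)
    return float(coef[0])
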