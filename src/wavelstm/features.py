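"""Feature-extraction stage: pluggable image-to-vector backends.

The classification pipeline consumes 4096-dimensional non-negative feature
vectors.  In production these come from the last fully connected layer of a
pretrained convolutional network used as a fixed feature extractor; here the
backend is an interface so the rest of the pipeline never depends on any
particular network or on downloaded weights.

Two backends ship:

* :class:`MockBackend` — a deterministic hashing projection of pixel
  statistics.  Each image is reduced to block-mean statistics on a fixed grid
  plus global moments, projected through a frozen random Gaussian matrix and
  rectified.  It is injective in practice on distinct images and emits vectors
  with the right shape, sign and sparsity character, which is all the
  downstream stages need for testing.
* :class:`UnavailableBackend` — a named placeholder for a real pretrained
  network adapter.  Calling it raises :class:`BackendUnavailableError` with
  instructions to use the mock or synthetic path; there is no silent
  fallback.  A real adapter must resize images to its network's input size
  (replicating the channel for grayscale input) and document that choice.

Also here: the diagnostic rendering of a feature vector as a square intensity
image, which makes the localized high-amplitude "discontinuities" that carry
class information visible as bright pixels.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

__all__ = [
    "BackendUnavailableError",
    "ExtractorBackend",
    "MockBackend",
    "UnavailableBackend",
    "get_backend",
    "extract_features",
    "feature_vector_to_image",
    "load_image_directory",
]


class BackendUnavailableError(RuntimeError):
    """A real extractor backend's weights are not available."""


class ExtractorBackend:
    """Interface: a deterministic map from one image to one feature vector."""

    name: str = "abstract"
    output_dim: int = 4096

    def extract(self, image: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


@dataclass
class MockBackend(ExtractorBackend):
    """Fixed hashing projection of pixel statistics into 4096 dimensions.

    The projection matrix is drawn once from a seeded generator at
    construction, so the same backend instance (or any instance with the same
    seed) maps the same image to the same vector.
    """

    output_dim: int = 4096
    grid: int = 16
    seed: int = 1234

    def __post_init__(self) -> None:
        self.name = f"mock-hash-{self.seed}"
        rng = np.random.default_rng(self.seed)
        n_stats = self.grid * self.grid + 5  # block means, moments, scale
        self._projection = rng.normal(size=(self.output_dim, n_stats))
        self._offset = rng.normal(size=self.output_dim) * 0.1

    def _statistics(self, image: np.ndarray) -> np.ndarray:
        img = np.asarray(image, dtype=np.float64)
        if img.ndim == 3:
            img = img.mean(axis=2)  # luminance collapse
        if img.ndim != 2:
            raise ValueError("image must be 2-D grayscale or H x W x channels")
        h, w = img.shape
        # block means on a fixed grid (nearest-sample resampling)
        rows = np.linspace(0, h - 1, self.grid).round().astype(int)
        cols = np.linspace(0, w - 1, self.grid).round().astype(int)
        blocks = img[np.ix_(rows, cols)].ravel()
        globals_ = np.array(
            [img.mean(), img.std(), img.min(), img.max()], dtype=np.float64
        )
        return np.concatenate([blocks, globals_])

    def extract(self, image: np.ndarray) -> np.ndarray:
        stats = self._statistics(image)
        # scale-normalize so 8-bit and unit-range images project comparably,
        # but keep the scale itself as a statistic so intensity still counts
        scale = max(abs(stats).max(), 1e-12)
        stats = np.concatenate([stats / scale, [np.log1p(scale)]])
        vec = self._projection @ stats + self._offset
        return np.maximum(vec, 0.0)


@dataclass
class UnavailableBackend(ExtractorBackend):
    """Placeholder for a pretrained-network adapter whose weights are absent."""

    name: str = "alexnet-fc7"
    output_dim: int = 4096

    def extract(self, image: np.ndarray) -> np.ndarray:
        raise BackendUnavailableError(
            f"backend {self.name!r} has no weights in this installation; "
            "use MockBackend or the synthetic dataset generator instead"
        )


def get_backend(name: str) -> ExtractorBackend:
    """Look up a backend by name (``mock`` or a registered real adapter)."""
    if name == "mock":
        return MockBackend()
    if name in ("alexnet", "alexnet-fc7"):
        return UnavailableBackend()
    raise ValueError(f"unknown extractor backend {name!r}")


def extract_features(
    images: list[np.ndarray] | np.ndarray, backend: ExtractorBackend
) -> np.ndarray:
    """Extract one feature vector per image; rows follow input order."""
    out = np.empty((len(images), backend.output_dim))
    for k, image in enumerate(images):
        vec = backend.extract(image)
        if vec.shape != (backend.output_dim,):
            raise ValueError(
                f"backend {backend.name!r} returned shape {vec.shape}, "
                f"expected ({backend.output_dim},)"
            )
        out[k] = vec
    return out


def feature_vector_to_image(vector: np.ndarray) -> np.ndarray:
    """Render a feature vector as a square min-max-scaled intensity grid.

    Row-major reshape: index 0 maps to the top-left pixel.  A 4096-long vector
    becomes a 64 x 64 grid; an all-equal vector maps to all zeros.
    """
    v = np.asarray(vector, dtype=np.float64).ravel()
    side = int(round(np.sqrt(v.size)))
    if side * side != v.size:
        raise ValueError(f"vector length {v.size} is not a perfect square")
    lo, hi = v.min(), v.max()
    if hi == lo:
        return np.zeros((side, side))
    return ((v - lo) / (hi - lo)).reshape(side, side)


def load_image_directory(root: str | Path) -> tuple[list[np.ndarray], np.ndarray, list[str]]:
    """Load a directory of class subdirectories of PNG/JPEG images.

    Returns ``(images, labels, class_names)`` with classes indexed in sorted
    subdirectory-name order and images in sorted filename order within each
    class.
    """
    from PIL import Image

    root = Path(root)
    class_dirs = sorted(p for p in root.iterdir() if p.is_dir())
    if not class_dirs:
        raise ValueError(f"{root}: no class subdirectories found")
    images: list[np.ndarray] = []
    labels: list[int] = []
    for ci, cdir in enumerate(class_dirs):
        files = sorted(
            f for f in cdir.iterdir()
            if f.suffix.lower() in (".png", ".jpg", ".jpeg")
        )
        for f in files:
            images.append(np.asarray(Image.open(f), dtype=np.float64))
            labels.append(ci)
    return images, np.asarray(labels, dtype=np.int64), [d.name for d in class_dirs]
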