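"""Core in-memory containers: imaging fields and label masks.

Pixel conventions used throughout the package: 2-D rasters are indexed
``[row, column]`` with a 0-based origin at the top-left; intensities are
16-bit unsigned (0..65535); label masks are non-negative integers with 0
reserved for background and object labels forming the contiguous set
``{1..K}``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import numpy as np

from .errors import InvalidParameterError, ShapeMismatchError

MAX_INTENSITY = 65535


@dataclass
class ImageField:
    """One imaging site: a set of same-shaped single-channel rasters.

    Parameters
    ----------
    channels
        Mapping from channel name (e.g. ``"dna"``, ``"lipid"``, ``"rxra"``,
        ``"pparg"``, ``"spots_SREBF1"``) to a 2-D ``uint16`` raster.
    metadata
        Free-form acquisition metadata. The pipeline relies on the keys
        ``field_id``, ``dose_nM``, ``time_h``, ``treatment`` and ``seed``.
    stacks
        Optional per-channel z-stacks (list of slices) from which the 2-D
        channels were max-projected. Only populated by the simulator's
        multi-slice mode.
    """

    channels: dict[str, np.ndarray]
    metadata: dict = field(default_factory=dict)
    stacks: dict[str, list[np.ndarray]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        shapes = {ch: arr.shape for ch, arr in self.channels.items()}
        if not shapes:
            raise InvalidParameterError("ImageField needs at least one channel")
        first = next(iter(shapes.values()))
        for ch, shp in shapes.items():
            if shp != first:
                raise ShapeMismatchError(
                    f"channel {ch!r} has shape {shp}, expected {first}"
                )

    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.channels.values())).shape

    def channel(self, name: str) -> np.ndarray:
        return self.channels[name]


@dataclass
class LabelMask:
    """Integer-labelled segmentation raster (0 = background).

    ``kind`` is one of ``nuclei``, ``cells``, ``cytoplasm``, ``droplets``.
    Labels are kept compact: exactly ``{1..n_objects}``.
    """

    labels: np.ndarray
    kind: str

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 2:
            raise InvalidParameterError("label mask must be 2-D")
        if self.labels.size and self.labels.min() < 0:
            raise InvalidParameterError("labels must be non-negative")

    @property
    def n_objects(self) -> int:
        return int(self.labels.max()) if self.labels.size else 0

    @property
    def shape(self) -> tuple[int, int]:
        return self.labels.shape


def as_float(image: np.ndarray) -> np.ndarray:
    """Return a float64 view/copy of an intensity raster."""
    return np.asarray(image, dtype=np.float64)


def check_same_shape(*arrays: np.ndarray | None) -> None:
    shapes = [a.shape for a in arrays if a is not None]
    if any(s != shapes[0] for s in shapes[1:]):
        raise ShapeMismatchError(f"shape mismatch: {shapes}")


def quantize_u16(image: np.ndarray) -> np.ndarray:
    """Clip to the 16-bit range and round to unsigned integers."""
    return np.clip(np.rint(image), 0, MAX_INTENSITY).astype(np.uint16)


def compact_labels(labels: np.ndarray, keep: np.ndarray | None = None) -> np.ndarray:
    """Relabel objects to the contiguous set {1..K}.

    Objects are ordered by their first pixel in raster-scan order, i.e.
    top-most then left-most. ``keep`` optionally restricts which original
    labels survive (boolean array indexed by label).
    """
    labels = np.asarray(labels)
    flat = labels.ravel()
    n = int(flat.max()) if flat.size else 0
    if n == 0:
        return np.zeros_like(labels, dtype=np.int32)
    # first flat index per label
    first = np.full(n + 1, flat.size, dtype=np.int64)
    nz = np.flatnonzero(flat)
    # reversed so earlier indices overwrite later ones
    first[flat[nz[::-1]]] = nz[::-1]
    present = first < flat.size
    if keep is not None:
        present &= keep
    present[0] = False
    old = np.flatnonzero(present)
    order = old[np.argsort(first[old], kind="stable")]
    mapping = np.zeros(n + 1, dtype=np.int32)
    mapping[order] = np.arange(1, len(order) + 1, dtype=np.int32)
    return mapping[labels]
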