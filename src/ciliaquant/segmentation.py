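"""Segmentation chain for one 2D channel image.

The chain reproduces the classical workflow for fluorescence morphometry:
hysteresis dual-threshold detection (pixels strictly above the high threshold
seed objects; 8-connected pixels strictly above the low threshold are
appended), size-based removal of small noise objects, and watershed splitting
of clustered objects on the Euclidean distance transform.

8-connectivity is used throughout: cilia are thin, often diagonal structures
that 4-connectivity would fragment.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi
from skimage import morphology as skmorph
from skimage.segmentation import watershed

__all__ = [
    "HysteresisParams",
    "SegmentationConfig",
    "resolve_thresholds",
    "hysteresis_segment",
    "remove_small_objects",
    "split_touching_objects",
    "segment_channel",
]

_STRUCT8 = np.ones((3, 3), dtype=bool)


@dataclass(frozen=True)
class HysteresisParams:
    """Dual thresholds, either absolute intensities or image quantiles.

    In ``quantile`` mode the thresholds are resolved per image from its
    empirical intensity distribution, which makes them independent of bit
    depth and acquisition gain. The defaults (0.90 / 0.99) assume sparse
    bright structures on a dominant background.
    """

    low: float = 0.90
    high: float = 0.99
    mode: str = "quantile"

    def __post_init__(self) -> None:
        if self.mode not in ("absolute", "quantile"):
            raise ValueError(f"mode must be 'absolute' or 'quantile'; got {self.mode!r}")
        if self.mode == "quantile":
            for q in (self.low, self.high):
                if not 0.0 <= q <= 1.0:
                    raise ValueError(f"quantile {q} outside [0, 1]")
        if self.low > self.high:
            raise ValueError(f"low ({self.low}) > high ({self.high})")


@dataclass(frozen=True)
class SegmentationConfig:
    """Parameters of the full chain for one channel.

    ``min_object_area_px`` plays the role of the user-selected minimum size
    below which segmented objects are discarded as noise; the default of 5 px
    suits thin cilia at ~0.1 µm/pixel. ``split_min_distance_px`` is the
    minimum separation between watershed seeds: marker regions closer than
    this are merged, suppressing spurious splits. Connectivity is fixed at
    8 neighbours.
    """

    hysteresis: HysteresisParams = field(default_factory=HysteresisParams)
    min_object_area_px: int = 5
    split_min_distance_px: int = 5

    def __post_init__(self) -> None:
        if self.min_object_area_px < 1:
            raise ValueError("min_object_area_px must be >= 1")
        if self.split_min_distance_px < 1:
            raise ValueError("split_min_distance_px must be >= 1")

    @classmethod
    def for_cilia(cls) -> "SegmentationConfig":
        # cilia cover well under 1% of a field, so the thresholds must sit in
        # the far tail of the intensity distribution to clear the noise floor
        return cls(
            hysteresis=HysteresisParams(0.99, 0.999, "quantile"),
            min_object_area_px=5,
            split_min_distance_px=5,
        )

    @classmethod
    def for_nuclei(cls) -> "SegmentationConfig":
        return cls(
            hysteresis=HysteresisParams(0.80, 0.99, "quantile"),
            min_object_area_px=50,
            split_min_distance_px=10,
        )


def resolve_thresholds(
    image: np.ndarray, params: HysteresisParams
) -> tuple[float, float]:
    """Resolve hysteresis parameters to absolute intensity thresholds.

    Absolute mode passes the stated values through; quantile mode returns the
    empirical quantiles of the flattened image. ``low <= high`` is guaranteed
    (quantiles are monotone in the probability).
    """
    image = np.asarray(image)
    if image.size == 0:
        raise ValueError("empty image")
    if params.mode == "absolute":
        low, high = float(params.low), float(params.high)
    else:
        low = float(np.quantile(image, params.low))
        high = float(np.quantile(image, params.high))
    if low > high:
        raise ValueError(f"resolved low ({low}) > high ({high})")
    return low, high


def hysteresis_segment(image: np.ndarray, low: float, high: float) -> np.ndarray:
    """Dual-threshold segmentation.

    Foreground is every pixel strictly above ``low`` that is 8-connected,
    through pixels strictly above ``low``, to at least one pixel strictly
    above ``high``. Pixels at or below ``low`` are never foreground, and
    isolated mid-range pixels without a seed connection are excluded.
    With ``low == high`` this degenerates to a simple strict threshold.

    Returns a boolean mask of the image's shape.
    """
    if low > high:
        raise ValueError(f"low ({low}) > high ({high})")
    image = np.asarray(image)
    mask_low = image > low
    mask_high = image > high
    if not mask_high.any():
        return np.zeros(image.shape, dtype=bool)
    labels, _ = ndi.label(mask_low, structure=_STRUCT8)
    seeded = np.unique(labels[mask_high])
    seeded = seeded[seeded > 0]
    return np.isin(labels, seeded)


def remove_small_objects(mask: np.ndarray, min_area_px: int) -> np.ndarray:
    """Drop 8-connected components with fewer than ``min_area_px`` pixels."""
    if min_area_px < 1:
        raise ValueError("min_area_px must be >= 1")
    mask = np.asarray(mask, dtype=bool)
    # components of exactly min_area_px survive: drop only size <= min_area_px - 1
    return skmorph.remove_small_objects(mask, max_size=min_area_px - 1, connectivity=2)


def _merge_close_markers(
    markers: np.ndarray, components: np.ndarray, min_distance_px: int
) -> np.ndarray:
    """Union marker regions of one mask component closer than min_distance_px."""
    n = int(markers.max())
    if n <= 1:
        return markers
    centroids = np.array(ndi.center_of_mass(markers > 0, markers, range(1, n + 1)))
    # component each marker sits in (markers never straddle components)
    comp_of = ndi.labeled_comprehension(
        components, markers, range(1, n + 1), lambda v: v[0], int, 0
    )
    parent = list(range(n))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            if comp_of[i] != comp_of[j]:
                continue
            if np.hypot(*(centroids[i] - centroids[j])) < min_distance_px:
                parent[find(i)] = find(j)
    mapping = np.zeros(n + 1, dtype=markers.dtype)
    roots: dict[int, int] = {}
    for i in range(n):
        r = find(i)
        mapping[i + 1] = roots.setdefault(r, len(roots) + 1)
    return mapping[markers]


def split_touching_objects(mask: np.ndarray, min_distance_px: int) -> np.ndarray:
    """Split clustered objects by watershed on the distance transform.

    Seeds are the h-maxima regions (h = 1 px) of the Euclidean distance
    transform — a thin object whose distance ridge is one flat plateau keeps
    a single seed, while two fused convex objects each contribute one.
    Seed regions closer than ``min_distance_px`` (centroid distance) are
    merged before flooding the negated distance map, restricted to the mask.

    Returns a label map with consecutive labels 1..N (raster order of first
    appearance); labels partition the foreground exactly. N is at least the
    number of 8-connected components of the mask.
    """
    if min_distance_px < 1:
        raise ValueError("min_distance_px must be >= 1")
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        return np.zeros(mask.shape, dtype=np.int32)
    dist = ndi.distance_transform_edt(mask)
    # h-maxima seeds: maxima separated by dips shallower than 1 px merge into
    # one plateau of the reconstruction, so a thin object's flat distance
    # ridge yields a single seed while two fused convex objects yield two.
    # The +1 offset inside the mask keeps 1-px-wide objects above the
    # background plateau so they too retain a regional maximum.
    dmark = np.where(mask, dist + 1.0, 0.0)
    rec = skmorph.reconstruction(dmark - 1.0, dmark, method="dilation")
    hmax = skmorph.local_maxima(rec, connectivity=2) & mask
    markers, n_markers = ndi.label(hmax, structure=_STRUCT8)
    components, _ = ndi.label(mask, structure=_STRUCT8)
    if n_markers == 0:  # degenerate flat distance map
        markers = components
    else:
        markers = _merge_close_markers(markers, components, min_distance_px)
    labels = watershed(-dist, markers=markers, mask=mask, connectivity=2)
    return _relabel_raster(labels)


def _relabel_raster(labels: np.ndarray) -> np.ndarray:
    """Renumber labels consecutively 1..N in raster order of first pixel."""
    flat = labels.ravel()
    uniq, first_idx = np.unique(flat, return_index=True)
    nz = uniq > 0
    uniq, first_idx = uniq[nz], first_idx[nz]
    if uniq.size == 0:
        return labels.astype(np.int32)
    mapping = np.zeros(int(labels.max()) + 1, dtype=np.int32)
    mapping[uniq[np.argsort(first_idx)]] = np.arange(1, uniq.size + 1)
    return mapping[labels]


def segment_channel(image: np.ndarray, config: SegmentationConfig) -> np.ndarray:
    """Full chain: thresholds → hysteresis → size filter → watershed split.

    Deterministic for fixed inputs. Returns the label map (0 = background).
    """
    low, high = resolve_thresholds(image, config.hysteresis)
    mask = hysteresis_segment(image, low, high)
    mask = remove_small_objects(mask, config.min_object_area_px)
    return split_touching_objects(mask, config.split_min_distance_px)
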