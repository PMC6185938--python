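"""Per-object and per-field morphometry.

For every segmented object the module extracts the region properties the
assay reports — pixel area, mean intensity over the original image, centroid —
plus two length estimates in µm: the longest geodesic path along the
1-pixel skeleton (the default "length" of a curved cilium, counting 1 per
axial step and √2 per diagonal step) and the ellipse-equivalent major-axis
length as an alternative. Field-level summaries hold the cilia count, the
nuclei count, the mean cilium length of the image, and the ciliation
incidence, defined as cilia count / nuclei count × 100%.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import dijkstra
from skimage.measure import regionprops
from skimage.morphology import skeletonize

__all__ = [
    "CiliumMeasurement",
    "FieldSummary",
    "skeleton_length",
    "measure_objects",
    "compute_incidence",
    "summarize_field",
]

_STRUCT8 = np.ones((3, 3), dtype=bool)

#: QC flag raised when incidence cannot be computed (no nuclei detected).
FLAG_NO_NUCLEI = "no_nuclei_detected"
#: QC flag raised when incidence exceeds 100% (multiciliation or oversegmentation).
FLAG_INCIDENCE_GT_100 = "multiciliation_or_oversegmentation"


@dataclass(frozen=True)
class CiliumMeasurement:
    """Measurements of one segmented cilium."""

    label: int
    area_px: int
    area_um2: float
    length_um: float
    major_axis_um: float
    mean_intensity: float
    centroid: tuple[float, float]  # (y, x), pixels


@dataclass(frozen=True)
class FieldSummary:
    """Per-image cilia metrics.

    ``mean_length_um`` is NaN when no cilia were detected; ``incidence_pct``
    is NaN (with a QC flag) when no nuclei were detected. Incidence above
    100% is reported as-is and flagged, not clamped — in this assay it
    signals oversegmentation rather than genuine multiciliation.
    """

    image_id: str
    n_cilia: int
    n_nuclei: int
    mean_length_um: float
    incidence_pct: float
    qc_flags: tuple[str, ...] = ()


def skeleton_length(object_mask: np.ndarray, pixel_size_um: float) -> float:
    """Longest geodesic path length along the object's skeleton, in µm.

    The object is thinned to a 1-pixel-wide skeleton; steps between
    8-neighbouring skeleton pixels count 1 (axial) or √2 (diagonal) pixel
    units. The returned value is the largest pairwise geodesic distance,
    found by shortest-path search from every skeleton endpoint (exact for
    tree-shaped skeletons, which thinning produces for simple elongated
    objects). A single-pixel skeleton has length 0.

    Raises on an empty mask or one with multiple 8-connected components.
    """
    mask = np.asarray(object_mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty object mask")
    _, n_comp = ndi.label(mask, structure=_STRUCT8)
    if n_comp != 1:
        raise ValueError(f"object mask has {n_comp} components; expected 1")
    skel = skeletonize(mask)
    coords = np.argwhere(skel)
    n = coords.shape[0]
    if n <= 1:
        return 0.0

    index = -np.ones(skel.shape, dtype=np.int64)
    index[tuple(coords.T)] = np.arange(n)
    rows, cols, weights = [], [], []
    # enumerate half the neighbourhood; symmetry supplies the rest
    for dy, dx, w in ((0, 1, 1.0), (1, 0, 1.0), (1, 1, math.sqrt(2)), (1, -1, math.sqrt(2))):
        ys, xs = coords[:, 0] + dy, coords[:, 1] + dx
        ok = (ys >= 0) & (ys < skel.shape[0]) & (xs >= 0) & (xs < skel.shape[1])
        ok[ok] &= skel[ys[ok], xs[ok]]
        src = np.arange(n)[ok]
        dst = index[ys[ok], xs[ok]]
        rows.extend(src)
        cols.extend(dst)
        weights.extend([w] * src.size)
    graph = coo_matrix((weights, (rows, cols)), shape=(n, n))
    graph = graph + graph.T

    degree = np.asarray((graph > 0).sum(axis=1)).ravel()
    sources = np.flatnonzero(degree <= 1)
    if sources.size == 0:  # cyclic skeleton: double-sweep approximation
        d0 = dijkstra(graph, indices=0)
        sources = np.array([int(np.argmax(np.where(np.isfinite(d0), d0, -1)))])
    dist = dijkstra(graph, indices=sources)
    dist = np.where(np.isfinite(dist), dist, 0.0)
    return float(dist.max()) * pixel_size_um


def measure_objects(
    labels: np.ndarray, intensity: np.ndarray, pixel_size_um: float
) -> list[CiliumMeasurement]:
    """Region properties for every label: area, intensity, centroid, lengths.

    ``mean_intensity`` is computed on the original (pre-threshold) intensity
    image. An empty label map yields an empty list.
    """
    labels = np.asarray(labels)
    intensity = np.asarray(intensity)
    if labels.shape != intensity.shape:
        raise ValueError(
            f"shape mismatch: labels {labels.shape} vs intensity {intensity.shape}"
        )
    out: list[CiliumMeasurement] = []
    for rp in regionprops(labels, intensity_image=intensity):
        comp, n_comp = ndi.label(rp.image, structure=_STRUCT8)
        if n_comp == 1:
            length = skeleton_length(rp.image, pixel_size_um)
        else:  # pathological split label: report the longest piece
            length = max(
                skeleton_length(comp == i, pixel_size_um) for i in range(1, n_comp + 1)
            )
        out.append(
            CiliumMeasurement(
                label=int(rp.label),
                area_px=int(rp.area),
                area_um2=float(rp.area) * pixel_size_um**2,
                length_um=length,
                major_axis_um=float(rp.axis_major_length) * pixel_size_um,
                mean_intensity=float(rp.intensity_mean),
                centroid=(float(rp.centroid[0]), float(rp.centroid[1])),
            )
        )
    return out


def compute_incidence(n_cilia: int, n_nuclei: int) -> float:
    """Ciliation incidence: cilia count / nuclei count × 100 (percent).

    Returns NaN when ``n_nuclei`` is 0 (the caller attaches a QC flag).
    """
    if n_cilia < 0 or n_nuclei < 0:
        raise ValueError("counts must be non-negative")
    if n_nuclei == 0:
        return float("nan")
    return n_cilia / n_nuclei * 100.0


def summarize_field(
    measurements: list[CiliumMeasurement],
    n_nuclei: int,
    image_id: str,
    extra_flags: tuple[str, ...] = (),
) -> FieldSummary:
    """Fold per-cilium measurements into the per-image summary.

    The reported cilia length is the mean over all cilia in the image (NaN
    when none); incidence follows :func:`compute_incidence`.
    """
    n_cilia = len(measurements)
    mean_len = (
        float(np.mean([m.length_um for m in measurements])) if n_cilia else float("nan")
    )
    incidence = compute_incidence(n_cilia, n_nuclei)
    flags = list(extra_flags)
    if n_nuclei == 0:
        flags.append(FLAG_NO_NUCLEI)
    elif incidence > 100.0:
        flags.append(FLAG_INCIDENCE_GT_100)
    return FieldSummary(
        image_id=image_id,
        n_cilia=n_cilia,
        n_nuclei=n_nuclei,
        mean_length_um=mean_len,
        incidence_pct=incidence,
        qc_flags=tuple(flags),
    )
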