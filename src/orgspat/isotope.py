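"""Conditioning and summarising of scaled 13C/12C isotope-ratio images.

Ratio images arrive registered to the segmentation grid, as dimensionless
scaled ratios whose natural-abundance (terrestrial) background is 102.
Conditioning is a 17x17 mean filter (matching the ~80 nm lateral resolution
of the ion image against the 5 nm SEM grid) plus a floor at the background:
values below 102 are measurement noise and are reset to 102.  Enrichment is
then an arithmetic mean of the conditioned pixels over a region — a pixel
set, a labeled object, a class, or the whole cell.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from orgspat.defaults import (
    BACKGROUND_RATIO,
    DEFAULT_PIXEL_SIZE_NM,
    RATIO_MEAN_FILTER_PX,
)
from orgspat.preprocess import LabeledObjects, MaskStack


@dataclass
class RatioImage:
    """Per-pixel scaled 13C/12C values on the segmentation grid.

    ``flags`` records the conditioning applied so far (``smoothed``,
    ``floored``); an empty set means a raw image.
    """

    values: np.ndarray
    pixel_size_nm: float = DEFAULT_PIXEL_SIZE_NM
    background: float = BACKGROUND_RATIO
    flags: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ValueError("ratio image must be 2-D")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


def smooth_ratio(img: RatioImage, size: int = RATIO_MEAN_FILTER_PX) -> RatioImage:
    """Replace each pixel by the mean of its ``size`` x ``size`` window.

    Edges are handled by nearest-value replication, so a constant image is a
    fixed point and border regions are not darkened toward zero.
    """
    if size > min(img.shape):
        raise ValueError(f"mean-filter size {size} exceeds image shape {img.shape}")
    out = ndimage.uniform_filter(img.values, size=size, mode="nearest")
    return RatioImage(
        out, img.pixel_size_nm, img.background, img.flags | {"smoothed"}
    )


def floor_background(img: RatioImage) -> RatioImage:
    """Reset sub-background pixels to the terrestrial background value."""
    out = np.maximum(img.values, img.background)
    return RatioImage(
        out, img.pixel_size_nm, img.background, img.flags | {"floored"}
    )


def condition_ratio(img: RatioImage, order: str = "floor-smooth") -> RatioImage:
    """Apply floor and mean filter in the configured order.

    ``order`` is ``"floor-smooth"`` (default) or ``"smooth-floor"``; with a
    floor that only touches rare sub-background pixels the two nearly
    commute.
    """
    if order == "floor-smooth":
        return smooth_ratio(floor_background(img))
    if order == "smooth-floor":
        return floor_background(smooth_ratio(img))
    raise ValueError(f"unknown conditioning order {order!r}")


def mean_ratio(region: np.ndarray, img: RatioImage) -> float:
    """Arithmetic mean of the ratio pixels inside a boolean region mask."""
    region = np.asarray(region, dtype=bool)
    if region.shape != img.shape:
        raise ValueError("region mask and ratio image shapes differ")
    n = int(region.sum())
    if n == 0:
        raise ValueError("empty region")
    return float(img.values[region].mean())


def enrichment_summary(
    objects: LabeledObjects, stack: MaskStack, img: RatioImage
) -> pd.DataFrame:
    """Per-object, per-class (pixel-weighted) and per-cell enrichment table.

    Returns rows of (scope, id, class, n_pixels, mean_ratio, sd_ratio) where
    scope is ``object``, ``class`` or ``cell``.  Class means are
    pixel-weighted means over member objects, i.e. plain means over the
    pooled class pixels; the cell row pools every pixel inside the cell mask.
    """
    if stack.shape != img.shape or objects.labels.shape != img.shape:
        raise ValueError("masks, labels and ratio image are not registered")
    rows = []
    vals = img.values
    labs = objects.labels
    for oid in objects.ids:
        pix = vals[labs == oid]
        rows.append(
            {
                "scope": "object",
                "id": oid,
                "class": objects.classes[oid],
                "n_pixels": pix.size,
                "mean_ratio": float(pix.mean()),
                "sd_ratio": float(pix.std(ddof=0)),
            }
        )
    for cls in sorted(set(objects.classes.values())):
        ids = [i for i, c in objects.classes.items() if c == cls]
        pix = vals[np.isin(labs, ids)]
        if pix.size == 0:
            continue
        rows.append(
            {
                "scope": "class",
                "id": None,
                "class": cls,
                "n_pixels": pix.size,
                "mean_ratio": float(pix.mean()),
                "sd_ratio": float(pix.std(ddof=0)),
            }
        )
    cell_pix = vals[stack.masks["cell"]]
    if cell_pix.size:
        rows.append(
            {
                "scope": "cell",
                "id": None,
                "class": "cell",
                "n_pixels": cell_pix.size,
                "mean_ratio": float(cell_pix.mean()),
                "sd_ratio": float(cell_pix.std(ddof=0)),
            }
        )
    return pd.DataFrame(rows)


def bin_enrichment(img: RatioImage, edges) -> np.ndarray:
    """Categorise ratio pixels into half-open enrichment bins.

    ``edges`` are strictly ascending thresholds starting at or above the
    terrestrial background.  A pixel with value v falls in category i when
    ``edges[i-1] <= v < edges[i]``; values below ``edges[0]`` map to
    category 0, and the last edge closes the top bin (values at or above it
    stay in category ``len(edges) - 1``).  A single edge therefore yields a
    binary above/below map.
    """
    edges = np.asarray(edges, dtype=float)
    if edges.ndim != 1 or edges.size == 0:
        raise ValueError("edges must be a non-empty 1-D sequence")
    if np.any(np.diff(edges) <= 0):
        raise ValueError("edges must be strictly ascending")
    if edges[0] < BACKGROUND_RATIO:
        raise ValueError(f"first edge must be >= {BACKGROUND_RATIO}")
    cats = np.digitize(img.values, edges, right=False)
    return np.minimum(cats, max(1, len(edges) - 1))
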