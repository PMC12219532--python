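"""Per-object geometry: perimeter pixel counts, circularity, centroids,
cell composition and the ranked-volume exponential fit.

Perimeter here is a pixel COUNT, not a polygonal length: an object pixel is
a perimeter pixel when at least one of its 8 neighbours lies outside the
object (pixels beyond the image border count as outside).  Circularity uses
the shape score

    score = 4*pi*A / P**2 * (1 - 0.5*r)**2,   r = P/(2*pi) + 0.5,

with A the pixel area and P the perimeter pixel count.  The (1 - 0.5 r)^2
factor is a perimeter-dependent correction applied verbatim; it is not
renormalised, so scores can exceed 1 for coarse perimeters.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import ndimage

from orgspat.preprocess import LabeledObjects, MaskStack

_SQUARE_3x3 = np.ones((3, 3), dtype=bool)


def perimeter_mask(mask: np.ndarray) -> np.ndarray:
    """Boolean mask of object pixels with >= 1 of 8 neighbours outside."""
    mask = np.asarray(mask, dtype=bool)
    interior = ndimage.binary_erosion(mask, structure=_SQUARE_3x3, border_value=0)
    return mask & ~interior


def perimeter_pixels(mask: np.ndarray) -> int:
    """Number of perimeter pixels of a (single) object mask."""
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty object has no perimeter")
    return int(perimeter_mask(mask).sum())


def circularity(area_px: float, perimeter_px: float) -> float:
    """Circularity score from pixel area A and perimeter pixel count P."""
    if area_px < 1:
        raise ValueError("area must be >= 1 pixel")
    if perimeter_px <= 0:
        raise ValueError("perimeter must be positive")
    r = perimeter_px / (2.0 * np.pi) + 0.5
    return float(4.0 * np.pi * area_px / perimeter_px**2 * (1.0 - 0.5 * r) ** 2)


def centroid(mask: np.ndarray, pixel_size_nm: float) -> tuple[float, float]:
    """Unweighted centroid of pixel centers, as (x_nm, y_nm).

    x is the column coordinate, y the row coordinate (y grows downward).
    """
    coords = np.argwhere(np.asarray(mask, dtype=bool))
    if coords.size == 0:
        raise ValueError("empty object has no centroid")
    y_px, x_px = coords.mean(axis=0)
    return float(x_px * pixel_size_nm), float(y_px * pixel_size_nm)


def object_table(objects: LabeledObjects) -> pd.DataFrame:
    """Morphometry table: one row per object.

    Columns: id, class, area_px, perimeter_px, circularity,
    centroid_x_nm, centroid_y_nm.
    """
    rows = []
    for oid in objects.ids:
        m = objects.labels == oid
        a = int(m.sum())
        p = perimeter_pixels(m)
        cx, cy = centroid(m, objects.pixel_size_nm)
        rows.append(
            {
                "id": oid,
                "class": objects.classes[oid],
                "area_px": a,
                "perimeter_px": p,
                "circularity": circularity(a, p),
                "centroid_x_nm": cx,
                "centroid_y_nm": cy,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "id",
            "class",
            "area_px",
            "perimeter_px",
            "circularity",
            "centroid_x_nm",
            "centroid_y_nm",
        ],
    )


def composition(stack: MaskStack) -> pd.DataFrame:
    """Fraction of the cell area occupied by each organelle class."""
    cell_area = int(stack.masks["cell"].sum())
    if cell_area == 0:
        raise ValueError("empty cell mask")
    rows = []
    for cls in stack.organelle_classes:
        area = int(stack.masks[cls].sum())
        rows.append({"class": cls, "area_px": area, "fraction": area / cell_area})
    return pd.DataFrame(rows, columns=["class", "area_px", "fraction"])


def ranked_volume_fit(volumes, space: str = "log") -> tuple[float, float, float]:
    """Fit v_k = a * exp(b * k) to volumes ranked ascending (k = 1..n).

    Returns (amplitude a, rate b, r_squared).  The default fit linearises by
    least squares on log(v_k), with r^2 reported on the log scale;
    ``space="linear"`` instead refits in linear space by nonlinear least
    squares seeded from the log fit and reports linear-space r^2.  Inputs
    must be positive; a degenerate all-equal input returns b = 0 and
    r^2 defined as 0.
    """
    v = np.sort(np.asarray(volumes, dtype=float))
    if v.size < 3:
        raise ValueError("need at least 3 volumes")
    if np.any(v <= 0):
        raise ValueError("volumes must be positive")
    k = np.arange(1, v.size + 1, dtype=float)
    logv = np.log(v)
    if np.ptp(logv) == 0:  # all volumes equal: flat fit, r^2 defined as 0
        return float(v[0]), 0.0, 0.0
    b, loga = np.polyfit(k, logv, 1)
    a = float(np.exp(loga))
    b = float(b)
    if space == "log":
        resid = logv - (loga + b * k)
        ss_tot = float(((logv - logv.mean()) ** 2).sum())
        r2 = 0.0 if ss_tot == 0 else 1.0 - float((resid**2).sum()) / ss_tot
        return a, b, r2
    if space == "linear":
        from scipy.optimize import curve_fit

        popt, _ = curve_fit(
            lambda x, aa, bb: aa * np.exp(bb * x), k, v, p0=(a, b), maxfev=10000
        )
        a, b = float(popt[0]), float(popt[1])
        resid = v - a * np.exp(b * k)
        ss_tot = float(((v - v.mean()) ** 2).sum())
        r2 = 0.0 if ss_tot == 0 else 1.0 - float((resid**2).sum()) / ss_tot
        return a, b, r2
    raise ValueError(f"unknown fit space {space!r}")
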