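"""Organelle-organelle contact sites from disjoint labeled masks.

A contact site is a group of mutually proximal perimeter pixels of two
distinct objects.  The search is a raster scan: for every perimeter pixel of
every object, a (2m+1) x (2m+1) region of interest centred on it is
examined, and perimeter pixels of OTHER objects whose centre-to-centre
Euclidean distance is at most m pixels (default m = 2, i.e. 10 nm at
5 nm/px) are recorded as contacting pixels.  Contacting pixels of one object
pair are grouped into discrete sites (8-adjacency within each object's
pixels, plus the cross-object proximity links), and sites in which either
object contributes only a single contacting pixel are discarded as
segmentation noise.

`find_contacts_bruteforce` recomputes the same quantity from the definition
— all-pairs distances between the two objects' perimeter pixel sets — with
independent grouping code, and exists to validate the raster scan.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from orgspat.defaults import (
    CLASS_SHORT_NAMES,
    DEFAULT_CONTACT_RADIUS_PX,
    DEFAULT_PIXEL_SIZE_NM,
    PARTNER_TIEBREAK_ORDER,
)
from orgspat.preprocess import LabeledObjects

_NEIGHBOURS_8 = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]


@dataclass(frozen=True)
class DistanceSpec:
    """Contact search radius: ``m`` pixels, ``m * pixel_size_nm`` nm."""

    m: int = DEFAULT_CONTACT_RADIUS_PX
    pixel_size_nm: float = DEFAULT_PIXEL_SIZE_NM

    def __post_init__(self) -> None:
        if self.m < 1:
            raise ValueError("search threshold m must be >= 1 pixel")

    @property
    def window_nm(self) -> float:
        return self.m * self.pixel_size_nm


@dataclass
class ContactSite:
    """One discrete contact between objects ``id_a`` and ``id_b``.

    ``pixels_a`` / ``pixels_b`` are the contacting perimeter pixels on each
    side as frozensets of (row, col); ``size`` counts both sides.
    """

    site_id: int
    id_a: int
    id_b: int
    class_a: str
    class_b: str
    pixels_a: frozenset
    pixels_b: frozenset
    min_dist_px: float

    @property
    def size(self) -> int:
        return len(self.pixels_a) + len(self.pixels_b)

    def pixels_of(self, object_id: int) -> frozenset:
        if object_id == self.id_a:
            return self.pixels_a
        if object_id == self.id_b:
            return self.pixels_b
        raise KeyError(f"object {object_id} not part of this site")


def euclidean_distance(p, q) -> float:
    """Euclidean distance between two points of equal dimensionality."""
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    if p.shape != q.shape:
        raise ValueError("points must have the same dimensionality")
    return float(np.sqrt(((q - p) ** 2).sum()))


def _window_offsets(m: int) -> list[tuple[int, int]]:
    """Offsets inside the (2m+1)^2 ROI within Euclidean distance m (excl. 0)."""
    offs = []
    for dy in range(-m, m + 1):
        for dx in range(-m, m + 1):
            if (dy or dx) and dy * dy + dx * dx <= m * m:
                offs.append((dy, dx))
    return offs


def _perimeter_raster(labels: np.ndarray) -> np.ndarray:
    """Pixels whose 8-neighbourhood leaves their own object.

    A pixel of object L is a perimeter pixel when at least one 8-neighbour
    (or the image border) does not belong to L; neighbouring pixels of other
    objects count as outside.
    """
    h, w = labels.shape
    perim = np.zeros((h, w), dtype=bool)
    fg = labels > 0
    for dy, dx in _NEIGHBOURS_8:
        shifted = np.zeros_like(labels)
        ys = slice(max(dy, 0), h + min(dy, 0))
        xs = slice(max(dx, 0), w + min(dx, 0))
        yt = slice(max(-dy, 0), h + min(-dy, 0))
        xt = slice(max(-dx, 0), w + min(-dx, 0))
        shifted[yt, xt] = labels[ys, xs]
        perim |= fg & (shifted != labels)
    # border pixels always face the outside
    perim[0, :] |= fg[0, :]
    perim[-1, :] |= fg[-1, :]
    perim[:, 0] |= fg[:, 0]
    perim[:, -1] |= fg[:, -1]
    return perim


class _UnionFind:
    def __init__(self):
        self.parent = {}

    def find(self, x):
        p = self.parent.setdefault(x, x)
        while p != x:
            self.parent[x] = p = self.parent[p]
            x = p
            p = self.parent[x]
        return x

    def union(self, a, b):
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[rb] = ra


def _sites_from_pairs(
    objects: LabeledObjects, pair_rows: np.ndarray, spec: DistanceSpec
) -> list[ContactSite]:
    """Group directed contacting-pixel pairs into filtered ContactSites.

    ``pair_rows`` columns: py, px, qy, qx, label_p, label_q, squared dist.
    """
    if len(pair_rows) == 0:
        return []
    # canonical unordered pair key (lo, hi); pixel on lo-side vs hi-side
    by_pair: dict[tuple[int, int], list[tuple]] = {}
    for py, px, qy, qx, lp, lq, d2 in pair_rows:
        lo, hi = (lp, lq) if lp < lq else (lq, lp)
        if lp < lq:
            row = ((py, px), (qy, qx), d2)
        else:
            row = ((qy, qx), (py, px), d2)
        by_pair.setdefault((int(lo), int(hi)), []).append(row)

    sites: list[ContactSite] = []
    for (lo, hi), rows in sorted(by_pair.items()):
        uf = _UnionFind()
        lo_pixels = {r[0] for r in rows}
        hi_pixels = {r[1] for r in rows}
        dist2: dict[tuple, int] = {}
        for p, q, d2 in rows:
            a, b = ("a", p), ("b", q)
            uf.union(a, b)
            key = (p, q)
            if key not in dist2 or d2 < dist2[key]:
                dist2[key] = d2
        for side, pixset in (("a", lo_pixels), ("b", hi_pixels)):
            for (y, x) in pixset:
                for dy, dx in _NEIGHBOURS_8:
                    nb = (y + dy, x + dx)
                    if nb in pixset:
                        uf.union((side, (y, x)), (side, nb))
        comps: dict[tuple, dict[str, set]] = {}
        for side, pix in list(uf.parent):
            root = uf.find((side, pix))
            comps.setdefault(root, {"a": set(), "b": set()})[side].add(pix)
        for root in sorted(comps, key=lambda r: sorted(comps[r]["a"] | comps[r]["b"])):
            ca, cb = comps[root]["a"], comps[root]["b"]
            if len(ca) <= 1 or len(cb) <= 1:
                continue  # single-contacting-pixel sites are noise
            d2min = min(
                d2 for (p, q), d2 in dist2.items() if p in ca and q in cb
            )
            sites.append(
                ContactSite(
                    site_id=0,
                    id_a=lo,
                    id_b=hi,
                    class_a=objects.classes[lo],
                    class_b=objects.classes[hi],
                    pixels_a=frozenset(ca),
                    pixels_b=frozenset(cb),
                    min_dist_px=float(np.sqrt(d2min)),
                )
            )
    for i, s in enumerate(sites, start=1):
        s.site_id = i
    return sites


def find_contacts(
    objects: LabeledObjects, spec: DistanceSpec | None = None
) -> list[ContactSite]:
    """Raster-scan ROI contact search over a labeled object raster.

    For every perimeter pixel, perimeter pixels of other objects inside the
    centred (2m+1) x (2m+1) window at Euclidean distance <= m are contacting
    pixels.  Distances compare squared integer pixel offsets, so threshold
    decisions are exact.
    """
    spec = spec or DistanceSpec(pixel_size_nm=objects.pixel_size_nm)
    labels = objects.labels
    h, w = labels.shape
    perim = _perimeter_raster(labels)
    plab = np.where(perim, labels, 0)
    rows = []
    for dy, dx in _window_offsets(spec.m):
        ys = slice(max(dy, 0), h + min(dy, 0))
        xs = slice(max(dx, 0), w + min(dx, 0))
        yt = slice(max(-dy, 0), h + min(-dy, 0))
        xt = slice(max(-dx, 0), w + min(-dx, 0))
        a = plab[yt, xt]
        b = plab[ys, xs]
        hit = (a > 0) & (b > 0) & (a != b)
        if not hit.any():
            continue
        py, px = np.nonzero(hit)
        py = py + max(-dy, 0)
        px = px + max(-dx, 0)
        qy, qx = py + dy, px + dx
        d2 = dy * dy + dx * dx
        rows.append(
            np.column_stack(
                [py, px, qy, qx, labels[py, px], labels[qy, qx],
                 np.full(py.shape, d2, dtype=np.int64)]
            )
        )
    pair_rows = np.concatenate(rows, axis=0) if rows else np.empty((0, 7), dtype=int)
    return _sites_from_pairs(objects, pair_rows, spec)


def find_contacts_bruteforce(
    objects: LabeledObjects, spec: DistanceSpec | None = None
) -> list[ContactSite]:
    """Definitional all-pairs contact computation (validation oracle).

    Enumerates every pair of objects, computes the full distance matrix
    between their perimeter pixel sets, thresholds at m, and groups
    contacting pixels into sites with networkx connected components.
    """
    import networkx as nx
    from scipy.spatial.distance import cdist

    spec = spec or DistanceSpec(pixel_size_nm=objects.pixel_size_nm)
    perim_coords = {}
    for oid in objects.ids:
        m = objects.labels == oid
        coords = np.argwhere(m)
        keep = []
        pixset = {tuple(c) for c in coords}
        for (y, x) in pixset:
            on_border = y in (0, objects.labels.shape[0] - 1) or x in (
                0,
                objects.labels.shape[1] - 1,
            )
            if on_border or any(
                (y + dy, x + dx) not in pixset for dy, dx in _NEIGHBOURS_8
            ):
                keep.append((y, x))
        perim_coords[oid] = np.array(sorted(keep), dtype=int)

    sites = []
    for ia, ib in itertools.combinations(objects.ids, 2):
        pa, pb = perim_coords[ia], perim_coords[ib]
        if len(pa) == 0 or len(pb) == 0:
            continue
        d2 = cdist(pa, pb, "sqeuclidean").round().astype(np.int64)
        ii, jj = np.nonzero(d2 <= spec.m * spec.m)
        if len(ii) == 0:
            continue
        g = nx.Graph()
        for i, j in zip(ii, jj):
            g.add_edge(("a", tuple(pa[i])), ("b", tuple(pb[j])), d2=int(d2[i, j]))
        for side, coords_used in (
            ("a", {tuple(pa[i]) for i in ii}),
            ("b", {tuple(pb[j]) for j in jj}),
        ):
            for (y, x) in coords_used:
                for dy, dx in _NEIGHBOURS_8:
                    if (y + dy, x + dx) in coords_used:
                        g.add_edge((side, (y, x)), (side, (y + dy, x + dx)))
        for comp in nx.connected_components(g):
            ca = {pix for s, pix in comp if s == "a"}
            cb = {pix for s, pix in comp if s == "b"}
            if len(ca) <= 1 or len(cb) <= 1:
                continue
            d2min = min(
                data["d2"]
                for u, v, data in g.edges(comp, data=True)
                if "d2" in data
            )
            sites.append(
                ContactSite(
                    site_id=0,
                    id_a=ia,
                    id_b=ib,
                    class_a=objects.classes[ia],
                    class_b=objects.classes[ib],
                    pixels_a=frozenset(ca),
                    pixels_b=frozenset(cb),
                    min_dist_px=float(np.sqrt(d2min)),
                )
            )
    sites.sort(key=lambda s: (s.id_a, s.id_b, sorted(s.pixels_a | s.pixels_b)))
    for i, s in enumerate(sites, start=1):
        s.site_id = i
    return sites


@dataclass
class ContactProfile:
    """Per-object contact summary.

    ``partner_counts`` are this object's contacting pixels per partner
    class; ``partner_fractions`` divide by the object's perimeter pixel
    count.  A pixel in contact with two partner classes counts toward both;
    ``total_fraction`` uses the union of contacting pixels, so it never
    exceeds 1.
    """

    object_id: int
    cls: str
    perimeter_px: int
    partner_counts: dict[str, int] = field(default_factory=dict)
    partner_fractions: dict[str, float] = field(default_factory=dict)
    partner_min_dist_px: dict[str, float] = field(default_factory=dict)
    total_fraction: float = 0.0
    label: str = "isolated"


def classify_by_partner(profile: ContactProfile) -> str:
    """Contact-class label from the closest interacting partner.

    The label is ``<Own>-<Partner>`` (e.g. ``Mito-ER``) for the partner
    class at the smallest minimum pixel distance; distance ties are broken
    by the larger contacting-pixel count, then by a fixed class priority
    (ER > LD > glycogen > mitochondria).  Objects without contacts are
    ``isolated``.
    """
    if not profile.partner_counts:
        return "isolated"
    order = {c: i for i, c in enumerate(PARTNER_TIEBREAK_ORDER)}
    best = min(
        profile.partner_counts,
        key=lambda c: (
            profile.partner_min_dist_px[c],
            -profile.partner_counts[c],
            order.get(c, len(order)),
        ),
    )
    own = CLASS_SHORT_NAMES.get(profile.cls, profile.cls)
    other = CLASS_SHORT_NAMES.get(best, best)
    return f"{own}-{other}"


def contact_profiles(
    objects: LabeledObjects,
    sites: list[ContactSite],
    perimeter_px: dict[int, int] | None = None,
) -> dict[int, ContactProfile]:
    """Contact fraction and closest-partner class for every object."""
    if perimeter_px is None:
        perim = _perimeter_raster(objects.labels)
        ids, counts = np.unique(
            objects.labels[perim & (objects.labels > 0)], return_counts=True
        )
        perimeter_px = dict(zip(ids.tolist(), counts.tolist()))
    profiles: dict[int, ContactProfile] = {}
    per_partner_pixels: dict[int, dict[str, set]] = {}
    all_pixels: dict[int, set] = {}
    for oid in objects.ids:
        p = perimeter_px.get(oid, 0)
        if p == 0:
            raise ValueError(f"object {oid} has zero perimeter")
        profiles[oid] = ContactProfile(
            object_id=oid, cls=objects.classes[oid], perimeter_px=p
        )
        per_partner_pixels[oid] = {}
        all_pixels[oid] = set()
    for s in sites:
        for oid, partner_cls, pix in (
            (s.id_a, s.class_b, s.pixels_a),
            (s.id_b, s.class_a, s.pixels_b),
        ):
            per_partner_pixels[oid].setdefault(partner_cls, set()).update(pix)
            all_pixels[oid].update(pix)
            prof = profiles[oid]
            prev = prof.partner_min_dist_px.get(partner_cls)
            if prev is None or s.min_dist_px < prev:
                prof.partner_min_dist_px[partner_cls] = s.min_dist_px
    for oid, prof in profiles.items():
        for partner_cls, pix in per_partner_pixels[oid].items():
            prof.partner_counts[partner_cls] = len(pix)
            prof.partner_fractions[partner_cls] = len(pix) / prof.perimeter_px
        prof.total_fraction = len(all_pixels[oid]) / prof.perimeter_px
        prof.label = classify_by_partner(prof)
    return profiles


def enrichment_by_contact_class(
    profiles: dict[int, ContactProfile],
    object_mean_ratio: dict[int, float],
    cls: str | None = None,
) -> pd.DataFrame:
    """Group object mean ratios by contact-class label.

    Optionally restrict to objects of one organelle class (e.g. compare
    isolated vs ER-contacting mitochondria).  Returns rows of
    (contact_class, n, mean_ratio, sd_ratio); empty groups are omitted.
    """
    groups: dict[str, list[float]] = {}
    for oid, prof in profiles.items():
        if cls is not None and prof.cls != cls:
            continue
        if oid in object_mean_ratio:
            groups.setdefault(prof.label, []).append(object_mean_ratio[oid])
    rows = [
        {
            "contact_class": label,
            "n": len(v),
            "mean_ratio": float(np.mean(v)),
            "sd_ratio": float(np.std(v, ddof=0)),
        }
        for label, v in sorted(groups.items())
    ]
    return pd.DataFrame(rows, columns=["contact_class", "n", "mean_ratio", "sd_ratio"])
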