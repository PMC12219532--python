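"""Ground-truth-annotated synthetic scenes, point patterns and benchmarking.

The generator emulates the anatomy that the downstream pipeline is built
for: a convex cell containing one nucleus, elliptical mitochondria, thick
curvilinear ER ribbons, clustered granular glycogen depots (granules of
~40 nm, i.e. ~8 px at 5 nm/px) and large circular lipid droplets, plus a
registered ratio image with per-class enrichment offsets over the 102
terrestrial background and additive Gaussian noise clipped at that floor.
Contacts between chosen class pairs can be planted at exact pixel gaps, and
point patterns of known spatial character (CSR / clustered / dispersed /
grid) support calibration of the randomness test.

Everything is deterministic under a fixed seed.  The generator makes no
attempt to mimic SEM texture or ion-counting statistics; it provides exact
geometric and isotopic ground truth, which is what the validation suite
needs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage import draw as skdraw
from skimage.morphology import disk as disk_struct

from orgspat.defaults import BACKGROUND_RATIO, DEFAULT_PIXEL_SIZE_NM
from orgspat.isotope import RatioImage
from orgspat.preprocess import LabeledObjects, MaskStack, label_objects

_PLACEMENT_ORDER = ("ld", "mitochondria", "er", "glycogen")


# ---------------------------------------------------------------------------
# point patterns


def generate_point_pattern(
    kind: str,
    n: int,
    box,
    params: dict | None = None,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Generate n points (nm) in a rectangular box with known spatial character.

    Parameters
    ----------
    kind
        ``csr`` (uniform / homogeneous Poisson conditioned on n),
        ``clustered`` (parent-offspring clusters; params ``n_parents``,
        ``offspring_sd``), ``dispersed`` (sequential inhibition with a
        minimum distance; param ``min_dist``), or ``grid`` (square lattice,
        row-major fill).
    box
        (width, height) in nm, lower-left corner at the origin, or
        (xmin, ymin, xmax, ymax).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    box = tuple(float(v) for v in box)
    if len(box) == 2:
        xmin, ymin, xmax, ymax = 0.0, 0.0, box[0], box[1]
    elif len(box) == 4:
        xmin, ymin, xmax, ymax = box
    else:
        raise ValueError("box must be (w, h) or (xmin, ymin, xmax, ymax)")
    w, h = xmax - xmin, ymax - ymin
    if w <= 0 or h <= 0:
        raise ValueError("box must have positive area")
    params = params or {}
    if rng is None:
        rng = np.random.default_rng(seed)

    if kind == "csr":
        pts = np.column_stack(
            [xmin + rng.random(n) * w, ymin + rng.random(n) * h]
        )
    elif kind == "clustered":
        n_parents = int(params.get("n_parents", 5))
        sd = float(params.get("offspring_sd", min(w, h) / 50.0))
        parents = np.column_stack(
            [xmin + rng.random(n_parents) * w, ymin + rng.random(n_parents) * h]
        )
        pts = np.empty((n, 2))
        for i in range(n):
            parent = parents[rng.integers(n_parents)]
            while True:
                p = parent + rng.normal(0.0, sd, size=2)
                if xmin <= p[0] <= xmax and ymin <= p[1] <= ymax:
                    pts[i] = p
                    break
    elif kind == "dispersed":
        lam = n / (w * h)
        min_dist = float(params.get("min_dist", 0.7 / np.sqrt(lam)))
        accepted: list[np.ndarray] = []
        tries = 0
        cap = max(10000, 1000 * n)
        while len(accepted) < n:
            tries += 1
            if tries > cap:
                raise RuntimeError(
                    "sequential inhibition failed; lower min_dist or n"
                )
            p = np.array([xmin + rng.random() * w, ymin + rng.random() * h])
            if all(np.hypot(*(p - q)) >= min_dist for q in accepted):
                accepted.append(p)
        pts = np.array(accepted)
    elif kind == "grid":
        side = int(np.ceil(np.sqrt(n)))
        s = min(w, h) / side
        pts = np.array(
            [
                (xmin + (i % side + 0.5) * s, ymin + (i // side + 0.5) * s)
                for i in range(n)
            ]
        )
    else:
        raise ValueError(f"unknown pattern kind {kind!r}")
    return pts


# ---------------------------------------------------------------------------
# scene configuration


def _default_counts() -> dict[str, int]:
    return {"mitochondria": 10, "er": 6, "glycogen": 6, "ld": 3}


def _default_fractions() -> dict[str, float]:
    # fractions of the CELL area, sized so that default objects survive the
    # standard size-exclusion thresholds (mito/LD >= 5000 px, ER/Gly >= 500)
    return {
        "nucleus": 0.15,
        "mitochondria": 0.13,
        "er": 0.045,
        "glycogen": 0.05,
        "ld": 0.05,
    }


def _default_offsets() -> dict[str, float]:
    # scaled-ratio offsets above the 102 background per class
    return {
        "nucleus": 15.0,
        "mitochondria": 30.0,
        "er": 20.0,
        "glycogen": 60.0,
        "ld": 10.0,
    }


@dataclass
class SceneConfig:
    """Parameters of one synthetic cell scene.

    ``counts`` are free-standing objects per class; planted contact pairs in
    ``contact_plan`` (class_a, class_b, gap_px) are additional objects.
    ``area_fractions`` are targets relative to the cell area; realized
    fractions land within +-20% of target.  ``noise_sd`` is the additive
    Gaussian noise on the scaled ratio (clipped at the 102 floor).
    """

    image_shape: tuple[int, int] = (896, 896)
    pixel_size_nm: float = DEFAULT_PIXEL_SIZE_NM
    counts: dict[str, int] = field(default_factory=_default_counts)
    area_fractions: dict[str, float] = field(default_factory=_default_fractions)
    contact_plan: list[tuple[str, str, int]] = field(default_factory=list)
    enrichment_offsets: dict[str, float] = field(default_factory=_default_offsets)
    noise_sd: float = 5.0
    background_value: float = BACKGROUND_RATIO
    er_width_px: int = 13
    glycogen_granule_radius_px: int = 4
    margin_px: int = 3
    max_retries: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if sum(self.area_fractions.values()) > 1.0:
            raise ValueError("area fractions sum to more than 1")
        if any(v < 0 for v in self.counts.values()):
            raise ValueError("counts must be >= 0")
        if any(g < 0 for _, _, g in self.contact_plan):
            raise ValueError("contact gaps must be >= 0")
        if self.noise_sd < 0:
            raise ValueError("noise sd must be >= 0")


@dataclass
class SyntheticScene:
    """A generated scene with exact ground truth.

    ``planted_contacts`` rows are ((class_a, id_a), (class_b, id_b),
    gap_px) with ids referring to per-class ground-truth labelings
    (:meth:`labeled`); the minimum pixel-centre distance between the two
    objects is exactly ``gap_px + 1``.
    """

    mask_stack: MaskStack
    ratio_image: RatioImage
    planted_contacts: list[tuple[tuple[str, int], tuple[str, int], int]]
    pattern_labels: dict[str, str]
    config: SceneConfig

    def labeled(self, cls: str) -> LabeledObjects:
        """Ground-truth labeling of one class (8-connected, raster order)."""
        return label_objects(
            self.mask_stack.masks[cls], cls, pixel_size_nm=self.config.pixel_size_nm
        )


# ---------------------------------------------------------------------------
# shape primitives (masks are small local stamps placed by rejection sampling)


def _disc_stamp(radius: int) -> np.ndarray:
    size = 2 * radius + 1
    stamp = np.zeros((size, size), dtype=bool)
    rr, cc = skdraw.disk((radius, radius), radius + 0.5, shape=stamp.shape)
    stamp[rr, cc] = True
    return stamp


def _ellipse_stamp(area_px: float, axis_ratio: float, rotation: float) -> np.ndarray:
    b = np.sqrt(area_px / (np.pi * axis_ratio))
    a = axis_ratio * b
    half = int(np.ceil(a)) + 2
    size = 2 * half + 1
    stamp = np.zeros((size, size), dtype=bool)
    rr, cc = skdraw.ellipse(half, half, b, a, shape=stamp.shape, rotation=rotation)
    stamp[rr, cc] = True
    return stamp


def _er_stamp(
    area_px: float, width_px: int, rng: np.random.Generator
) -> np.ndarray:
    """Curvilinear ribbon: a smoothed random walk dilated to a fixed width."""
    length = max(int(area_px / width_px), 20)
    step = 3.0
    n_steps = max(length // int(step), 5)
    heading = rng.uniform(0, 2 * np.pi)
    pos = np.zeros(2)
    pts = [pos.copy()]
    for _ in range(n_steps):
        heading += rng.uniform(-0.25, 0.25)
        pos = pos + step * np.array([np.cos(heading), np.sin(heading)])
        pts.append(pos.copy())
    pts = np.array(pts)
    pts -= pts.min(axis=0)
    radius = width_px // 2
    h = int(np.ceil(pts[:, 1].max())) + 2 * radius + 3
    w = int(np.ceil(pts[:, 0].max())) + 2 * radius + 3
    stamp = np.zeros((h, w), dtype=bool)
    ipts = np.rint(pts[:, ::-1]).astype(int) + radius + 1  # (row, col)
    for (r0, c0), (r1, c1) in zip(ipts[:-1], ipts[1:]):
        rr, cc = skdraw.line(r0, c0, r1, c1)
        stamp[rr, cc] = True
    return ndimage.binary_dilation(stamp, structure=disk_struct(radius))


def _glycogen_stamp(
    area_px: float, granule_radius: int, rng: np.random.Generator
) -> np.ndarray:
    """Connected depot of overlapping granules (beta-particle cluster)."""
    g = _disc_stamp(granule_radius)
    est = int(np.ceil(area_px / (0.55 * g.sum()))) + 1
    half = int(np.ceil(np.sqrt(area_px))) + 4 * granule_radius
    size = 2 * half + 1
    stamp = np.zeros((size, size), dtype=bool)
    centers = [np.array([half, half], dtype=float)]
    _place_stamp(stamp, g, half - granule_radius, half - granule_radius)
    cap = max(2000, 20 * est)
    while stamp.sum() < area_px and len(centers) < cap:
        base = centers[rng.integers(len(centers))]
        ang = rng.uniform(0, 2 * np.pi)
        dist = rng.uniform(1.3 * granule_radius, 2.0 * granule_radius)
        c = base + dist * np.array([np.sin(ang), np.cos(ang)])
        r0, c0 = int(round(c[0])) - granule_radius, int(round(c[1])) - granule_radius
        if r0 < 0 or c0 < 0 or r0 + g.shape[0] > size or c0 + g.shape[1] > size:
            continue
        centers.append(c)
        _place_stamp(stamp, g, r0, c0)
    return _crop_to_content(stamp)


def _place_stamp(canvas: np.ndarray, stamp: np.ndarray, r0: int, c0: int) -> None:
    canvas[r0 : r0 + stamp.shape[0], c0 : c0 + stamp.shape[1]] |= stamp


def _crop_to_content(mask: np.ndarray) -> np.ndarray:
    rows = np.any(mask, axis=1)
    cols = np.any(mask, axis=0)
    return mask[rows.argmax() : len(rows) - rows[::-1].argmax(),
                cols.argmax() : len(cols) - cols[::-1].argmax()]


def _make_stamp(
    cls: str, area_px: float, config: SceneConfig, rng: np.random.Generator
) -> np.ndarray:
    if cls == "mitochondria":
        return _crop_to_content(
            _ellipse_stamp(area_px, rng.uniform(1.0, 3.0), rng.uniform(0, np.pi))
        )
    if cls == "ld":
        return _disc_stamp(max(int(round(np.sqrt(area_px / np.pi))), 1))
    if cls == "er":
        return _crop_to_content(_er_stamp(area_px, config.er_width_px, rng))
    if cls == "glycogen":
        return _glycogen_stamp(area_px, config.glycogen_granule_radius_px, rng)
    raise ValueError(f"no geometry primitive for class {cls!r}")


# ---------------------------------------------------------------------------
# scene assembly


def _try_place(
    stamp: np.ndarray,
    allowed: np.ndarray,
    occupied: np.ndarray,
    margin: int,
    rng: np.random.Generator,
    max_retries: int,
) -> tuple[int, int] | None:
    """Find an (r0, c0) where the stamp fits inside `allowed` clear of `occupied`."""
    H, W = allowed.shape
    h, w = stamp.shape
    if h > H or w > W:
        return None
    if margin > 0:
        grown = ndimage.binary_dilation(
            np.pad(stamp, margin), structure=disk_struct(margin)
        )
    else:
        grown = stamp
    gh, gw = grown.shape
    pad = (gh - h) // 2
    for _ in range(max_retries):
        r0 = int(rng.integers(0, H - h + 1))
        c0 = int(rng.integers(0, W - w + 1))
        window = allowed[r0 : r0 + h, c0 : c0 + w]
        if not window[stamp].all():
            continue
        gr0, gc0 = r0 - pad, c0 - pad
        rs = slice(max(gr0, 0), min(gr0 + gh, H))
        cs = slice(max(gc0, 0), min(gc0 + gw, W))
        gsub = grown[rs.start - gr0 : rs.stop - gr0, cs.start - gc0 : cs.stop - gc0]
        if (occupied[rs, cs] & gsub).any():
            continue
        return r0, c0
    return None


def _min_pair_distance(mask_a: np.ndarray, mask_b: np.ndarray) -> float:
    from scipy.spatial.distance import cdist

    ca = np.argwhere(mask_a)
    cb = np.argwhere(mask_b)
    return float(np.sqrt(cdist(ca, cb, "sqeuclidean").min()))


def generate_scene(config: SceneConfig | None = None) -> SyntheticScene:
    """Generate a synthetic cell scene with exact geometric ground truth.

    Raises ``RuntimeError`` naming the class when an object cannot be placed
    without overlap within the configured retry budget.
    """
    config = config or SceneConfig()
    rng = np.random.default_rng(config.seed)
    H, W = config.image_shape

    cell = np.zeros((H, W), dtype=bool)
    rr, cc = skdraw.ellipse(H / 2, W / 2, 0.45 * H, 0.45 * W, shape=(H, W))
    cell[rr, cc] = True
    cell_area = cell.sum()

    masks: dict[str, np.ndarray] = {"cell": cell}
    occupied = np.zeros((H, W), dtype=bool)

    # nucleus: one disc near the centre
    nuc_frac = config.area_fractions.get("nucleus", 0.0)
    if nuc_frac > 0:
        r_nuc = int(round(np.sqrt(nuc_frac * cell_area / np.pi)))
        stamp = _disc_stamp(r_nuc)
        jitter = rng.integers(-H // 16, H // 16 + 1, size=2)
        r0 = H // 2 - r_nuc + int(jitter[0])
        c0 = W // 2 - r_nuc + int(jitter[1])
        nuc = np.zeros((H, W), dtype=bool)
        _place_stamp(nuc, stamp, r0, c0)
        if not cell[nuc].all():
            raise RuntimeError("failed to place class 'nucleus' inside the cell")
        masks["nucleus"] = nuc
        occupied |= nuc

    placed_seeds: dict[str, list[tuple[int, int]]] = {c: [] for c in _PLACEMENT_ORDER}
    class_masks = {c: np.zeros((H, W), dtype=bool) for c in _PLACEMENT_ORDER}

    def object_area(cls: str) -> float:
        n_total = config.counts.get(cls, 0) + sum(
            1 for a, b, _ in config.contact_plan for x in (a, b) if x == cls
        )
        frac = config.area_fractions.get(cls, 0.0)
        if n_total == 0 or frac == 0:
            return 0.0
        return frac * cell_area / n_total

    planted: list[tuple[tuple[str, int], tuple[str, int], int]] = []
    planted_seeds: list[tuple[str, tuple[int, int], str, tuple[int, int], int]] = []

    # planted contact pairs first: two square pads side by side at an exact
    # gap; the flat facing edges give an extended, unambiguous contact zone
    for cls_a, cls_b, gap in config.contact_plan:
        side_a = max(int(round(np.sqrt(max(object_area(cls_a), 64)))), 3)
        side_b = max(int(round(np.sqrt(max(object_area(cls_b), 64)))), 3)
        sa = np.ones((side_a, side_a), dtype=bool)
        sb = np.ones((side_b, side_b), dtype=bool)
        h = max(sa.shape[0], sb.shape[0])
        # leftmost pixel of B sits gap+1 columns right of A's rightmost pixel,
        # on the shared centre row, so the minimum centre distance is gap+1
        w = sa.shape[1] + gap + sb.shape[1]
        pair = np.zeros((h, w), dtype=bool)
        ya = (h - sa.shape[0]) // 2
        yb = (h - sb.shape[0]) // 2
        _place_stamp(pair, sa, ya, 0)
        _place_stamp(pair, sb, yb, sa.shape[1] + gap)
        pos = _try_place(pair, cell, occupied, config.margin_px, rng, config.max_retries)
        if pos is None:
            raise RuntimeError(
                f"failed to place planted contact pair {cls_a}-{cls_b}"
            )
        r0, c0 = pos
        ma = np.zeros((H, W), dtype=bool)
        mb = np.zeros((H, W), dtype=bool)
        _place_stamp(ma, sa, r0 + ya, c0)
        _place_stamp(mb, sb, r0 + yb, c0 + sa.shape[1] + gap)
        realized = _min_pair_distance(ma, mb)
        if realized != gap + 1:
            raise RuntimeError(
                f"planted gap mismatch for {cls_a}-{cls_b}: {realized} != {gap + 1}"
            )
        class_masks[cls_a] |= ma
        class_masks[cls_b] |= mb
        occupied |= ma | mb
        seed_a = tuple(np.argwhere(ma)[0])
        seed_b = tuple(np.argwhere(mb)[0])
        planted_seeds.append((cls_a, seed_a, cls_b, seed_b, gap))

    # free-standing objects, largest classes first
    for cls in _PLACEMENT_ORDER:
        n = config.counts.get(cls, 0)
        if n == 0:
            continue
        target = object_area(cls)
        for k in range(n):
            placed = False
            for _ in range(20):  # regenerate the shape if it will not fit
                stamp = _make_stamp(cls, target, config, rng)
                if cls == "er" and abs(stamp.sum() - target) > 0.15 * target:
                    continue
                pos = _try_place(
                    stamp, cell, occupied, config.margin_px, rng, config.max_retries
                )
                if pos is not None:
                    r0, c0 = pos
                    _place_stamp(class_masks[cls], stamp, r0, c0)
                    occupied |= class_masks[cls]
                    first = np.argwhere(stamp)[0]
                    placed_seeds[cls].append((r0 + first[0], c0 + first[1]))
                    placed = True
                    break
            if not placed:
                raise RuntimeError(
                    f"failed to place object {k + 1}/{n} of class {cls!r}"
                )

    for cls in _PLACEMENT_ORDER:
        if class_masks[cls].any():
            masks[cls] = class_masks[cls]

    stack = MaskStack(masks, pixel_size_nm=config.pixel_size_nm, preprocessed=False)

    # resolve planted seeds to ground-truth per-class object ids
    label_cache = {
        cls: label_objects(stack.masks[cls], cls, pixel_size_nm=config.pixel_size_nm)
        for cls in stack.organelle_classes
        if cls != "nucleus"
    }
    for cls_a, seed_a, cls_b, seed_b, gap in planted_seeds:
        id_a = int(label_cache[cls_a].labels[seed_a])
        id_b = int(label_cache[cls_b].labels[seed_b])
        planted.append(((cls_a, id_a), (cls_b, id_b), gap))

    pattern_labels = {cls: "csr" for cls in stack.organelle_classes}
    pattern_labels.pop("nucleus", None)

    scene = SyntheticScene(
        mask_stack=stack,
        ratio_image=RatioImage(
            np.full((H, W), config.background_value),
            pixel_size_nm=config.pixel_size_nm,
        ),
        planted_contacts=planted,
        pattern_labels=pattern_labels,
        config=config,
    )
    scene.ratio_image = render_ratio_image(scene, config)
    return scene


def render_ratio_image(
    scene: SyntheticScene,
    config: SceneConfig | None = None,
    rng: np.random.Generator | None = None,
) -> RatioImage:
    """Render the scaled-ratio image for a scene.

    Pixels start at ``background_value``; each organelle class adds its
    enrichment offset; Gaussian noise of ``noise_sd`` is added everywhere
    and the result is clipped at the 102 terrestrial floor.
    """
    config = config or scene.config
    if config.noise_sd < 0:
        raise ValueError("noise sd must be >= 0")
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, 7]))
    vals = np.full(scene.mask_stack.shape, config.background_value, dtype=np.float64)
    for cls, offset in config.enrichment_offsets.items():
        if cls in scene.mask_stack.masks:
            vals[scene.mask_stack.masks[cls]] += offset
    if config.noise_sd > 0:
        vals = vals + rng.normal(0.0, config.noise_sd, size=vals.shape)
    vals = np.maximum(vals, BACKGROUND_RATIO)
    return RatioImage(
        vals, pixel_size_nm=config.pixel_size_nm, flags=frozenset({"floored"})
    )


# ---------------------------------------------------------------------------
# small random object fields for fuzzing the contact search


def generate_blob_field(
    shape: tuple[int, int] = (128, 128),
    n_objects: int = 8,
    classes: tuple[str, ...] = ("mitochondria", "er", "glycogen", "ld"),
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    max_retries: int = 200,
) -> LabeledObjects:
    """Scatter small random discs/ellipses/rectangles as labeled objects.

    Objects are pairwise disjoint but may lie arbitrarily close (including
    direct adjacency), which makes these fields good stress inputs for the
    contact-site search.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    H, W = shape
    labels = np.zeros((H, W), dtype=np.int32)
    class_of: dict[int, str] = {}
    next_id = 1
    for _ in range(n_objects):
        kind = rng.choice(("disc", "ellipse", "rect"))
        if kind == "disc":
            stamp = _disc_stamp(int(rng.integers(2, 7)))
        elif kind == "ellipse":
            stamp = _crop_to_content(
                _ellipse_stamp(
                    float(rng.integers(20, 150)),
                    rng.uniform(1.0, 3.0),
                    rng.uniform(0, np.pi),
                )
            )
        else:
            stamp = np.ones((int(rng.integers(2, 10)), int(rng.integers(2, 10))), bool)
        for _ in range(max_retries):
            r0 = int(rng.integers(0, H - stamp.shape[0] + 1))
            c0 = int(rng.integers(0, W - stamp.shape[1] + 1))
            window = labels[r0 : r0 + stamp.shape[0], c0 : c0 + stamp.shape[1]]
            if (window[stamp] != 0).any():
                continue
            window[stamp] = next_id
            class_of[next_id] = str(rng.choice(classes))
            next_id += 1
            break
    return LabeledObjects(labels, class_of)


# ---------------------------------------------------------------------------
# segmentation benchmarking


@dataclass
class BenchmarkResult:
    """Pixel-level comparison of a predicted mask against ground truth."""

    tp: int
    fp: int
    fn: int
    precision: float
    recall: float
    f_score: float


def benchmark_masks(predicted: np.ndarray, truth: np.ndarray) -> BenchmarkResult:
    """Pixel precision / recall / F-score of a predicted binary mask.

    With no true-positive pixels, precision, recall and F are all defined
    as 0 (this keeps the scores monotone without dividing by zero).
    """
    predicted = np.asarray(predicted, dtype=bool)
    truth = np.asarray(truth, dtype=bool)
    if predicted.shape != truth.shape:
        raise ValueError("predicted and truth masks must have the same shape")
    tp = int((predicted & truth).sum())
    fp = int((predicted & ~truth).sum())
    fn = int((~predicted & truth).sum())
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    f = (
        2 * precision * recall / (precision + recall)
        if precision + recall
        else 0.0
    )
    return BenchmarkResult(tp, fp, fn, precision, recall, f)
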