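"""File I/O, configuration and the end-to-end per-cell pipeline.

One invocation analyses one cell: a set of per-class masks plus an optional
registered ratio image.  Float-valued inputs are treated as segmentation
probability maps and binarized at a confidence threshold (default 0.90);
integer inputs are binarized at > 0.  All tabular outputs are CSV, masks are
single-channel 8-bit TIFF/PNG, ratio images 32-bit float TIFF, and a JSON
run log captures the configuration and seed so a rerun is byte-identical.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile
import yaml

from orgspat import __version__ as _pkg_version
from orgspat.contacts import (
    ContactSite,
    DistanceSpec,
    contact_profiles,
    enrichment_by_contact_class,
    find_contacts,
)
from orgspat.defaults import (
    DEFAULT_CONTACT_RADIUS_PX,
    DEFAULT_CSR_N_SIMS,
    DEFAULT_NETWORK_RADIUS_NM,
    DEFAULT_PIXEL_SIZE_NM,
    DEFAULT_PROBABILITY_THRESHOLD,
    SIZE_THRESHOLDS_PX,
)
from orgspat.isotope import RatioImage, condition_ratio, enrichment_summary
from orgspat.morphometry import composition, object_table
from orgspat.network import (
    build_network,
    communities,
    connectivity_fraction,
    first_neighbor_proportions,
    nn_csr_test,
)
from orgspat.preprocess import (
    LabeledObjects,
    MaskStack,
    PreprocessConfig,
    preprocess_stack,
)

log = logging.getLogger("orgspat")


@dataclass
class PipelineConfig:
    """Everything one per-cell analysis needs, with standard defaults."""

    mask_paths: dict[str, str] = field(default_factory=dict)
    ratio_path: str | None = None
    pixel_size_nm: float = DEFAULT_PIXEL_SIZE_NM
    probability_threshold: float = DEFAULT_PROBABILITY_THRESHOLD
    size_thresholds: dict[str, int] = field(
        default_factory=lambda: dict(SIZE_THRESHOLDS_PX)
    )
    contact_m: int = DEFAULT_CONTACT_RADIUS_PX
    radius_nm: float = DEFAULT_NETWORK_RADIUS_NM
    csr_n_sims: int = DEFAULT_CSR_N_SIMS
    seed: int = 0
    out_dir: str = "orgspat_out"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)


def _binarize(arr: np.ndarray, threshold: float) -> np.ndarray:
    if arr.ndim == 3:  # collapse an RGB(A) export to one channel
        arr = arr[..., 0]
    if np.issubdtype(arr.dtype, np.floating):
        return arr >= threshold
    return arr > 0


def read_mask(path: str | Path, threshold: float = DEFAULT_PROBABILITY_THRESHOLD) -> np.ndarray:
    """Read a single-channel mask or probability map and binarize it."""
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        arr = tifffile.imread(path)
    else:
        arr = iio.imread(path)
    return _binarize(np.asarray(arr), threshold)


def write_mask(path: str | Path, mask: np.ndarray) -> None:
    arr = (np.asarray(mask, dtype=bool) * np.uint8(255)).astype(np.uint8)
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, arr)
    else:
        iio.imwrite(path, arr)


def read_ratio(path: str | Path, pixel_size_nm: float = DEFAULT_PIXEL_SIZE_NM) -> RatioImage:
    """Read a 32-bit float TIFF ratio image."""
    return RatioImage(tifffile.imread(path), pixel_size_nm=pixel_size_nm)


def write_ratio(path: str | Path, img: RatioImage) -> None:
    tifffile.imwrite(path, img.values.astype(np.float32))


def load_mask_stack(config: PipelineConfig) -> MaskStack:
    """Load and binarize all configured masks onto one grid.

    Raises with the offending file names when shapes disagree.
    """
    masks = {}
    for cls, path in config.mask_paths.items():
        masks[cls] = read_mask(path, config.probability_threshold)
    shapes = {cls: m.shape for cls, m in masks.items()}
    if len(set(shapes.values())) > 1:
        detail = ", ".join(f"{config.mask_paths[c]}: {s}" for c, s in shapes.items())
        raise ValueError(f"mask shapes disagree: {detail}")
    return MaskStack(masks, pixel_size_nm=config.pixel_size_nm)


def write_mask_stack(stack: MaskStack, out_dir: str | Path, fmt: str = "tif") -> dict[str, Path]:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {}
    for cls, mask in stack.masks.items():
        p = out_dir / f"mask_{cls}.{fmt}"
        write_mask(p, mask)
        paths[cls] = p
    return paths


def sites_table(sites: list[ContactSite], pixel_size_nm: float) -> pd.DataFrame:
    rows = [
        {
            "site_id": s.site_id,
            "class_a": s.class_a,
            "id_a": s.id_a,
            "class_b": s.class_b,
            "id_b": s.id_b,
            "size": s.size,
            "min_dist_px": s.min_dist_px,
            "min_dist_nm": s.min_dist_px * pixel_size_nm,
        }
        for s in sites
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "site_id", "class_a", "id_a", "class_b", "id_b",
            "size", "min_dist_px", "min_dist_nm",
        ],
    )


def profiles_table(profiles) -> pd.DataFrame:
    rows = []
    for oid, p in sorted(profiles.items()):
        partners = sorted(p.partner_counts)
        rows.append(
            {
                "id": oid,
                "class": p.cls,
                "perimeter_px": p.perimeter_px,
                "total_contact_fraction": p.total_fraction,
                "contact_class": p.label,
                "partners": ";".join(partners),
                "partner_fractions": ";".join(
                    f"{c}:{p.partner_fractions[c]:.6g}" for c in partners
                ),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "id", "class", "perimeter_px", "total_contact_fraction",
            "contact_class", "partners", "partner_fractions",
        ],
    )


def run_pipeline_arrays(
    stack: MaskStack,
    ratio: RatioImage | None,
    config: PipelineConfig,
    out_dir: str | Path,
) -> dict[str, object]:
    """Run preprocess -> quantify -> contacts -> network -> CSR on arrays.

    Writes the full CSV output set under ``out_dir`` and returns the
    in-memory results.  When ``ratio`` is None the enrichment outputs are
    skipped with a logged notice and every geometric stage still runs.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    pp = PreprocessConfig(size_thresholds=dict(config.size_thresholds))
    resolved, objects = preprocess_stack(stack, pp)
    objtab = object_table(objects)
    composition(resolved).to_csv(out_dir / "composition.csv", index=False)

    enrich = None
    mean_by_id: dict[int, float] = {}
    if ratio is not None:
        conditioned = condition_ratio(ratio)
        enrich = enrichment_summary(objects, resolved, conditioned)
        enrich.to_csv(out_dir / "enrichment.csv", index=False)
        obj_rows = enrich[enrich["scope"] == "object"]
        mean_by_id = dict(zip(obj_rows["id"].astype(int), obj_rows["mean_ratio"]))
        objtab = objtab.assign(mean_ratio=objtab["id"].map(mean_by_id))
    else:
        log.warning("no ratio image configured; skipping enrichment outputs")
    objtab.to_csv(out_dir / "objects.csv", index=False)

    spec = DistanceSpec(m=config.contact_m, pixel_size_nm=config.pixel_size_nm)
    sites = find_contacts(objects, spec)
    sites_table(sites, config.pixel_size_nm).to_csv(out_dir / "contact_sites.csv", index=False)
    profiles = contact_profiles(objects, sites)
    profiles_table(profiles).to_csv(out_dir / "contact_profiles.csv", index=False)
    if mean_by_id:
        enrichment_by_contact_class(profiles, mean_by_id).to_csv(
            out_dir / "enrichment_by_contact_class.csv", index=False
        )

    # centroid network over organelle nodes (nucleus is not a node)
    nodes = objtab[objtab["class"] != "nucleus"][
        ["id", "class", "centroid_x_nm", "centroid_y_nm"]
    ].rename(columns={"centroid_x_nm": "x_nm", "centroid_y_nm": "y_nm"})
    results: dict[str, object] = {
        "stack": resolved,
        "objects": objects,
        "object_table": objtab,
        "sites": sites,
        "profiles": profiles,
        "enrichment": enrich,
    }
    if len(nodes) >= 1:
        net = build_network(nodes, radius_nm=config.radius_nm)
        comm = communities(net)
        comm.to_csv(out_dir / "communities.csv", index=False)
        fnp = first_neighbor_proportions(net)
        fnp.to_csv(out_dir / "first_neighbor_proportions.csv")
        results["network"] = net
        results["connectivity_fraction"] = connectivity_fraction(net)
        edges = pd.DataFrame(sorted(net.graph.edges), columns=["id_a", "id_b"])
        edges.to_csv(out_dir / "network_edges.csv", index=False)

        csr_rows = []
        for cls, grp in nodes.groupby("class"):
            pts = grp[["x_nm", "y_nm"]].to_numpy()
            if len(pts) < 3:
                continue
            res = nn_csr_test(pts, n_sims=config.csr_n_sims, seed=config.seed)
            csr_rows.append(
                {
                    "class": cls,
                    "n": res.n,
                    "area_nm2": res.area_nm2,
                    "observed_mean_nn_nm": res.observed_mean_nn,
                    "expected_mean_nn_nm": res.expected_mean_nn,
                    "R": res.R,
                    "z": res.z,
                    "n_sims": res.n_sims,
                }
            )
        csr_df = pd.DataFrame(
            csr_rows,
            columns=[
                "class", "n", "area_nm2", "observed_mean_nn_nm",
                "expected_mean_nn_nm", "R", "z", "n_sims",
            ],
        )
        csr_df.to_csv(out_dir / "csr.csv", index=False)
        results["csr"] = csr_df

    run_log = {
        "package": "orgspat",
        "version": _pkg_version,
        "seed": config.seed,
        "config": dataclasses.asdict(config),
        "n_objects": int(objects.n_objects),
        "n_contact_sites": len(sites),
    }
    with open(out_dir / "run_log.json", "w") as fh:
        json.dump(run_log, fh, indent=2, sort_keys=True)
    return results


def run_pipeline(config: PipelineConfig) -> dict[str, object]:
    """Load configured inputs and run the full per-cell pipeline."""
    stack = load_mask_stack(config)
    ratio = None
    if config.ratio_path is not None:
        ratio = read_ratio(config.ratio_path, config.pixel_size_nm)
        if ratio.shape != stack.shape:
            raise ValueError(
                f"ratio image shape {ratio.shape} does not match masks {stack.shape}"
            )
    return run_pipeline_arrays(stack, ratio, config, config.out_dir)
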