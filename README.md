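# orgspat

Spatial analysis of correlated electron-microscopy and stable-isotope
imaging of single cells.

Correlated SEM + multi-isotope imaging mass spectrometry (MIMS-EM) yields,
for one cell, a set of per-organelle segmentation masks on a 5 nm pixel
grid and a registered, scaled ¹³C/¹²C ratio image whose natural-abundance
(terrestrial) background sits at the scaled value 102. `orgspat` turns
those inputs into quantitative per-cell readouts:

- **Preprocessing** — hole filling, ER smoothing (4× erosion with a 3×3
  square), LD dilation (2× with a 3×3 diamond), overlap resolution by a
  fixed class priority (nucleus > mitochondria > ER > glycogen > LD, all
  confined to the cell outline), 8-connected component labeling, and
  per-class size exclusion (ER/glycogen ≥ 500 px, mitochondria/LD ≥ 5000 px).
- **Isotope enrichment** — floor at the 102 background, 17 px mean filter,
  then arithmetic-mean ¹³C/¹²C per object, class and cell.
- **Morphometry** — perimeter *pixel counts* P (a pixel with ≥ 1 of its 8
  neighbours outside the object), centroids, cell composition fractions,
  and the circularity score

  ```
  score = 4πA / P² · (1 − 0.5 r)²,   r = P/(2π) + 0.5
  ```

  applied verbatim (no renormalisation), plus a rank-ordered exponential
  fit `v_k = a·exp(b·k)` for particle volume distributions.
- **Contact sites** — a raster scan over perimeter pixels with a
  (2m+1)×(2m+1) region of interest detects perimeter pixels of other
  objects within Euclidean distance m (default 2 px = 10 nm); contacting
  pixels are grouped into discrete sites, single-pixel noise sites are
  dropped, and objects are classified by their closest interacting partner
  (e.g. `Mito-ER`, `isolated`).
- **Interaction networks** — organelle centroids become nodes of a radius
  graph (edges ≤ 500 nm); connected components are communities size-classed
  as isolated / 1to3 / 4to10 / 10+, with connectivity and first-neighbour
  proportions per class.
- **Spatial randomness** — the Clark–Evans ratio `R = observed mean NN /
  (0.5/√(n/area))` over the axis-aligned bounding box, with a z-score from
  1000 Monte-Carlo CSR patterns in the same box; z < −2 flags clustering,
  z > 2 dispersion.
- **Synthetic scenes** — a seeded generator builds annotated cells
  (elliptical mitochondria, curvilinear ER ribbons, granular glycogen
  depots, LD discs inside a convex cell), plants contacts at exact pixel
  gaps, renders ratio images with known offsets, and produces CSR /
  clustered / dispersed / grid point patterns — so every stage is testable
  with exact ground truth. Pixel precision / recall / F-score benchmarking
  of predicted masks is included.

## Worked example

```python
from orgspat import (SceneConfig, generate_scene, preprocess_stack,
                     PreprocessConfig, find_contacts, DistanceSpec)

scene = generate_scene(SceneConfig(
    seed=3, contact_plan=[("mitochondria", "er", 1), ("mitochondria", "ld", 0)]))
_, objects = preprocess_stack(
    scene.mask_stack, PreprocessConfig(er_erosions=0, ld_dilations=0))
for s in find_contacts(objects, DistanceSpec(m=2)):
    print(s.class_a, s.class_b, s.size, s.min_dist_px)
```

prints

```
mitochondria er 114 2.0
mitochondria ld 152 1.0
```

— the planted mitochondrion–ER pair at a 1 px gap is found as one contact
site of 114 contacting perimeter pixels with a minimum pixel distance of
2 px (10 nm), and the touching mitochondrion–LD pair as a 152-pixel site at
1 px (5 nm). The `examples/` directory has one short script per
capability (scene generation, enrichment, contacts, networks + CSR,
benchmarking + volume fits); each prints its numbers with a note on what
they mean.

A thin CLI wraps the same library for shell use:

```bash
orgspat generate --seed 1 --out scene/
orgspat run --config cell.yaml        # preprocess → quantify → contacts → network → CSR
```

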