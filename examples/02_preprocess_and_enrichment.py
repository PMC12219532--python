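"""Preprocess masks and quantify isotope enrichment per organelle class.

Runs the standard mask pipeline (hole filling, ER erosion, LD dilation,
overlap resolution, labeling, size exclusion), conditions the ratio image
(floor at 102, 17 px mean filter) and prints per-class mean ratios.
"""

from orgspat import (
    PreprocessConfig,
    SceneConfig,
    enrichment_summary,
    generate_scene,
    preprocess_stack,
)
from orgspat.isotope import condition_ratio

config = SceneConfig(seed=7)
scene = generate_scene(config)

resolved, objects = preprocess_stack(scene.mask_stack, PreprocessConfig())
conditioned = condition_ratio(scene.ratio_image)
table = enrichment_summary(objects, resolved, conditioned)

print(f"{objects.n_objects} labeled objects after size exclusion")
print(table[table.scope == "class"].to_string(index=False))
# mean_ratio is the arithmetic mean of conditioned 13C/12C pixels per class;
# values above 102 indicate tracer-derived carbon. The planted offsets are
# (nucleus 15, mito 30, ER 20, glycogen 60, LD 10); smoothing attenuates
# thin structures (ER) toward the background.
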