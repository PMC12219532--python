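"""Shared constants and analysis defaults.

All physical defaults describe SEM imaging at 5 nm/pixel with a registered,
scaled 13C/12C ratio image whose natural-abundance (terrestrial) background
sits at the scaled value 102.
"""

#: Organelle classes in the priority order used to resolve mask overlaps:
#: a contested pixel is kept by the earliest class in this order.
ORGANELLE_CLASSES: tuple[str, ...] = (
    "nucleus",
    "mitochondria",
    "er",
    "glycogen",
    "ld",
)

#: Short display names used in contact-class labels such as ``Mito-ER``.
CLASS_SHORT_NAMES: dict[str, str] = {
    "nucleus": "Nuc",
    "mitochondria": "Mito",
    "er": "ER",
    "glycogen": "Gly",
    "ld": "LD",
}

#: Scaled 13C/12C ratio of the terrestrial (natural-abundance) background.
#: Ratio pixels below this value are measurement noise and are floored to it.
BACKGROUND_RATIO: float = 102.0

#: SEM pixel pitch in nanometers.
DEFAULT_PIXEL_SIZE_NM: float = 5.0

#: Minimum object sizes in pixels; connected components strictly smaller than
#: the class threshold are discarded as segmentation false positives.
SIZE_THRESHOLDS_PX: dict[str, int] = {
    "er": 500,
    "mitochondria": 5000,
    "glycogen": 500,
    "ld": 5000,
}

#: Side of the square mean filter applied to ratio images (17 px = 85 nm
#: at 5 nm/px, matching the ~80 nm lateral resolution of the ion images).
RATIO_MEAN_FILTER_PX: int = 17

#: Contact-site search radius in pixels (2 px = 10 nm at 5 nm/px).
DEFAULT_CONTACT_RADIUS_PX: int = 2

#: Centroid-network edge radius in nanometers.
DEFAULT_NETWORK_RADIUS_NM: float = 500.0

#: Monte-Carlo replicates for the nearest-neighbour randomness test.
DEFAULT_CSR_N_SIMS: int = 1000

#: Confidence threshold applied to float-valued probability maps when they
#: are binarized at load time.
DEFAULT_PROBABILITY_THRESHOLD: float = 0.90

#: Tie-break priority between partner classes whose minimum contact
#: distances are equal (after the larger-contact-count rule).
PARTNER_TIEBREAK_ORDER: tuple[str, ...] = (
    "er",
    "ld",
    "glycogen",
    "mitochondria",
    "nucleus",
)
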