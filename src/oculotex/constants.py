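"""Naming conventions shared by the whole pipeline.

Layers are ordered inner (vitreous side) to outer; quadrants are named in the
orientation-standardised frame, i.e. after left-eye images have been flipped
so that the temporal side is the low-column side for every eye.
"""

#: Neuroretinal layers, inner to outer.
LAYERS = ("RNFL", "GCL", "IPL", "INL", "OPL", "ONL")

#: Retinal quadrants of the en-face block grid (post-flip frame):
#: Q1 temporal-superior, Q2 nasal-superior, Q3 temporal-inferior,
#: Q4 nasal-inferior.
QUADRANTS = ("Q1", "Q2", "Q3", "Q4")

#: Eye labels: OD = right eye, OS = left eye.
EYES = ("OD", "OS")

SEXES = ("female", "male")

#: The 21 grey-level co-occurrence matrix texture features, canonical order.
FEATURES = (
    "Autocorrelation",
    "Cluster Prominence",
    "Cluster Shade",
    "Contrast",
    "Correlation",
    "Difference Entropy",
    "Difference Variance",
    "Dissimilarity",
    "Energy",
    "Entropy",
    "Homogeneity",
    "IMC1",
    "IMC2",
    "Inverse Difference",
    "IDMN",
    "IDN",
    "Maximum Probability",
    "Sum Average",
    "Sum Entropy",
    "SSV",
    "Sum Variance",
)


def feature_id(layer: str, quadrant: str, feature: str) -> str:
    """Canonical string key for one (layer, quadrant, feature) cell."""
    return f"{layer}/{quadrant}/{feature}"


def feature_id_sort_key(fid: str):
    layer, quadrant, feature = fid.split("/", 2)
    return (LAYERS.index(layer), QUADRANTS.index(quadrant), FEATURES.index(feature))
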