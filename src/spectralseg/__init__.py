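"""spectralseg: brain-tissue segmentation from multi-energy CT.

Segments white matter, grey matter and cerebrospinal fluid from co-registered
virtual monoenergetic CT volumes (50/70/120 keV) with U-Net / U-Net++ variants
that exploit the spectral dimension, trains them with a class-masked Dice
loss under fold cross-validation, ensembles the fold models at inference, and
evaluates with DSC, 95th-percentile Hausdorff distance and volume-difference
statistics.  A synthetic head-phantom cohort generator stands in for patient
data.
"""

__version__ = "0.1.0"

from .core import (  # noqa: F401
    BACKGROUND,
    CSF,
    GM,
    N_CLASSES,
    TISSUE_CLASSES,
    VMI_LEVELS,
    WM,
    CLASS_NAMES,
    SpectralStack,
    TissueLabelMap,
)

__all__ = [
    "BACKGROUND",
    "CSF",
    "GM",
    "N_CLASSES",
    "TISSUE_CLASSES",
    "VMI_LEVELS",
    "WM",
    "CLASS_NAMES",
    "SpectralStack",
    "TissueLabelMap",
    "SpectralSegmenter",
    "__version__",
]


def __getattr__(name):
    # lazy import to keep `import spectralseg` light
    if name == "SpectralSegmenter":
        from .estimator import SpectralSegmenter
        return SpectralSegmenter
    raise AttributeError(f"module {__name__!r} has no attribute {name!r}")
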