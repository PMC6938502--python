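"""Lipid-corrected protein unmixing.

The protein channel (2930 cm^-1) picks up signal from lipids as well as
proteins, because the CH2 and CH3 stretch bands overlap.  Subtracting a
scaled copy of the lipid channel isolates protein-specific contrast:

    protein_corrected = protein - alpha * lipid

``alpha`` is the lipid bleed-through coefficient.  On channels normalized to
a shared intensity scale it is close to 1; :func:`calibrate_alpha` estimates
it directly from pixels known to be pure lipid (e.g. macrophage cytoplasm),
where a correct alpha drives the corrected protein signal to zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import CalibrationError
from .image_model import Mosaic


@dataclass
class UnmixParams:
    alpha: float = 1.0
    clip_negative: bool = True

    def __post_init__(self):
        if not np.isfinite(self.alpha) or self.alpha < 0:
            raise ValueError(f"alpha must be finite and >= 0, got {self.alpha}")


@dataclass
class ChemicalMap:
    """Paired lipid and lipid-corrected protein images on the mosaic grid."""

    lipid: np.ndarray
    protein_corrected: np.ndarray
    pixel_size: float
    params: UnmixParams = field(default_factory=UnmixParams)

    def __post_init__(self):
        self.lipid = np.asarray(self.lipid, dtype=float)
        self.protein_corrected = np.asarray(self.protein_corrected, dtype=float)
        if self.lipid.shape != self.protein_corrected.shape:
            raise ValueError(
                f"lipid {self.lipid.shape} and protein_corrected "
                f"{self.protein_corrected.shape} must share dimensions"
            )
        if self.params.clip_negative and self.protein_corrected.min() < 0:
            raise ValueError("protein_corrected is negative despite clip_negative")

    @property
    def shape(self) -> tuple[int, int]:
        return self.lipid.shape


def lipid_correct(mosaic: Mosaic, params: UnmixParams | None = None) -> ChemicalMap:
    """Subtract the scaled lipid channel from the protein channel.

    The lipid image passes through unchanged; the corrected protein image is
    ``protein - alpha * lipid``, clipped at zero when ``clip_negative`` is
    set (negative abundance is unphysical).
    """
    if params is None:
        params = UnmixParams()
    if not np.isfinite(mosaic.pixels).all():
        raise ValueError("mosaic contains non-finite values")
    corrected = mosaic.protein - params.alpha * mosaic.lipid
    if params.clip_negative:
        corrected = np.clip(corrected, 0.0, None)
    return ChemicalMap(
        lipid=mosaic.lipid.copy(),
        protein_corrected=corrected,
        pixel_size=mosaic.pixel_size,
        params=params,
    )


def calibrate_alpha(
    mosaic: Mosaic,
    lipid_roi: np.ndarray,
    clip_negative: bool = True,
) -> UnmixParams:
    """Estimate the bleed-through coefficient from a pure-lipid region.

    Over the ROI, ``alpha`` is the median of the per-pixel protein/lipid
    ratio, which makes the post-correction corrected-protein median inside
    the ROI (approximately) zero.  Zero-lipid pixels cannot constrain the
    ratio and are excluded.

    Parameters
    ----------
    mosaic
        Two-channel mosaic in canonical order.
    lipid_roi
        Boolean (or 0/1) mask of pixels asserted to be pure lipid, matching
        the mosaic dimensions.

    Raises
    ------
    CalibrationError
        If the ROI is empty or contains no pixel with positive lipid signal.
    """
    roi = np.asarray(lipid_roi).astype(bool)
    if roi.shape != mosaic.shape:
        raise ValueError(f"ROI shape {roi.shape} does not match mosaic {mosaic.shape}")
    if not roi.any():
        raise CalibrationError("lipid ROI is empty")
    lipid = mosaic.lipid[roi]
    protein = mosaic.protein[roi]
    usable = lipid > 0
    if not usable.any():
        raise CalibrationError("every ROI pixel has zero lipid signal; cannot calibrate")
    alpha = float(np.median(protein[usable] / lipid[usable]))
    return UnmixParams(alpha=alpha, clip_negative=clip_negative)
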