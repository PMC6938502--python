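"""Color renderings of a two-channel chemical map.

Two display schemes are provided:

* **Pseudo-H&E** — a Beer-Lambert-style mapping in which the corrected
  protein image attenuates light like hematoxylin (purple; nuclei) and the
  lipid image like eosin (pink; cytoplasm and stroma):

      RGB = 255 * exp(-(P_hat * OD_h + L_hat * OD_e))

  with P_hat, L_hat the images scaled by a high percentile to ~[0, 1] and
  OD_h, OD_e per-stain optical-density vectors.  Zero signal renders white,
  and every channel darkens monotonically with either input, matching how a
  real absorptive stain behaves.

* **Two-color** — lipid mapped linearly to green and protein to magenta
  (red + blue), a direct linear remapping of concentration to brightness.
  This view preserves the chemistry that pseudo-H&E collapses: a
  collagen-rich, lipid-poor matrix is unmistakably magenta.

``nuclear_contrast_score`` quantifies how well nuclei stand out against
cytoplasm in a rendering; protein-rich matrices (chondroid tissue) score
low because there is little lipid contrast around the nuclei.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .chemistry import ChemicalMap
from .image_model import RGBRendering

#: Conventional H&E absorbance directions (R, G, B optical densities).
DEFAULT_HEMATOXYLIN_OD = (0.65, 0.70, 0.29)
DEFAULT_EOSIN_OD = (0.07, 0.99, 0.11)


@dataclass
class StainVectors:
    """Per-stain RGB optical-density vectors for pseudo-H&E."""

    hematoxylin_od: tuple[float, float, float] = DEFAULT_HEMATOXYLIN_OD
    eosin_od: tuple[float, float, float] = DEFAULT_EOSIN_OD
    intensity_percentile: float = 99.0

    def __post_init__(self):
        for name, vec in (("hematoxylin_od", self.hematoxylin_od), ("eosin_od", self.eosin_od)):
            vec = tuple(float(v) for v in vec)
            if len(vec) != 3 or any(v < 0 for v in vec):
                raise ValueError(f"{name} must be a 3-vector of non-negative ODs, got {vec}")
            if not any(v > 0 for v in vec):
                raise ValueError(f"{name} must have at least one positive component")
            setattr(self, name, vec)
        if not (0 < self.intensity_percentile <= 100):
            raise ValueError("intensity_percentile must be in (0, 100]")


@dataclass
class RenderConfig:
    mode: str = "pseudo_he"
    stains: StainVectors = field(default_factory=StainVectors)
    low_percentile: float = 1.0
    high_percentile: float = 99.0
    gamma: float = 1.0

    def __post_init__(self):
        if self.mode not in ("pseudo_he", "two_color"):
            raise ValueError(f"mode must be 'pseudo_he' or 'two_color', got {self.mode!r}")
        if not (0 <= self.low_percentile < self.high_percentile <= 100):
            raise ValueError(
                f"need 0 <= low_percentile < high_percentile <= 100, "
                f"got ({self.low_percentile}, {self.high_percentile})"
            )
        if self.gamma <= 0:
            raise ValueError("gamma must be positive")


def _percentile_scale(img: np.ndarray, pct: float) -> float:
    """Scale factor from the given percentile of tissue (nonzero) pixels."""
    nz = img[img > 0]
    if nz.size == 0:
        return 0.0
    return float(np.percentile(nz, pct))


def render_pseudo_he(cmap: ChemicalMap, config: RenderConfig | None = None) -> RGBRendering:
    """Render a chemical map as a virtual H&E image.

    Corrected protein takes the hematoxylin color, lipid the eosin color.
    A map with no signal at all renders entirely white (with a warning).
    """
    if config is None:
        config = RenderConfig(mode="pseudo_he")
    if config.mode != "pseudo_he":
        raise ValueError(f"config.mode must be 'pseudo_he', got {config.mode!r}")
    st = config.stains
    scales = []
    for img in (cmap.protein_corrected, cmap.lipid):
        s = _percentile_scale(img, st.intensity_percentile)
        scales.append(s)
    if scales[0] == 0 and scales[1] == 0:
        warnings.warn("chemical map has no signal; rendering is uniformly white", stacklevel=2)
    p_hat = cmap.protein_corrected / scales[0] if scales[0] > 0 else np.zeros(cmap.shape)
    l_hat = cmap.lipid / scales[1] if scales[1] > 0 else np.zeros(cmap.shape)
    if config.gamma != 1.0:
        p_hat = np.power(p_hat, config.gamma)
        l_hat = np.power(l_hat, config.gamma)
    od = (
        p_hat[..., None] * np.asarray(st.hematoxylin_od)
        + l_hat[..., None] * np.asarray(st.eosin_od)
    )
    rgb = np.rint(255.0 * np.exp(-od)).astype(np.uint8)
    return RGBRendering(pixels=rgb, mode="pseudo_he", pixel_size=cmap.pixel_size)


def _linear_rescale(img: np.ndarray, low_pct: float, high_pct: float) -> np.ndarray:
    lo = float(np.percentile(img, low_pct))
    hi = float(np.percentile(img, high_pct))
    if hi <= lo:
        warnings.warn(
            "degenerate percentile range; channel rendered constant", stacklevel=3
        )
        return np.zeros_like(img, dtype=float)
    return np.clip((img - lo) / (hi - lo), 0.0, 1.0)


def render_two_color(cmap: ChemicalMap, config: RenderConfig | None = None) -> RGBRendering:
    """Render lipid as green and protein as magenta with linear intensity mapping."""
    if config is None:
        config = RenderConfig(mode="two_color")
    if config.mode != "two_color":
        raise ValueError(f"config.mode must be 'two_color', got {config.mode!r}")
    lipid = _linear_rescale(cmap.lipid, config.low_percentile, config.high_percentile)
    protein = _linear_rescale(cmap.protein_corrected, config.low_percentile, config.high_percentile)
    if config.gamma != 1.0:
        lipid = np.power(lipid, config.gamma)
        protein = np.power(protein, config.gamma)
    rgb = np.empty(cmap.shape + (3,), dtype=np.uint8)
    rgb[..., 0] = np.rint(255.0 * protein)
    rgb[..., 1] = np.rint(255.0 * lipid)
    rgb[..., 2] = np.rint(255.0 * protein)
    return RGBRendering(pixels=rgb, mode="two_color", pixel_size=cmap.pixel_size)


def nuclear_contrast_score(
    rendering: RGBRendering,
    nuclei_mask: np.ndarray,
    cytoplasm_mask: np.ndarray,
) -> float:
    """Luminance separation between cytoplasm and nuclei, in [-1, 1].

    Positive when nuclei are darker than their surrounding cytoplasm, as in
    a well-stained H&E section; near zero when the rendering offers no
    nuclear contrast (the failure mode of lipid-poor chondroid tissue).
    """
    nuc = np.asarray(nuclei_mask).astype(bool)
    cyt = np.asarray(cytoplasm_mask).astype(bool)
    if not nuc.any() or not cyt.any():
        raise ValueError("both masks must be nonempty")
    if (nuc & cyt).any():
        raise ValueError("nuclei and cytoplasm masks must be disjoint")
    # Rec. 709 luma
    lum = rendering.pixels @ np.array([0.2126, 0.7152, 0.0722])
    return float((lum[cyt].mean() - lum[nuc].mean()) / 255.0)
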