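"""Synthetic two-channel SRS tissue phantoms with pixel-level ground truth.

The generator emulates the cytoarchitectural motifs seen in skull-base
tumors imaged by two-channel SRS, at the level of lipid/protein contrast
rather than photorealism:

* nuclei: protein-rich, lipid-poor disks placed by a hard-core point
  process (no two nuclei closer than 1.5x the mean radius);
* cytoplasm: annuli around each nucleus with tunable lipid/protein means;
* macrophages: lipid-laden foam cells replacing a fraction of cells;
* collagen: protein-only curvilinear fibers, either wrapped *around*
  lobules of cells (meningioma-like) or threaded *between* individual
  cells (schwannoma-like);
* chondroid matrix: a protein-rich, lipid-poor background (chondrosarcoma);
* psammoma bodies: concentric calcified whorls, low signal in both
  channels.

Per-pixel intensities are drawn with a shot-noise term (scaled Poisson
counts at ``photon_scale`` counts per intensity unit) plus additive
zero-mean Gaussian read noise, the standard two-term model for a lock-in
detected laser-scanning microscope.  Optical vignetting is tile-relative:
every cut tile sees the same radial gain profile, which is what makes
flat-field estimation from the tile stack well-posed.

Everything is deterministic given ``seed`` (NumPy PCG64 generator).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.cluster.vq import kmeans2
from scipy.spatial import cKDTree
from skimage.draw import disk, line

from .errors import PlacementError
from .image_model import ManifestEntry, Mosaic, SRSTile, TileManifest

# label-image codes; later entries overwrite earlier when painting
_MATRIX, _COLLAGEN, _CYTO, _MACRO, _NUC, _PSAMMOMA = range(6)

_ARCHETYPES = ("meningioma", "schwannoma", "chondrosarcoma", "generic")


@dataclass
class PhantomSpec:
    """Parameters of one synthetic specimen.

    Intensity means are in arbitrary acquisition units (the same scale for
    both channels); geometric parameters are physical (um, nuclei/mm^2) and
    converted to pixels via ``pixel_size``.
    """

    archetype: str = "generic"
    image_size: int = 512
    pixel_size: float = 1.0          # um per pixel
    nuclear_density: float = 1500.0  # nuclei per mm^2
    nuclear_radius_um: tuple[float, float] = (3.0, 0.5)  # mean, sd
    cytoplasm_lipid: float = 6.0
    cytoplasm_protein: float = 4.0
    matrix_protein: float = 2.0
    matrix_lipid: float = 1.0
    nucleus_protein: float = 10.0
    nucleus_lipid: float = 0.5
    collagen_protein: float = 8.0
    collagen_lipid: float = 0.3
    macrophage_lipid: float = 12.0
    macrophage_protein: float = 3.0
    macrophage_fraction: float = 0.0
    collagen_topology: str = "none"  # "around_lobules" | "between_cells" | "none"
    psammoma_count: int = 0
    psammoma_protein: float = 0.8
    psammoma_lipid: float = 0.4
    illumination: str = "uniform"    # "uniform" | "radial"
    vignette_strength: float = 0.3
    noise_sigma_read: float = 0.1
    photon_scale: float | None = 200.0  # counts per intensity unit; None = no shot noise
    seed: int = 0

    def __post_init__(self):
        if self.archetype not in _ARCHETYPES:
            raise ValueError(f"unknown archetype {self.archetype!r}")
        if self.collagen_topology not in ("around_lobules", "between_cells", "none"):
            raise ValueError(f"unknown collagen_topology {self.collagen_topology!r}")
        if self.illumination not in ("uniform", "radial"):
            raise ValueError(f"unknown illumination {self.illumination!r}")
        if not (0 <= self.macrophage_fraction <= 1):
            raise ValueError("macrophage_fraction must be in [0, 1]")
        if not (0 <= self.vignette_strength < 1):
            raise ValueError("vignette_strength must be in [0, 1)")
        for name in ("cytoplasm_lipid", "cytoplasm_protein", "matrix_protein", "matrix_lipid",
                     "nucleus_protein", "nucleus_lipid", "collagen_protein", "collagen_lipid",
                     "macrophage_lipid", "macrophage_protein", "psammoma_protein",
                     "psammoma_lipid", "nuclear_density"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.psammoma_count < 0:
            raise ValueError("psammoma_count must be >= 0")
        # archetype consistency
        if self.archetype == "chondrosarcoma":
            if not (self.matrix_protein > self.cytoplasm_lipid):
                raise ValueError("chondrosarcoma requires matrix_protein > cytoplasm_lipid")
            if self.matrix_lipid > 0.05 * max(self.matrix_protein, 1.0):
                raise ValueError("chondrosarcoma requires near-zero matrix lipid")
        if self.archetype == "meningioma" and self.collagen_topology != "around_lobules":
            raise ValueError("meningioma phantoms carry collagen around lobules")
        if self.archetype == "schwannoma" and self.collagen_topology != "between_cells":
            raise ValueError("schwannoma phantoms carry collagen between cells")


def archetype_spec(archetype: str, **overrides) -> PhantomSpec:
    """Preset :class:`PhantomSpec` for a tumor archetype.

    The presets are ordinal — they encode who is lipid-richer than whom,
    collagen topology, and the presence of psammoma bodies or macrophages —
    not calibrated absolute intensities.
    """
    presets = {
        "generic": {},
        "meningioma": dict(
            collagen_topology="around_lobules",
            macrophage_fraction=0.08,
            psammoma_count=3,
            cytoplasm_lipid=6.0,
        ),
        "schwannoma": dict(
            collagen_topology="between_cells",
            cytoplasm_lipid=5.0,
            nuclear_density=1200.0,
        ),
        "chondrosarcoma": dict(
            collagen_topology="none",
            nuclear_density=600.0,
            cytoplasm_lipid=1.5,
            cytoplasm_protein=4.0,
            matrix_protein=8.0,
            matrix_lipid=0.0,
        ),
    }
    if archetype not in presets:
        raise ValueError(f"unknown archetype {archetype!r}")
    kwargs = dict(presets[archetype])
    kwargs.update(overrides)
    return PhantomSpec(archetype=archetype, **kwargs)


@dataclass
class GroundTruth:
    """Pixel-accurate labels for a generated phantom.

    Masks are mutually disjoint and, together with ``matrix_mask``, cover
    the image.  ``injected_gain`` is filled by :func:`tile_phantom` when the
    specimen is cut into vignetted tiles (it is tile-shaped, because the
    vignette is a property of the optics, not the specimen).
    """

    nuclei_mask: np.ndarray
    cytoplasm_mask: np.ndarray
    collagen_mask: np.ndarray
    macrophage_mask: np.ndarray
    matrix_mask: np.ndarray
    psammoma_mask: np.ndarray
    cell_centers: np.ndarray  # (n, 2) in um, (x, y)
    injected_gain: np.ndarray | None = None

    def __post_init__(self):
        masks = [self.nuclei_mask, self.cytoplasm_mask, self.collagen_mask,
                 self.macrophage_mask, self.matrix_mask, self.psammoma_mask]
        total = np.zeros(masks[0].shape, dtype=int)
        for m in masks:
            total += m.astype(int)
        if (total > 1).any():
            raise ValueError("ground-truth masks must be mutually disjoint")
        if (total == 0).any():
            raise ValueError("ground-truth masks must cover the image")


def _hardcore_centers(rng, H, W, n_target, min_sep, margin):
    """Dart-throwing hard-core point process on a [margin, size-margin] window."""
    if n_target == 0:
        return np.empty((0, 2))
    cell = max(min_sep, 1.0)
    grid: dict[tuple[int, int], list[int]] = {}
    pts: list[tuple[float, float]] = []
    budget = 300 * n_target
    lo_y, hi_y = margin, H - margin
    lo_x, hi_x = margin, W - margin
    if hi_y <= lo_y or hi_x <= lo_x:
        raise PlacementError("image too small for the requested nuclear radius", 0.0)
    for _ in range(budget):
        if len(pts) >= n_target:
            break
        y = rng.uniform(lo_y, hi_y)
        x = rng.uniform(lo_x, hi_x)
        gy, gx = int(y // cell), int(x // cell)
        ok = True
        for dy in (-1, 0, 1):
            for dx in (-1, 0, 1):
                for idx in grid.get((gy + dy, gx + dx), ()):
                    py, px = pts[idx]
                    if (py - y) ** 2 + (px - x) ** 2 < min_sep ** 2:
                        ok = False
                        break
                if not ok:
                    break
            if not ok:
                break
        if ok:
            grid.setdefault((gy, gx), []).append(len(pts))
            pts.append((y, x))
    if len(pts) < n_target:
        raise PlacementError(
            f"hard-core placement reached only {len(pts)} of {n_target} nuclei",
            achieved_density=len(pts),
        )
    return np.array(pts)


def _paint_collagen(label, centers, topology, mean_r_px, rng):
    H, W = label.shape
    if topology == "none" or len(centers) == 0:
        return
    if topology == "between_cells":
        # thread a fiber from each cell to its nearest neighbours
        tree = cKDTree(centers)
        k = min(3, len(centers))
        _, idx = tree.query(centers, k=k)
        drawn = set()
        for i in range(len(centers)):
            for j in np.atleast_1d(idx[i])[1:]:
                key = (min(i, int(j)), max(i, int(j)))
                if key in drawn:
                    continue
                drawn.add(key)
                r0, c0 = centers[i]
                r1, c1 = centers[int(j)]
                rr, cc = line(int(r0), int(c0), int(r1), int(c1))
                keep = (rr >= 0) & (rr < H) & (cc >= 0) & (cc < W)
                label[rr[keep], cc[keep]] = _COLLAGEN
                # thicken to ~2 px
                rr2 = np.clip(rr[keep] + 1, 0, H - 1)
                label[rr2, cc[keep]] = _COLLAGEN
    else:  # around_lobules
        k = max(1, len(centers) // 20)
        seed = int(rng.integers(0, 2**31 - 1))
        _, assignment = kmeans2(centers.astype(float), k, minit="++", seed=seed)
        yy, xx = np.mgrid[0:H, 0:W]
        for lob in range(k):
            members = centers[assignment == lob]
            if len(members) == 0:
                continue
            cy, cx = members.mean(axis=0)
            dmax = np.sqrt(((members - (cy, cx)) ** 2).sum(axis=1)).max()
            radius = dmax + 3.0 * mean_r_px + 3.0
            dist = np.sqrt((yy - cy) ** 2 + (xx - cx) ** 2)
            theta = np.arctan2(yy - cy, xx - cx)
            phase = rng.uniform(0, 2 * np.pi)
            wobble = 1.0 + 0.06 * np.sin(3 * theta + phase)
            ring = np.abs(dist - radius * wobble) < 1.5
            label[ring] = _COLLAGEN


def generate_phantom(spec: PhantomSpec) -> tuple[Mosaic, GroundTruth]:
    """Generate one phantom specimen and its ground truth.

    Deterministic given ``spec.seed``.  Raises :class:`PlacementError` when
    the requested nuclear density cannot be reached by hard-core placement.
    """
    rng = np.random.default_rng(spec.seed)
    H = W = spec.image_size
    psz = spec.pixel_size
    mean_r_px = spec.nuclear_radius_um[0] / psz
    sd_r_px = spec.nuclear_radius_um[1] / psz
    area_mm2 = (H * psz / 1000.0) * (W * psz / 1000.0)
    n_target = int(round(spec.nuclear_density * area_mm2))
    min_sep = 1.5 * mean_r_px

    label = np.full((H, W), _MATRIX, dtype=np.uint8)
    centers = _hardcore_centers(rng, H, W, n_target, min_sep,
                                margin=max(2.5 * mean_r_px, 1.0))
    radii = np.clip(rng.normal(mean_r_px, sd_r_px, len(centers)), 1.0, None)

    n_macro = int(round(spec.macrophage_fraction * len(centers)))
    macro_idx = set(rng.choice(len(centers), size=n_macro, replace=False).tolist()) \
        if n_macro else set()

    # cytoplasm first, then collagen over it, then cells, so fibers run
    # between cells but never through a nucleus
    for i, ((cy, cx), r) in enumerate(zip(centers, radii)):
        if i in macro_idx:
            continue
        rr, cc = disk((cy, cx), 2.2 * r, shape=(H, W))
        label[rr, cc] = _CYTO
    _paint_collagen(label, centers, spec.collagen_topology, mean_r_px, rng)
    for i, ((cy, cx), r) in enumerate(zip(centers, radii)):
        if i in macro_idx:
            rr, cc = disk((cy, cx), 2.0 * r, shape=(H, W))
            label[rr, cc] = _MACRO
        else:
            rr, cc = disk((cy, cx), r, shape=(H, W))
            label[rr, cc] = _NUC

    # psammoma bodies: concentric calcified whorls, overwrite everything
    psammoma_mod = np.ones((H, W))
    for _ in range(spec.psammoma_count):
        pr = 5.0 * mean_r_px
        cy = rng.uniform(pr, H - pr)
        cx = rng.uniform(pr, W - pr)
        rr, cc = disk((cy, cx), pr, shape=(H, W))
        label[rr, cc] = _PSAMMOMA
        d = np.sqrt((rr - cy) ** 2 + (cc - cx) ** 2)
        ring_parity = (d // max(mean_r_px, 1.0)).astype(int) % 2
        psammoma_mod[rr, cc] = np.where(ring_parity == 0, 1.0, 0.4)

    lip_means = np.array([spec.matrix_lipid, spec.collagen_lipid, spec.cytoplasm_lipid,
                          spec.macrophage_lipid, spec.nucleus_lipid, spec.psammoma_lipid])
    pro_means = np.array([spec.matrix_protein, spec.collagen_protein, spec.cytoplasm_protein,
                          spec.macrophage_protein, spec.nucleus_protein, spec.psammoma_protein])
    mean_img = np.stack([lip_means[label], pro_means[label]]) * psammoma_mod

    if spec.photon_scale is None or not math.isfinite(spec.photon_scale):
        signal = mean_img.copy()
    else:
        signal = rng.poisson(mean_img * spec.photon_scale) / spec.photon_scale
    if spec.noise_sigma_read > 0:
        signal = signal + rng.normal(0.0, spec.noise_sigma_read, signal.shape)
    signal = np.clip(signal, 0.0, None)

    mosaic = Mosaic(
        pixels=signal,
        pixel_size=psz,
        origin=(0.0, 0.0),
        provenance={"phantom": {
            "archetype": spec.archetype,
            "seed": spec.seed,
            "illumination": spec.illumination,
            "vignette_strength": spec.vignette_strength,
            "n_nuclei": len(centers),
        }},
    )
    truth = GroundTruth(
        nuclei_mask=label == _NUC,
        cytoplasm_mask=label == _CYTO,
        collagen_mask=label == _COLLAGEN,
        macrophage_mask=label == _MACRO,
        matrix_mask=label == _MATRIX,
        psammoma_mask=label == _PSAMMOMA,
        cell_centers=np.column_stack([centers[:, 1], centers[:, 0]]) * psz
        if len(centers) else np.empty((0, 2)),
    )
    return mosaic, truth


def radial_gain(shape: tuple[int, int], strength: float) -> np.ndarray:
    """Radially decaying vignette profile: 1 at the centre, 1-strength at the corners."""
    h, w = shape
    yy, xx = np.mgrid[0:h, 0:w]
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    r2 = ((yy - cy) / (h / 2.0)) ** 2 + ((xx - cx) / (w / 2.0)) ** 2
    return 1.0 - strength * r2 / 2.0


def tile_phantom(
    mosaic: Mosaic,
    truth: GroundTruth,
    tile_fov_um: float = 285.0,
    overlap_fraction: float = 0.10,
) -> tuple[TileManifest, list[SRSTile]]:
    """Cut a phantom mosaic into an overlapping tile grid as a microscope would.

    Tiles are cut with stride ``tile * (1 - overlap)``; a final tile is
    clamped to the image edge so the whole specimen is covered.  Stage
    positions are recorded exactly.  When the phantom was specified with
    radial illumination, every tile is multiplied by the same tile-relative
    vignette profile (fixed optics), and that profile is stored in
    ``truth.injected_gain``.
    """
    if not (0 <= overlap_fraction < 0.5):
        raise ValueError(f"overlap_fraction must be in [0, 0.5), got {overlap_fraction}")
    psz = mosaic.pixel_size
    side = int(round(tile_fov_um / psz))
    H, W = mosaic.shape
    if side > min(H, W):
        raise ValueError(f"tile side {side} px exceeds mosaic {mosaic.shape}")
    stride = max(int(round(side * (1.0 - overlap_fraction))), 1)

    def starts(size):
        s = list(range(0, size - side + 1, stride))
        if s[-1] != size - side:
            s.append(size - side)
        return s

    ys, xs = starts(H), starts(W)
    phantom_meta = mosaic.provenance.get("phantom", {})
    illum = phantom_meta.get("illumination", "uniform")
    gain = None
    if illum == "radial":
        gain = radial_gain((side, side), float(phantom_meta.get("vignette_strength", 0.3)))
        truth.injected_gain = gain

    fov = side * psz
    tiles, entries = [], []
    for r, y0 in enumerate(ys):
        for c, x0 in enumerate(xs):
            crop = mosaic.pixels[:, y0:y0 + side, x0:x0 + side].copy()
            if gain is not None:
                crop = crop * gain
            stage_x = mosaic.origin[0] + x0 * psz
            stage_y = mosaic.origin[1] + y0 * psz
            tiles.append(SRSTile(crop, r, c, stage_x, stage_y, psz, fov))
            entries.append(ManifestEntry(None, ("lipid", "protein"), r, c, stage_x, stage_y))
    manifest = TileManifest(entries, len(ys), len(xs), overlap_fraction)
    return manifest, tiles


def collagen_adjacency_fraction(truth: GroundTruth, spec: PhantomSpec) -> float:
    """Fraction of collagen pixels lying within one mean cell radius of a nucleus.

    The cell radius is the cytoplasm outer radius (2.2x the mean nuclear
    radius).  Collagen threaded between cells hugs the cells and scores
    high; collagen wrapped around lobules sits away from individual nuclei
    and scores near zero.  Returns NaN when the phantom has no collagen.
    """
    coll = np.argwhere(truth.collagen_mask)
    if len(coll) == 0 or len(truth.cell_centers) == 0:
        return float("nan")
    centers_px = truth.cell_centers[:, ::-1] / spec.pixel_size  # (y, x)
    tree = cKDTree(centers_px)
    d, _ = tree.query(coll)
    cell_radius = 2.2 * spec.nuclear_radius_um[0] / spec.pixel_size
    return float((d <= cell_radius).mean())
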