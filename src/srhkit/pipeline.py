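"""End-to-end processing chain: tiles -> flat-field -> mosaic -> chemistry -> colors.

The stage order is fixed: tiles are read, flat-field normalized, stitched,
lipid-corrected, then rendered in both color schemes.  Every run writes a
machine-readable summary (parameters, output checksums, per-stage timings)
so results can be audited and reruns compared; with a fixed configuration
the image outputs are byte-identical across runs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import __version__
from .chemistry import UnmixParams, lipid_correct
from .errors import ConfigError, SRHError
from .image_model import read_manifest, read_tile_stack, write_mosaic, write_rendering
from .preprocessing import StitchConfig, apply_flat_field, estimate_flat_field, stitch_tiles
from .rendering import RenderConfig, StainVectors, render_pseudo_he, render_two_color

log = logging.getLogger("srhkit.pipeline")


class StageError(SRHError):
    """A pipeline stage failed; carries the stage label."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    manifest: Path
    out_dir: Path
    smoothing_scale: float = 8.0
    flat_field: bool = True
    stitch: StitchConfig = field(default_factory=StitchConfig)
    unmix: UnmixParams = field(default_factory=UnmixParams)
    stains: StainVectors = field(default_factory=StainVectors)
    low_percentile: float = 1.0
    high_percentile: float = 99.0
    gamma: float = 1.0
    pixel_size_um: float | None = None
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self):
        self.manifest = Path(self.manifest)
        self.out_dir = Path(self.out_dir)

    def validate(self) -> None:
        if not self.manifest.exists():
            raise ConfigError(f"manifest does not exist: {self.manifest}")
        parent = self.out_dir if self.out_dir.exists() else self.out_dir.parent
        if not parent.exists():
            raise ConfigError(f"output directory is not creatable: {self.out_dir}")
        if self.smoothing_scale <= 0:
            raise ConfigError("smoothing_scale must be positive")
        # delegate range checks to the stage configs by re-instantiating them
        try:
            StitchConfig(**dataclasses.asdict(self.stitch))
            UnmixParams(**dataclasses.asdict(self.unmix))
            RenderConfig(mode="two_color", low_percentile=self.low_percentile,
                         high_percentile=self.high_percentile, gamma=self.gamma)
        except (ValueError, TypeError) as exc:
            raise ConfigError(str(exc)) from exc

    @classmethod
    def from_yaml(cls, path, **overrides) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        raw.update({k: v for k, v in overrides.items() if v is not None})
        try:
            stitch = StitchConfig(**raw.pop("stitch", {}))
            unmix = UnmixParams(**raw.pop("unmix", {}))
            stains = StainVectors(**raw.pop("stains", {}))
            render = raw.pop("render", {})
            return cls(
                manifest=raw.pop("manifest"),
                out_dir=raw.pop("out_dir"),
                stitch=stitch, unmix=unmix, stains=stains,
                low_percentile=render.get("low_percentile", 1.0),
                high_percentile=render.get("high_percentile", 99.0),
                gamma=render.get("gamma", 1.0),
                **raw,
            )
        except (KeyError, TypeError, ValueError) as exc:
            raise ConfigError(f"invalid pipeline configuration: {exc}") from exc


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the full chain and write outputs plus a JSON run summary.

    Returns the summary dict.  Raises :class:`ConfigError` before any
    computation if the configuration is invalid, and :class:`StageError`
    (labelled with the failing stage) otherwise; on failure the summary is
    still written with the partial outputs flagged.
    """
    config.validate()
    out = config.out_dir
    out.mkdir(parents=True, exist_ok=True)
    summary: dict = {
        "srhkit_version": __version__,
        "parameters": _params_dict(config),
        "stages": [],
        "outputs": {},
        "completed": False,
    }
    t_all = time.perf_counter()

    def stage(name):
        def deco(fn):
            def run(*args):
                t0 = time.perf_counter()
                try:
                    result = fn(*args)
                except Exception as exc:  # noqa: BLE001 - relabelled below
                    summary["stages"].append(
                        {"name": name, "seconds": time.perf_counter() - t0, "ok": False})
                    _write_summary(out, summary)
                    raise StageError(name, exc) from exc
                summary["stages"].append(
                    {"name": name, "seconds": time.perf_counter() - t0, "ok": True})
                log.info("stage %s done in %.2fs", name, summary["stages"][-1]["seconds"])
                return result
            return run
        return deco

    @stage("read_tiles")
    def _read():
        manifest = read_manifest(config.manifest)
        tiles = read_tile_stack(manifest, base_dir=config.manifest.parent,
                                pixel_size_um=config.pixel_size_um)
        return manifest, tiles

    @stage("flat_field")
    def _flat(tiles):
        if not config.flat_field:
            return tiles
        flat = estimate_flat_field(tiles, smoothing_scale=config.smoothing_scale)
        return [apply_flat_field(t, flat) for t in tiles]

    @stage("stitch")
    def _stitch(tiles):
        mosaic = stitch_tiles(tiles, config.stitch)
        path = out / "stitched.tif"
        write_mosaic(mosaic, path)
        summary["outputs"]["stitched"] = str(path)
        return mosaic

    @stage("lipid_correct")
    def _unmix(mosaic):
        return lipid_correct(mosaic, config.unmix)

    @stage("render")
    def _render(cmap):
        he = render_pseudo_he(cmap, RenderConfig(mode="pseudo_he", stains=config.stains,
                                                 gamma=config.gamma))
        tc = render_two_color(cmap, RenderConfig(
            mode="two_color", low_percentile=config.low_percentile,
            high_percentile=config.high_percentile, gamma=config.gamma))
        he_path, tc_path = out / "pseudo_he.png", out / "two_color.png"
        write_rendering(he, he_path)
        write_rendering(tc, tc_path)
        summary["outputs"]["pseudo_he"] = str(he_path)
        summary["outputs"]["two_color"] = str(tc_path)

    manifest, tiles = _read()
    tiles = _flat(tiles)
    mosaic = _stitch(tiles)
    cmap = _unmix(mosaic)
    _render(cmap)

    summary["completed"] = True
    summary["checksums"] = {k: _sha256(Path(v)) for k, v in summary["outputs"].items()}
    summary["total_seconds"] = time.perf_counter() - t_all
    _write_summary(out, summary)
    return summary


def _params_dict(config: PipelineConfig) -> dict:
    d = dataclasses.asdict(config)
    d["manifest"] = str(d["manifest"])
    d["out_dir"] = str(d["out_dir"])
    return d


def _write_summary(out: Path, summary: dict) -> None:
    with open(out / "run_summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, default=str)
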