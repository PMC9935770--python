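"""End-to-end workflow: manifest of strip images in, comparison report out.

The pipeline mirrors the experimental procedure: photograph the twelve
reacted strips under each lamp, average the RGB grayscale over the paper
disc, fit the per-channel calibration lines, score them with R^2, and
compare light sources.  Outputs are plain CSV/JSON files:

``stats.csv``        one row per image (per-channel ROI mean/SD, pixel count)
``fits.csv``/``fits.json``  per light source x channel calibration fits
``comparison.csv``   light source x channel R^2 plus best channel and LOD/LOQ

:func:`make_fixtures` emits the 3 x 12 synthetic strip PNG set with JSON
sidecars and a manifest CSV, which :func:`run_pipeline` consumes.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, fields, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import roi, synthetic
from .calibration import CHANNELS, CalibrationDataset, fit_line, rank_channels
from .errors import BilistripError
from .limits import detection_limits

__all__ = ["RunConfig", "PipelineReport", "run_pipeline", "make_fixtures",
           "load_config", "DEFAULT_CONFIG"]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class RunConfig:
    """Parameters of one analysis run.

    ``camera_distance_cm`` and ``source_distance_cm`` record the rig
    geometry (lens-to-paper and lamp-to-paper distances); they are carried
    into the report metadata and do not affect the computation.
    """

    manifest: str = ""
    out_dir: str = ""
    roi_side: int = roi.DEFAULT_WINDOW_SIDE_PX
    roi_diameter: int = roi.DEFAULT_DISC_DIAMETER_PX
    channels: tuple = CHANNELS
    lod_convention: str = "3sigma/10sigma"
    seed: int = 0
    verbose: bool = False
    camera_distance_cm: float = 10.0
    source_distance_cm: float = 15.0


DEFAULT_CONFIG = RunConfig()

_BOOL = {"true": True, "1": True, "yes": True, "false": False, "0": False, "no": False}


def load_config(path) -> dict:
    """Parse a ``key = value`` configuration file (``#`` starts a comment)."""
    out = {}
    valid = {f.name for f in fields(RunConfig)}
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"{path}:{lineno}: expected 'key = value', got {raw!r}")
        key, value = (part.strip() for part in line.split("=", 1))
        if key not in valid:
            raise ValueError(f"{path}:{lineno}: unknown configuration key {key!r}")
        out[key] = value
    # coerce to the dataclass field types
    typed = {}
    for f in fields(RunConfig):
        if f.name not in out:
            continue
        v = out[f.name]
        if f.type in ("int",):
            typed[f.name] = int(v)
        elif f.type in ("float",):
            typed[f.name] = float(v)
        elif f.type in ("bool",):
            typed[f.name] = _BOOL[v.lower()]
        elif f.name == "channels":
            typed[f.name] = tuple(ch.strip() for ch in v.split(",") if ch.strip())
        else:
            typed[f.name] = v
    return typed


@dataclass(frozen=True)
class PipelineReport:
    stats: pd.DataFrame        # per-image ROI statistics
    fits: pd.DataFrame         # ranked per light source x channel fits
    comparison: pd.DataFrame   # light source x channel R^2 + LOD summary
    failures: list = field(default_factory=list)


def _analyse_images(cfg: RunConfig, manifest: pd.DataFrame,
                    base_dir: Path) -> tuple[pd.DataFrame, list]:
    mask = roi.circular_roi_mask(cfg.roi_side, cfg.roi_diameter)
    rows, failures = [], []
    for rec in manifest.itertuples(index=False):
        path = base_dir / rec.filename
        try:
            px = roi.load_image(path)
            r0 = (px.shape[0] - cfg.roi_side) // 2
            c0 = (px.shape[1] - cfg.roi_side) // 2
            stats = roi.channel_stats(px, mask.with_origin(r0, c0))
        except (OSError, ValueError, BilistripError) as exc:
            log.warning("skipping %s: %s", rec.filename, exc)
            failures.append((str(rec.filename), str(exc)))
            continue
        row = {"filename": rec.filename,
               "light_source": rec.light_source,
               "concentration_mg_dl": float(rec.concentration_mg_dl),
               "n_pixels": stats.n_pixels}
        for i, ch in enumerate(CHANNELS):
            row[f"mean_{ch}"] = stats.mean[i]
            row[f"sd_{ch}"] = stats.sd[i]
        rows.append(row)
    return pd.DataFrame(rows), failures


def run_pipeline(cfg: RunConfig) -> PipelineReport:
    """Execute the full manifest -> comparison-report workflow."""
    manifest_path = Path(cfg.manifest)
    manifest = pd.read_csv(manifest_path)
    if manifest.empty:
        raise BilistripError(f"manifest {manifest_path} lists no images")
    required = {"filename", "concentration_mg_dl", "light_source"}
    if not required.issubset(manifest.columns):
        raise BilistripError(
            f"manifest must have columns {sorted(required)}")

    stats, failures = _analyse_images(cfg, manifest, manifest_path.parent)
    if stats.empty:
        raise BilistripError("no readable images in manifest")

    all_fits, comparison_rows = [], []
    for light, group in stats.groupby("light_source", sort=True):
        ds = CalibrationDataset(group.reset_index(drop=True), light_source=light)
        fits = [fit_line(ds, ch) for ch in cfg.channels]
        all_fits.extend(fits)
        best = max(fits, key=lambda f: (f.r_squared,
                                        -CHANNELS.index(f.channel)))
        lim = detection_limits(best.slope, best.residual_sd, cfg.lod_convention)
        row = {"light_source": light,
               "concentration_range_mg_dl": "0.1-2",
               "total_points": cfg.roi_side ** 2,
               "analysis_points": int(group["n_pixels"].iloc[0])}
        for ch in cfg.channels:
            row[f"r2_{ch}"] = next(f.r_squared for f in fits if f.channel == ch)
        row.update(best_channel=best.channel, lod_mg_dl=lim.lod,
                   loq_mg_dl=lim.loq, lod_convention=lim.convention)
        comparison_rows.append(row)

    report = PipelineReport(stats=stats,
                            fits=rank_channels(all_fits),
                            comparison=pd.DataFrame(comparison_rows),
                            failures=failures)
    if cfg.out_dir:
        _write_report(Path(cfg.out_dir), report, cfg)
    return report


def _write_report(out_dir: Path, report: PipelineReport, cfg: RunConfig) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    report.stats.to_csv(out_dir / "stats.csv", index=False)
    report.fits.to_csv(out_dir / "fits.csv", index=False)
    report.comparison.to_csv(out_dir / "comparison.csv", index=False)
    payload = {
        "config": {"roi_side": cfg.roi_side, "roi_diameter": cfg.roi_diameter,
                   "lod_convention": cfg.lod_convention, "seed": cfg.seed,
                   "camera_distance_cm": cfg.camera_distance_cm,
                   "source_distance_cm": cfg.source_distance_cm},
        "fits": report.fits.to_dict(orient="records"),
        "comparison": report.comparison.to_dict(orient="records"),
        "failures": report.failures,
    }
    (out_dir / "fits.json").write_text(json.dumps(payload, indent=2,
                                                  sort_keys=True) + "\n")


def make_fixtures(out_dir, seed: int = 0,
                  lights=synthetic.LIGHT_SOURCES,
                  concs=None,
                  noise_sd: float = 2.0,
                  size_px: int = 160) -> Path:
    """Emit the synthetic strip-image fixture set and its manifest.

    One PNG plus JSON sidecar per light source x concentration (3 x 12 by
    default).  Strip-to-strip variability is a common-mode Gaussian factor
    shared by the three channels of one strip, scaled by the per-channel
    fixture SDs; pixel noise is i.i.d. Gaussian.  Fully reproducible: the
    per-image seeds derive from ``seed``.

    Returns the path of the manifest CSV.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    concs = synthetic.default_concentration_series() if concs is None else concs
    rng = np.random.default_rng(seed)
    rows = []
    for light in lights:
        sigmas = synthetic.fixture_strip_sigmas(light)
        for i, c in enumerate(concs):
            z = rng.standard_normal()
            offset = tuple(sigmas[ch] * z for ch in CHANNELS)
            img_seed = int(rng.integers(0, 2 ** 31 - 1))
            img = synthetic.render_strip_image(
                c, light=light, noise_sd=noise_sd, size_px=size_px,
                seed=img_seed, channel_offset=offset)
            stem = f"{light}_{i:02d}"
            import imageio.v3 as iio
            iio.imwrite(out / f"{stem}.png", img.pixels)
            (out / f"{stem}.json").write_text(
                json.dumps(img.metadata, indent=2, sort_keys=True) + "\n")
            rows.append({"filename": f"{stem}.png",
                         "concentration_mg_dl": float(c),
                         "light_source": light})
    manifest = out / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest
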