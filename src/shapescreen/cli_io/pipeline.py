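"""End-to-end screen pipeline: quantify -> aggregate -> test -> validate."""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .. import __version__, morphometry, screen_stats
from .config import PipelineConfig
from .layout import read_layout, write_results

logger = logging.getLogger(__name__)

__all__ = ["ScreenBundle", "read_image", "run_screen"]


@dataclass
class ScreenBundle:
    """All tables produced by one screen run, plus its manifest."""

    per_cell: pd.DataFrame
    aggregated: pd.DataFrame
    normalized: pd.DataFrame
    results: pd.DataFrame
    validation: pd.DataFrame
    manifest: dict

    def tables(self) -> dict[str, pd.DataFrame]:
        return {"per_cell": self.per_cell, "aggregated": self.aggregated,
                "normalized": self.normalized, "results": self.results,
                "validation": self.validation}


def read_image(path: str | Path) -> np.ndarray:
    """Read a grayscale TIFF or PNG micrograph as a 2D array."""
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        import tifffile

        image = tifffile.imread(path)
    else:
        import imageio.v3 as iio

        image = iio.imread(path)
    image = np.asarray(image)
    if image.ndim == 3 and image.shape[-1] in (3, 4):  # flatten RGB(A)
        image = image[..., :3].mean(axis=-1)
    if image.ndim != 2:
        raise ValueError(f"{path.name}: expected a single-channel 2D image, "
                         f"got shape {image.shape}")
    return image


def quantify_layout(layout: pd.DataFrame, images_dir: str | Path,
                    config: morphometry.MorphometryConfig | None = None
                    ) -> pd.DataFrame:
    """Run per-cell morphometry for every image of a layout."""
    config = config or morphometry.MorphometryConfig()
    images_dir = Path(images_dir)
    frames = []
    for row in layout.itertuples(index=False):
        image = read_image(images_dir / row.image)
        meta = {"image": row.image, "gene": row.gene, "sirna": row.sirna,
                "experiment": row.experiment, "field": row.field}
        try:
            frames.append(morphometry.analyze_field(image, config, meta))
        except Exception as exc:
            raise type(exc)(f"image {row.image!r}: {exc}") from exc
    return pd.concat(frames, ignore_index=True)


def run_screen(layout: str | Path | pd.DataFrame,
               images_dir: str | Path | None = None,
               config: PipelineConfig | None = None,
               out_dir: str | Path | None = None,
               table: pd.DataFrame | None = None) -> ScreenBundle:
    """Execute the full screen analysis and optionally write all outputs.

    Either ``layout`` + ``images_dir`` (image-level run) or ``table``
    (pre-aggregated mean circularities; layout ignored) must be given.
    Deterministic for fixed inputs and config; the manifest records the
    config, package versions, per-stage row counts and the fitted
    variance prior.
    """
    config = config or PipelineConfig()
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), 20))

    if table is not None:
        per_cell = pd.DataFrame()
        agg_input = table
        n_images = 0
    else:
        if images_dir is None:
            raise ValueError("images_dir is required for an image-level run")
        if not isinstance(layout, pd.DataFrame):
            layout = read_layout(layout, images_dir)
        n_images = len(layout)
        per_cell = quantify_layout(layout, images_dir, config.morphometry)
        if per_cell.empty:
            raise ValueError("morphometry produced no cells; check images")
        agg_input = per_cell

    stats_cfg = config.stats
    aggregated = screen_stats.aggregate_condition(
        agg_input, control_label=stats_cfg.control_label)
    normalized = screen_stats.normalize_experiment(aggregated, stats_cfg)
    results, prior = screen_stats.differential_test(normalized, stats_cfg)
    results = screen_stats.classify_hits(results, stats_cfg)
    validation = screen_stats.validate_genes(results, stats_cfg)

    manifest = {
        "shapescreen_version": __version__,
        "numpy_version": np.__version__,
        "pandas_version": pd.__version__,
        "config": config.to_dict(),
        "n_images": n_images,
        "row_counts": {"per_cell": len(per_cell),
                       "aggregated": len(aggregated),
                       "normalized": len(normalized),
                       "results": len(results),
                       "validation": len(validation)},
        "variance_prior": (dataclasses.asdict(prior)
                           if prior is not None else None),
        "n_hits_positive": int((results["hit_class"] == "positive").sum()),
        "n_hits_negative": int((results["hit_class"] == "negative").sum()),
        "n_validated": int((validation["status"] == "validated").sum()),
    }
    bundle = ScreenBundle(per_cell=per_cell, aggregated=aggregated,
                          normalized=normalized, results=results,
                          validation=validation, manifest=manifest)
    if out_dir is not None:
        out_dir = Path(out_dir)
        write_results(bundle.tables(), out_dir)
        with open(out_dir / "manifest.json", "w", encoding="utf-8") as fh:
            json.dump(manifest, fh, indent=2, default=str)
    return bundle
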