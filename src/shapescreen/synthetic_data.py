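"""Seeded synthetic-data generators with analytic ground truth.

Every generator is deterministic for a fixed seed and emits the ground
truth needed to test the downstream stages: cell-field images carry
per-cell masks and closed-form circularities, table-level screens carry
planted log2 effects, scratch pairs carry known band widths, and Ct
tables carry planted fold changes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from scipy import special

__all__ = [
    "ShapeSpec",
    "FieldGroundTruth",
    "ScreenDesign",
    "ScratchGroundTruth",
    "shape_spec",
    "analytic_area",
    "analytic_perimeter",
    "generate_field",
    "generate_screen_tables",
    "generate_scratch_pair",
    "generate_ct_table",
    "generate_image_screen",
]

# Branch geometry for ramified cells, as fractions of the soma radius.
# Width < 2r keeps the closed-form union area/perimeter valid; length 2r
# makes each added process cost much more perimeter than area, so the
# analytic circularity strictly decreases with every branch.
_BRANCH_WIDTH_FRAC = 0.6
_BRANCH_LENGTH_FRAC = 2.0


@dataclass(frozen=True)
class ShapeSpec:
    """A continuous cell shape with its closed-form circularity.

    Use :func:`shape_spec` to construct one; ``target_circularity`` is
    derived from the closed-form area and perimeter, never supplied.
    """

    kind: str
    size_px: float
    aspect_ratio: float = 1.0
    n_branches: int = 0
    target_circularity: float = field(default=1.0)

    def __post_init__(self) -> None:
        if self.kind not in ("disk", "ellipse", "ramified"):
            raise ValueError(f"unknown shape kind {self.kind!r}")
        if self.size_px <= 0:
            raise ValueError("size_px must be positive")
        if self.aspect_ratio < 1:
            raise ValueError("aspect_ratio must be >= 1")
        if self.kind == "disk" and self.aspect_ratio != 1:
            raise ValueError("disk requires aspect_ratio == 1")
        if self.n_branches < 0:
            raise ValueError("n_branches must be >= 0")
        if self.kind != "ramified" and self.n_branches:
            raise ValueError("n_branches only applies to ramified shapes")


def _branch_geometry(r: float) -> tuple[float, float, float, float]:
    """Return (width, length, inner x-offset, half-opening angle)."""
    w = _BRANCH_WIDTH_FRAC * r
    length = _BRANCH_LENGTH_FRAC * r
    x0 = math.sqrt(r * r - (w / 2.0) ** 2)
    theta = math.asin(w / (2.0 * r))
    return w, length, x0, theta


def _max_branches(r: float) -> int:
    _, _, _, theta = _branch_geometry(r)
    return int((2.0 * math.pi) // (2.0 * theta * 1.25))


def analytic_area(kind: str, size_px: float, aspect_ratio: float = 1.0,
                  n_branches: int = 0) -> float:
    """Closed-form area of the continuous shape, in px^2."""
    r = float(size_px)
    if kind == "disk":
        return math.pi * r * r
    if kind == "ellipse":
        a = r * math.sqrt(aspect_ratio)
        b = r / math.sqrt(aspect_ratio)
        return math.pi * a * b
    if kind == "ramified":
        w, length, x0, theta = _branch_geometry(r)
        # circular segment of the disk that lies inside each branch base
        segment = r * r * theta - x0 * w / 2.0
        return math.pi * r * r + n_branches * (w * length - segment)
    raise ValueError(f"unknown shape kind {kind!r}")


def analytic_perimeter(kind: str, size_px: float, aspect_ratio: float = 1.0,
                       n_branches: int = 0) -> float:
    """Closed-form perimeter of the continuous shape, in px.

    Ellipse perimeter uses the complete elliptic integral of the second
    kind (exact), not a series approximation.
    """
    r = float(size_px)
    if kind == "disk":
        return 2.0 * math.pi * r
    if kind == "ellipse":
        a = r * math.sqrt(aspect_ratio)
        b = r / math.sqrt(aspect_ratio)
        m = 1.0 - (b / a) ** 2
        return 4.0 * a * float(special.ellipe(m))
    if kind == "ramified":
        w, length, x0, theta = _branch_geometry(r)
        arc_removed = 2.0 * theta * r
        exposed = 2.0 * length + w
        return 2.0 * math.pi * r + n_branches * (exposed - arc_removed)
    raise ValueError(f"unknown shape kind {kind!r}")


def shape_spec(kind: str, size_px: float, aspect_ratio: float = 1.0,
               n_branches: int = 0) -> ShapeSpec:
    """Build a :class:`ShapeSpec` with its analytic circularity filled in."""
    if kind == "ramified" and n_branches > _max_branches(size_px):
        raise ValueError(
            f"n_branches={n_branches} exceeds the non-overlapping maximum "
            f"{_max_branches(size_px)} for this soma size"
        )
    area = analytic_area(kind, size_px, aspect_ratio, n_branches)
    perim = analytic_perimeter(kind, size_px, aspect_ratio, n_branches)
    circ = 4.0 * math.pi * area / (perim * perim)
    return ShapeSpec(kind=kind, size_px=float(size_px),
                     aspect_ratio=float(aspect_ratio),
                     n_branches=int(n_branches),
                     target_circularity=circ)


@dataclass
class FieldGroundTruth:
    """One synthetic field: the image plus everything a test needs."""

    image: np.ndarray
    masks: list[np.ndarray]
    shapes: list[ShapeSpec]
    n_interior: int
    n_border: int
    seed: int

    def to_frame(self) -> pd.DataFrame:
        """Per-cell ground-truth table (analytic values for each shape)."""
        rows = []
        n = len(self.shapes)
        for i, (spec, mask) in enumerate(zip(self.shapes, self.masks)):
            rows.append({
                "cell_id": i + 1,
                "kind": spec.kind,
                "area": analytic_area(spec.kind, spec.size_px,
                                      spec.aspect_ratio, spec.n_branches),
                "perimeter": analytic_perimeter(spec.kind, spec.size_px,
                                                spec.aspect_ratio,
                                                spec.n_branches),
                "circularity": spec.target_circularity,
                "border_flag": i >= n - self.n_border,
                "pixels": int(mask.sum()),
            })
        return pd.DataFrame(rows)


def _rasterize(spec: ShapeSpec, center: tuple[float, float], angle: float,
               shape_hw: tuple[int, int]) -> np.ndarray:
    """Boolean mask of the shape on the full image grid (clipped at edges)."""
    h, w = shape_hw
    rr, cc = np.mgrid[0:h, 0:w]
    y = rr - center[0]
    x = cc - center[1]
    ca, sa = math.cos(angle), math.sin(angle)
    # rotate world coords into the shape's local frame
    xl = ca * x + sa * y
    yl = -sa * x + ca * y
    r = spec.size_px
    if spec.kind == "disk":
        return xl * xl + yl * yl <= r * r
    if spec.kind == "ellipse":
        a = r * math.sqrt(spec.aspect_ratio)
        b = r / math.sqrt(spec.aspect_ratio)
        return (xl / a) ** 2 + (yl / b) ** 2 <= 1.0
    # ramified: soma disk plus n equally spaced radial rectangles
    mask = xl * xl + yl * yl <= r * r
    bw, bl, x0, _ = _branch_geometry(r)
    for i in range(spec.n_branches):
        phi = 2.0 * math.pi * i / max(spec.n_branches, 1)
        cb, sb = math.cos(phi), math.sin(phi)
        u = cb * xl + sb * yl
        v = -sb * xl + cb * yl
        mask |= (u >= x0) & (u <= x0 + bl) & (np.abs(v) <= bw / 2.0)
    return mask


def _shape_extent(spec: ShapeSpec) -> float:
    r = spec.size_px
    if spec.kind == "disk":
        return r
    if spec.kind == "ellipse":
        return r * math.sqrt(spec.aspect_ratio)
    bw, bl, x0, _ = _branch_geometry(r)
    return math.hypot(x0 + bl, bw / 2.0)


class PlacementError(RuntimeError):
    """Raised when shapes cannot be placed at the requested density."""


def generate_field(specs: list[ShapeSpec], image_size: int | tuple[int, int],
                   n_border: int = 0, noise_sd: float = 0.0, seed: int = 0,
                   bit_depth: int = 16, foreground: float | None = None,
                   min_pixels: int = 60, max_attempts: int = 400,
                   gap_px: int = 3) -> FieldGroundTruth:
    """Render non-overlapping cells on a dark field with Gaussian noise.

    The last ``n_border`` specs are placed intersecting an image edge; the
    rest are kept at least one pixel away from every edge.  Shapes are
    placed by rejection sampling with a ``gap_px`` dilation gap so that
    neighbouring cells never merge into one connected component.

    Raises
    ------
    PlacementError
        if a shape cannot be placed within ``max_attempts`` tries.
    """
    if n_border < 0 or n_border > len(specs):
        raise ValueError("n_border must be between 0 and len(specs)")
    if bit_depth not in (8, 16):
        raise ValueError("bit_depth must be 8 or 16")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    hw = (image_size, image_size) if isinstance(image_size, int) else tuple(image_size)
    h, w = hw
    maxval = 2 ** bit_depth - 1
    if foreground is None:
        foreground = 200.0 if bit_depth == 8 else 200.0 * 257.0

    rng = np.random.default_rng(seed)
    occupied = np.zeros(hw, dtype=bool)
    masks: list[np.ndarray] = []
    n_interior = len(specs) - n_border
    structure = np.ones((2 * gap_px + 1, 2 * gap_px + 1), dtype=bool)

    for i, spec in enumerate(specs):
        at_border = i >= n_interior
        extent = _shape_extent(spec)
        placed = False
        for _ in range(max_attempts):
            angle = rng.uniform(0.0, 2.0 * math.pi)
            if at_border:
                edge = rng.integers(0, 4)
                off = rng.uniform(-extent * 0.4, extent * 0.4)
                along_r = rng.uniform(extent, h - 1 - extent) if h > 2 * extent + 2 else h / 2
                along_c = rng.uniform(extent, w - 1 - extent) if w > 2 * extent + 2 else w / 2
                if edge == 0:
                    center = (along_r, off)
                elif edge == 1:
                    center = (along_r, w - 1 + off)
                elif edge == 2:
                    center = (off, along_c)
                else:
                    center = (h - 1 + off, along_c)
            else:
                lo = extent + 2.0
                if h - 3.0 - extent <= lo or w - 3.0 - extent <= lo:
                    raise PlacementError(
                        f"shape {i} (extent {extent:.1f} px) does not fit "
                        f"inside a {h}x{w} image away from the borders"
                    )
                center = (rng.uniform(lo, h - 3.0 - extent),
                          rng.uniform(lo, w - 3.0 - extent))
            mask = _rasterize(spec, center, angle, hw)
            if mask.sum() < min_pixels:
                continue
            touches = (mask[0, :].any() or mask[-1, :].any()
                       or mask[:, 0].any() or mask[:, -1].any())
            if touches != at_border:
                continue
            grown = ndi.binary_dilation(mask, structure=structure)
            if (grown & occupied).any():
                continue
            occupied |= grown
            masks.append(mask)
            placed = True
            break
        if not placed:
            raise PlacementError(
                f"could not place shape {i} after {max_attempts} attempts; "
                "reduce the number or size of shapes"
            )

    union = np.zeros(hw, dtype=float)
    for mask in masks:
        union[mask] = foreground
    if noise_sd > 0:
        union = union + rng.normal(0.0, noise_sd, size=hw)
    image = np.clip(np.rint(union), 0, maxval).astype(
        np.uint8 if bit_depth == 8 else np.uint16)
    return FieldGroundTruth(image=image, masks=masks, shapes=list(specs),
                            n_interior=n_interior, n_border=n_border,
                            seed=seed)


@dataclass(frozen=True)
class ScreenDesign:
    """Design of a table-level simulated screen with planted effects.

    ``effect_map`` maps gene name -> planted log2 circularity shift; genes
    are named ``G001 .. G<n_genes>``.  ``control_replicates`` is the number
    of independent control wells per experiment (real screens carry several
    control wells per plate; averaging them stabilises the normaliser).
    """

    n_genes: int = 157
    sirnas_per_gene: int = 3
    n_experiments: int = 3
    fields_per_condition: int = 3
    cells_per_field: int = 20
    control_label: str = "Scrambled"
    effect_map: dict[str, float] = field(default_factory=dict)
    noise_sd: float = 0.1
    control_mean: float = 0.5
    control_replicates: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        for name, value in (("n_genes", self.n_genes),
                            ("sirnas_per_gene", self.sirnas_per_gene),
                            ("n_experiments", self.n_experiments),
                            ("fields_per_condition", self.fields_per_condition),
                            ("cells_per_field", self.cells_per_field),
                            ("control_replicates", self.control_replicates)):
            if int(value) != value or value <= 0:
                raise ValueError(f"{name} must be a positive integer")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.control_mean <= 0:
            raise ValueError("control_mean must be > 0")
        if self.effect_map.get(self.control_label, 0.0) != 0.0:
            raise ValueError("the control gene cannot carry a planted effect")

    @property
    def gene_names(self) -> list[str]:
        width = max(3, len(str(self.n_genes)))
        return [f"G{i + 1:0{width}d}" for i in range(self.n_genes)]


def generate_screen_tables(design: ScreenDesign) -> pd.DataFrame:
    """Simulate mean circularities for every (gene, siRNA, experiment).

    Each value is ``control_mean * 2**(effect + eps)`` with
    ``eps ~ N(0, noise_sd^2)``; control wells (effect 0) are included in
    every experiment.  The schema matches the morphometry aggregation, so
    the stats stage consumes either source interchangeably.
    """
    genes = design.gene_names
    unknown = set(design.effect_map) - set(genes) - {design.control_label}
    if unknown:
        raise ValueError(f"effect_map references unknown genes: {sorted(unknown)}")

    rng = np.random.default_rng(design.seed)
    rows = []
    for exp in range(1, design.n_experiments + 1):
        for rep in range(1, design.control_replicates + 1):
            eps = rng.normal(0.0, design.noise_sd) if design.noise_sd > 0 else 0.0
            rows.append({
                "gene": design.control_label,
                "sirna": f"ctrl{rep}" if design.control_replicates > 1 else "ctrl",
                "experiment": exp,
                "mean_circularity": design.control_mean * 2.0 ** eps,
            })
        for gene in genes:
            effect = design.effect_map.get(gene, 0.0)
            for s in range(1, design.sirnas_per_gene + 1):
                eps = rng.normal(0.0, design.noise_sd) if design.noise_sd > 0 else 0.0
                rows.append({
                    "gene": gene,
                    "sirna": f"s{s}",
                    "experiment": exp,
                    "mean_circularity": design.control_mean * 2.0 ** (effect + eps),
                })
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class ScratchGroundTruth:
    width_t1_px: float
    width_t24_px: float
    seed: int

    @property
    def closure_percent(self) -> float:
        return 100.0 * self.width_t24_px / self.width_t1_px


def _scratch_image(width: float, hw: tuple[int, int], texture_sd: float,
                   rng: np.random.Generator) -> np.ndarray:
    h, w = hw
    img = rng.normal(150.0, texture_sd, size=hw)
    band = int(round(width))
    if band > 0:
        c0 = (w - band) // 2
        img[:, c0:c0 + band] = 60.0
    return np.clip(np.rint(img), 0, 255).astype(np.uint8)


def generate_scratch_pair(width_t1: float, width_t24: float,
                          image_size: int | tuple[int, int] = (400, 600),
                          texture_sd: float = 30.0, seed: int = 0
                          ) -> tuple[np.ndarray, np.ndarray, ScratchGroundTruth]:
    """Two scratch-assay images: textured lawn with a centred smooth band.

    ``width_t24 <= width_t1`` (wounds close, they do not open); width 0
    yields a fully textured image (complete closure).
    """
    hw = (image_size, image_size) if isinstance(image_size, int) else tuple(image_size)
    if width_t24 < 0 or width_t1 < 0:
        raise ValueError("widths must be >= 0")
    if width_t24 > width_t1:
        raise ValueError("width_t24 cannot exceed width_t1")
    if width_t1 > hw[1]:
        raise ValueError("width_t1 exceeds the image width")
    rng = np.random.default_rng(seed)
    img1 = _scratch_image(width_t1, hw, texture_sd, rng)
    img24 = _scratch_image(width_t24, hw, texture_sd, rng)
    return img1, img24, ScratchGroundTruth(float(width_t1), float(width_t24), seed)


def generate_ct_table(true_fold_changes: dict[str, float], base_ct: float = 24.0,
                      ref_ct: float = 18.0, noise_sd: float = 0.0,
                      n_triplicates: int = 3, seed: int = 0,
                      target_gene: str = "BDNF", reference_gene: str = "GAPDH",
                      calibrator_label: str = "Scrambled") -> pd.DataFrame:
    """Ct replicates with planted fold changes relative to the calibrator.

    For sample ``s`` with planted fold ``f``, target-gene Ct replicates are
    ``base_ct - log2(f) + eps`` and reference-gene Ct replicates are
    ``ref_ct + eps`` (``eps ~ N(0, noise_sd^2)``), so the recovered
    2^-ddCt at ``noise_sd=0`` equals ``f`` exactly for dyadic folds.
    """
    if n_triplicates < 1:
        raise ValueError("n_triplicates must be >= 1")
    for sample, fold in true_fold_changes.items():
        if fold <= 0:
            raise ValueError(f"fold change for {sample!r} must be > 0")
    folds = {calibrator_label: 1.0}
    folds.update({s: f for s, f in true_fold_changes.items()
                  if s != calibrator_label})
    rng = np.random.default_rng(seed)
    rows = []
    for sample, fold in folds.items():
        for gene, clean_ct in ((target_gene, base_ct - math.log2(fold)),
                               (reference_gene, ref_ct)):
            for rep in range(1, n_triplicates + 1):
                eps = rng.normal(0.0, noise_sd) if noise_sd > 0 else 0.0
                rows.append({"sample": sample, "gene": gene,
                             "replicate": rep, "ct": clean_ct + eps})
    return pd.DataFrame(rows)


def generate_image_screen(out_dir: str | Path, n_genes: int = 8,
                          planted_round: dict[str, float] | None = None,
                          sirnas_per_gene: int = 3, n_experiments: int = 3,
                          fields_per_condition: int = 3, cells_per_field: int = 4,
                          image_size: int = 128, cell_radius: float = 8.0,
                          base_aspect: float = 4.0, between_sd: float = 0.06,
                          within_sd: float = 0.05, noise_sd: float = 800.0,
                          seed: int = 0, control_label: str = "Scrambled"
                          ) -> pd.DataFrame:
    """Write a full image-level screen to ``out_dir`` and return its layout.

    Cells are ellipses; the control and null genes draw aspect ratios
    around ``base_aspect`` (elongated), while genes in ``planted_round``
    (gene -> aspect ratio, e.g. 1.2) are rendered much rounder, planting a
    positive differential-circularity effect.  Lognormal jitter is applied
    per condition (between experiments) and per cell.  Images are 16-bit
    TIFFs named ``<gene>_<sirna>_e<exp>_f<field>.tif``.
    """
    import tifffile

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    planted_round = dict(planted_round or {})
    width = max(3, len(str(n_genes)))
    genes = [f"G{i + 1:0{width}d}" for i in range(n_genes)]
    unknown = set(planted_round) - set(genes)
    if unknown:
        raise ValueError(f"planted_round references unknown genes: {sorted(unknown)}")

    rng = np.random.default_rng(seed)
    conditions = [(control_label, "pool")] + [
        (g, f"s{s}") for g in genes for s in range(1, sirnas_per_gene + 1)]
    rows = []
    for gene, sirna in conditions:
        aspect0 = planted_round.get(gene, base_aspect)
        for exp in range(1, n_experiments + 1):
            cond_jitter = rng.normal(0.0, between_sd)
            for fld in range(1, fields_per_condition + 1):
                specs = []
                for _ in range(cells_per_field):
                    jit = rng.normal(0.0, within_sd)
                    aspect = max(1.0, aspect0 * math.exp(cond_jitter + jit))
                    specs.append(shape_spec("ellipse", cell_radius, aspect))
                field_seed = int(rng.integers(0, 2 ** 31 - 1))
                gt = generate_field(specs, image_size, n_border=0,
                                    noise_sd=noise_sd, seed=field_seed)
                name = f"{gene}_{sirna}_e{exp}_f{fld}.tif"
                tifffile.imwrite(out_dir / name, gt.image)
                rows.append({"image": name, "gene": gene, "sirna": sirna,
                             "experiment": exp, "field": fld})
    return pd.DataFrame(rows)
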