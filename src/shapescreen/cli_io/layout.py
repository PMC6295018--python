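"""Strict CSV schemas: screen layouts and result bundles."""

from __future__ import annotations

from pathlib import Path

import pandas as pd

__all__ = ["LAYOUT_COLUMNS", "read_layout", "write_results"]

LAYOUT_COLUMNS = ["image", "gene", "sirna", "experiment", "field"]


def read_layout(path: str | Path, images_dir: str | Path | None = None,
                require_exists: bool = True) -> pd.DataFrame:
    """Read and validate a screen layout CSV.

    Enforces the exact column set, uniqueness of (gene, sirna,
    experiment, field), and — when ``require_exists`` — that every image
    file exists under ``images_dir`` (default: the layout's directory).
    """
    path = Path(path)
    layout = pd.read_csv(path)
    missing = [c for c in LAYOUT_COLUMNS if c not in layout.columns]
    extra = [c for c in layout.columns if c not in LAYOUT_COLUMNS]
    if missing or extra:
        raise ValueError(
            f"layout schema mismatch in {path.name}: "
            f"missing columns {missing}, unexpected columns {extra}")
    key = ["gene", "sirna", "experiment", "field"]
    dupes = layout.loc[layout.duplicated(key, keep=False)]
    if len(dupes):
        first = dupes.iloc[0][key].tolist()
        raise ValueError(f"duplicate layout entries for "
                         f"(gene, sirna, experiment, field) = {first}")
    if require_exists:
        base = Path(images_dir) if images_dir is not None else path.parent
        absent = [name for name in layout["image"]
                  if not (base / name).is_file()]
        if absent:
            raise FileNotFoundError(
                f"{len(absent)} image(s) from the layout not found under "
                f"{base}, first: {absent[0]}")
    return layout


def write_results(bundle: dict[str, pd.DataFrame], out_dir: str | Path
                  ) -> dict[str, Path]:
    """Write every table of a result bundle as ``<name>.csv``."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {}
    for name, frame in bundle.items():
        dest = out_dir / f"{name}.csv"
        frame.to_csv(dest, index=False)
        paths[name] = dest
    return paths
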