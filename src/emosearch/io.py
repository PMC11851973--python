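"""Reading and writing the package's tabular and image formats.

Gaze streams and trial/layout tables travel as TSV with a header; features
and per-image behavior as CSV; ground truth and bin metadata as JSON
sidecars; images as 8- or 16-bit grayscale PNG.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

GAZE_COLUMNS = ["participant", "trial", "block", "condition",
                "target_emotion", "t_ms", "x_deg", "y_deg", "validity"]


def write_tsv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def read_gaze(path) -> pd.DataFrame:
    df = read_tsv(path)
    missing = set(GAZE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"gaze file lacks columns {sorted(missing)}")
    return df


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=1, default=_jsonable))


def _jsonable(o):
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, (np.integer, np.floating, np.bool_)):
        return o.item()
    raise TypeError(f"not JSON serializable: {type(o)}")


def write_image_png(image: np.ndarray, path, bit_depth: int = 8) -> None:
    """Write a float image as grayscale PNG, linearly rescaled to the full
    integer range."""
    img = np.asarray(image, dtype=float)
    lo, hi = img.min(), img.max()
    scale = (hi - lo) if hi > lo else 1.0
    norm = (img - lo) / scale
    if bit_depth == 8:
        Image.fromarray((norm * 255).round().astype(np.uint8), "L").save(path)
    elif bit_depth == 16:
        Image.fromarray((norm * 65535).round().astype(np.uint16),
                        "I;16").save(path)
    else:
        raise ValueError("bit_depth must be 8 or 16")


def read_image_gray(path) -> np.ndarray:
    """Load an image as a float grayscale array in [0, 1]."""
    with Image.open(path) as im:
        arr = np.asarray(im.convert("F"), dtype=float)
    peak = 65535.0 if arr.max() > 255.0 else 255.0
    return arr / peak
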