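"""Batch feature extraction over an image directory tree.

Layout: ``<root>/<pot_id>/<date>/<view>.png`` with views ``top``, ``side-0``
and ``side-90``.  Produces one row per (pot, date, view) with the seven shape
features plus an ``empty_flag``; unreadable files are flagged and logged but
never abort the batch.
"""

from __future__ import annotations

import logging
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd

from ..errors import EmptyMaskError
from .features import FEATURE_NAMES, extract_features
from .segment import SegmentationParams, segment_plant

log = logging.getLogger(__name__)

VIEWS = ("top", "side-0", "side-90")


def _feature_row(pot_id: str, timestamp: float, view: str) -> dict:
    row: dict = {"pot_id": pot_id, "timestamp": timestamp, "view": view}
    row.update({name: np.nan for name in FEATURE_NAMES})
    row["empty_flag"] = True
    row["error"] = ""
    return row


def extract_image(path: Path, params: SegmentationParams) -> dict:
    """Segment and measure a single image file; errors land in the row."""
    image = iio.imread(path)
    if image.ndim == 3 and image.shape[2] == 4:
        image = image[..., :3]
    mask = segment_plant(image, params)
    return mask, extract_features(mask) if not mask.empty else None


def batch_extract(
    image_root: str | Path,
    params: SegmentationParams = SegmentationParams(),
    *,
    save_masks: str | Path | None = None,
) -> pd.DataFrame:
    """Extract shape features for every image under ``image_root``.

    Rows are ordered by (pot_id, timestamp, view); the ordering and all
    values are deterministic, so re-runs produce byte-identical tables.
    """
    root = Path(image_root)
    if not root.is_dir():
        raise FileNotFoundError(f"image root {root} is not a directory")
    mask_root = Path(save_masks) if save_masks is not None else None

    rows: list[dict] = []
    for pot_dir in sorted(p for p in root.iterdir() if p.is_dir()):
        for date_dir in sorted(p for p in pot_dir.iterdir() if p.is_dir()):
            try:
                timestamp = float(date_dir.name)
            except ValueError:
                log.warning("skipping non-numeric date directory %s", date_dir)
                continue
            for view in VIEWS:
                img_path = date_dir / f"{view}.png"
                if not img_path.exists():
                    continue
                row = _feature_row(pot_dir.name, timestamp, view)
                try:
                    mask, feats = extract_image(img_path, params)
                except EmptyMaskError:  # pragma: no cover - guarded above
                    feats = None
                except Exception as exc:  # unreadable / corrupt file
                    row["error"] = f"{type(exc).__name__}: {exc}"
                    log.warning("failed to process %s: %s", img_path, exc)
                    rows.append(row)
                    continue
                if feats is not None:
                    row.update(feats.as_dict())
                    row["empty_flag"] = False
                else:
                    log.warning("no plant found in %s", img_path)
                if mask_root is not None:
                    out = mask_root / pot_dir.name / date_dir.name
                    out.mkdir(parents=True, exist_ok=True)
                    iio.imwrite(
                        out / f"{view}.png",
                        (mask.grid.astype(np.uint8) * 255),
                    )
                rows.append(row)

    table = pd.DataFrame(
        rows,
        columns=["pot_id", "timestamp", "view", *FEATURE_NAMES, "empty_flag", "error"],
    )
    return table.sort_values(["pot_id", "timestamp", "view"], kind="mergesort").reset_index(
        drop=True
    )
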