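"""Reading and writing the study's on-disk formats.

Attention and saliency maps travel either as 16-bit grayscale PNGs (with
a linear intensity scale recorded in the sidecar manifest, so the round
trip is lossy only at 1/65535 relative resolution) or as plain-text dense
matrices.  Fixations, responses, comparison results, and pooled results
are delimited text with headers; face masks are 1-bit PNGs; AOI polygons
and study ground truth are JSON.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from PIL import Image

from .maps import AttentionMap, FaceMask, FixationEvent, IntensityGrid
from .metrics import AOIRegion, ComparisonResult
from .stats import MetaResult, ResponseRecord

__all__ = [
    "write_map_png", "read_map_png", "write_map_txt", "read_map_txt",
    "write_manifest", "read_manifest", "write_maps",
    "read_maps", "write_mask_png", "read_mask_png",
    "write_fixations", "read_fixations",
    "write_responses", "read_responses",
    "write_aois", "read_aois",
    "write_comparisons", "read_comparisons", "write_meta_results",
]

FIXATION_COLUMNS = ["participant_id", "image_id", "x", "y", "onset_ms", "duration_ms"]
RESPONSE_COLUMNS = ["participant_id", "group", "image_id", "truth_affected",
                    "response_affected", "condition_named_correctly"]
MANIFEST_COLUMNS = ["filename", "participant_id", "group", "image_id", "stage", "scale"]
COMPARISON_COLUMNS = ["image_id", "pair", "level", "iou", "iou_sd", "kl", "kl_sd",
                      "n_pixels_a", "n_pixels_b"]


# -- dense maps ---------------------------------------------------------------

def write_map_png(path, values: np.ndarray) -> float:
    """Write a nonnegative map as 16-bit grayscale PNG; returns the linear
    scale (original max) needed to recover intensities on read."""
    v = np.clip(np.asarray(values, dtype=np.float64), 0.0, None)
    scale = float(v.max())
    if scale > 0:
        img = np.round(v / scale * 65535.0).astype(np.uint16)
    else:
        img = np.zeros(v.shape, dtype=np.uint16)
    Image.fromarray(img).save(path)
    return scale


def read_map_png(path, scale: float = 1.0) -> np.ndarray:
    arr = np.asarray(Image.open(path), dtype=np.float64)
    if scale > 0:
        arr = arr / 65535.0 * scale
    return arr


def write_map_txt(path, values: np.ndarray) -> None:
    np.savetxt(path, np.asarray(values), fmt="%.10g")


def read_map_txt(path) -> np.ndarray:
    return np.loadtxt(path, ndmin=2)


def write_manifest(path, rows: Sequence[dict]) -> None:
    pd.DataFrame(rows, columns=MANIFEST_COLUMNS).to_csv(path, index=False)


def read_manifest(path) -> pd.DataFrame:
    return pd.read_csv(path, keep_default_na=False)


def write_maps(directory, maps: Sequence[AttentionMap], fmt: str = "png") -> Path:
    """Write attention maps plus a ``manifest.csv`` mapping file → metadata."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    rows = []
    for i, m in enumerate(maps):
        stem = f"map_{i:04d}"
        if fmt == "png":
            fn = f"{stem}.png"
            scale = write_map_png(directory / fn, m.values)
        elif fmt == "txt":
            fn = f"{stem}.txt"
            write_map_txt(directory / fn, m.values)
            scale = 1.0
        else:
            raise ValueError(f"unknown map format {fmt!r}")
        rows.append({"filename": fn, "participant_id": m.participant_id,
                     "group": m.group, "image_id": m.image_id, "stage": m.stage,
                     "scale": scale})
    manifest = directory / "manifest.csv"
    write_manifest(manifest, rows)
    return manifest


def read_maps(manifest_path) -> list[AttentionMap]:
    manifest_path = Path(manifest_path)
    directory = manifest_path.parent
    out = []
    for row in read_manifest(manifest_path).itertuples(index=False):
        path = directory / row.filename
        if path.suffix == ".png":
            values = read_map_png(path, float(row.scale))
        else:
            values = read_map_txt(path)
        out.append(AttentionMap(IntensityGrid(values), participant_id=str(row.participant_id),
                                group=str(row.group), image_id=str(row.image_id),
                                stage=str(row.stage)))
    return out


def write_mask_png(path, mask: FaceMask) -> None:
    Image.fromarray(mask.mask).convert("1").save(path)


def read_mask_png(path) -> FaceMask:
    return FaceMask(np.asarray(Image.open(path).convert("1"), dtype=bool))


# -- delimited tables ---------------------------------------------------------

def write_fixations(path, fixations: Sequence[FixationEvent]) -> None:
    pd.DataFrame([{c: getattr(f, c) for c in FIXATION_COLUMNS} for f in fixations],
                 columns=FIXATION_COLUMNS).to_csv(path, index=False)


def read_fixations(path) -> list[FixationEvent]:
    df = pd.read_csv(path, float_precision="round_trip")
    return [FixationEvent(participant_id=str(r.participant_id), image_id=str(r.image_id),
                          x=int(r.x), y=int(r.y), onset_ms=float(r.onset_ms),
                          duration_ms=float(r.duration_ms))
            for r in df.itertuples(index=False)]


def write_responses(path, responses: Sequence[ResponseRecord]) -> None:
    rows = []
    for r in responses:
        row = {c: getattr(r, c) for c in RESPONSE_COLUMNS}
        if row["condition_named_correctly"] is None:
            row["condition_named_correctly"] = ""
        rows.append(row)
    pd.DataFrame(rows, columns=RESPONSE_COLUMNS).to_csv(path, index=False)


def read_responses(path) -> list[ResponseRecord]:
    df = pd.read_csv(path, keep_default_na=False)
    out = []
    for r in df.itertuples(index=False):
        named = r.condition_named_correctly
        named = None if named == "" else str(named) == "True"
        out.append(ResponseRecord(participant_id=str(r.participant_id), group=str(r.group),
                                  image_id=str(r.image_id),
                                  truth_affected=str(r.truth_affected) == "True",
                                  response_affected=str(r.response_affected) == "True",
                                  condition_named_correctly=named))
    return out


def write_aois(path, aois: Sequence[AOIRegion]) -> None:
    payload = [{"image_id": a.image_id, "name": a.name,
                "polygon": [list(p) for p in a.polygon]} for a in aois]
    Path(path).write_text(json.dumps(payload, indent=1))


def read_aois(path) -> list[AOIRegion]:
    payload = json.loads(Path(path).read_text())
    return [AOIRegion(image_id=a["image_id"], name=a["name"],
                      polygon=tuple(tuple(p) for p in a["polygon"])) for a in payload]


def write_comparisons(path, results: Sequence[ComparisonResult]) -> None:
    pd.DataFrame([{c: getattr(r, c) for c in COMPARISON_COLUMNS} for r in results],
                 columns=COMPARISON_COLUMNS).to_csv(path, index=False)


def read_comparisons(path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_meta_results(path, rows: Sequence[dict]) -> None:
    """One row per pooled analysis: pair, level, metric, pooled, se, ci, tau2, k."""
    cols = ["pair", "level", "metric", "pooled", "se", "ci_lo", "ci_hi", "tau2", "k"]
    pd.DataFrame(rows, columns=cols).to_csv(path, index=False)
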