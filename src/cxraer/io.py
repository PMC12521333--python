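"""Reading and writing images, annotations and tables.

Raw phantoms go to disk as 16-bit grayscale PNG (values rounded to the
nearest integer; the in-memory pipeline keeps float64 throughout, so disk
round-trips add at most half an intensity unit of quantization).
Normalized images are written as 32-bit float TIFF.  Annotations use one
JSON file per image; measurements and summaries are plain CSV.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import tifffile
from PIL import Image

from .datatypes import AnnotationSet, RawRadiograph
from .phantom import PhantomBundle, PhantomTruth


def write_raw_png(raw: RawRadiograph, path: str | Path) -> None:
    arr = np.rint(raw.pixels).astype(np.uint16 if raw.bit_depth == 16 else np.uint8)
    Image.fromarray(arr).save(str(path))


def read_raw_image(path: str | Path, image_id: str | None = None) -> RawRadiograph:
    """Read an 8/16-bit grayscale PNG or TIFF as a RawRadiograph."""
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        arr = tifffile.imread(str(path))
    else:
        arr = np.asarray(Image.open(str(path)))
    arr = np.asarray(arr)
    if arr.ndim != 2:
        raise ValueError(f"{path}: expected a single-channel grayscale image")
    bit_depth = 16 if arr.dtype.itemsize >= 2 else 8
    return RawRadiograph(
        image_id=image_id or path.stem, pixels=arr.astype(np.float64), bit_depth=bit_depth
    )


def write_normalized_tiff(pixels: np.ndarray, path: str | Path) -> None:
    tifffile.imwrite(str(path), np.asarray(pixels, dtype=np.float32))


def read_normalized_tiff(path: str | Path) -> np.ndarray:
    return tifffile.imread(str(path)).astype(np.float64)


def write_bundle(bundle: PhantomBundle, out_dir: str | Path) -> dict[str, Path]:
    """Write one phantom's image, annotation JSON and truth JSON."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    pid = bundle.image.image_id
    img_path = out_dir / f"{pid}.png"
    ann_path = out_dir / f"{pid}.annotations.json"
    truth_path = out_dir / f"{pid}.truth.json"
    write_raw_png(bundle.image, img_path)
    bundle.annotations.save(ann_path)
    truth_path.write_text(json.dumps(truth_to_dict(bundle.truth), indent=1))
    return {"image": img_path, "annotations": ann_path, "truth": truth_path}


def truth_to_dict(truth: PhantomTruth) -> dict:
    return {
        "segment_means": {f"{s}:{k}": v for (s, k), v in truth.segment_means.items()},
        "slopes": truth.slopes,
        "intercepts": truth.intercepts,
        "speckle_sd": {f"{s}:{k}": v for (s, k), v in truth.speckle_sd.items()},
        "lr_offset": truth.lr_offset,
    }


def truth_from_dict(d: dict) -> PhantomTruth:
    def unkey(m):
        out = {}
        for key, v in m.items():
            s, k = key.split(":")
            out[(s, int(k))] = v
        return out

    return PhantomTruth(
        segment_means=unkey(d["segment_means"]),
        slopes=dict(d["slopes"]),
        intercepts=dict(d["intercepts"]),
        speckle_sd=unkey(d["speckle_sd"]),
        lr_offset=d["lr_offset"],
    )


def load_bundle_inputs(out_dir: str | Path, image_id: str) -> tuple[RawRadiograph, AnnotationSet]:
    out_dir = Path(out_dir)
    raw = read_raw_image(out_dir / f"{image_id}.png", image_id=image_id)
    ann = AnnotationSet.load(out_dir / f"{image_id}.annotations.json")
    return raw, ann


def sha256_of(path: str | Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()
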