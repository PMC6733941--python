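"""File I/O helpers: TIFF stacks, count traces, manifests."""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile


def write_stack_tiff(path, stack) -> None:
    """Write an image stack as a multi-page 16-bit unsigned TIFF."""
    arr = np.asarray(stack)
    clipped = np.clip(np.rint(arr), 0, np.iinfo(np.uint16).max).astype(np.uint16)
    tifffile.imwrite(Path(path), clipped)


def read_stack_tiff(path) -> np.ndarray:
    return tifffile.imread(Path(path)).astype(float)


def write_counts(path, counts, bin_dt: float, meta: dict | None = None) -> None:
    """Per-bin count trace as CSV with a JSON sidecar carrying bin_dt."""
    path = Path(path)
    pd.DataFrame({"counts": np.asarray(counts)}).to_csv(path, index=False)
    sidecar = {"bin_dt": bin_dt}
    if meta:
        sidecar.update(meta)
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def read_counts(path):
    path = Path(path)
    counts = pd.read_csv(path)["counts"].to_numpy()
    sidecar = json.loads(path.with_suffix(".json").read_text())
    return counts, float(sidecar["bin_dt"]), sidecar


def sha256_file(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for block in iter(lambda: fh.read(1 << 16), b""):
            h.update(block)
    return h.hexdigest()
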