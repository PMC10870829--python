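"""Small shared helpers."""

from __future__ import annotations

import hashlib
import json
import math
from pathlib import Path


def round_sig(x: float, sig: int) -> float:
    """Round to ``sig`` significant figures (0 maps to 0)."""
    if x == 0 or not math.isfinite(x):
        return float(x)
    d = sig - 1 - math.floor(math.log10(abs(x)))
    return round(float(x), d)


def sha256_file(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def write_json(obj, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_json(path):
    with open(path, "r", encoding="utf-8") as fh:
        return json.load(fh)
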