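"""Minimal reader for Praat TextGrid point tiers.

Supports the plain-text long "TextGrid" format (UTF-8 or UTF-16 with BOM)
far enough to pull the point times out of a named point tier (class
``TextTier``), which is how syllable-nuclei timings are commonly exchanged.
Interval tiers are ignored.
"""

from __future__ import annotations

import re
from pathlib import Path

import numpy as np

__all__ = ["read_textgrid_points"]


def _decode(raw: bytes) -> str:
    if raw.startswith(b"\xff\xfe") or raw.startswith(b"\xfe\xff"):
        return raw.decode("utf-16")
    return raw.decode("utf-8-sig")


_ITEM = re.compile(r"item\s*\[\s*\d+\s*\]\s*:", re.IGNORECASE)
_CLASS = re.compile(r'class\s*=\s*"([^"]*)"')
_NAME = re.compile(r'name\s*=\s*"([^"]*)"')
_NUMBER = re.compile(r"(?:number|time)\s*=\s*([0-9.eE+-]+)")


def read_textgrid_points(path, tier_name: str | None = None) -> np.ndarray:
    """Return the sorted point times (s) of a TextGrid point tier.

    With ``tier_name`` the tier of that name is selected; otherwise the first
    point tier is used. Raises ``ValueError`` if no matching point tier
    exists.
    """
    text = _decode(Path(path).read_bytes())
    if "TextGrid" not in text.split("\n", 3)[0] and "TextGrid" not in text[:200]:
        raise ValueError(f"{path} does not look like a Praat TextGrid")
    chunks = _ITEM.split(text)
    candidates = chunks[1:] if len(chunks) > 1 else [text]
    for chunk in candidates:
        cls = _CLASS.search(chunk)
        if not cls or cls.group(1) != "TextTier":
            continue
        name = _NAME.search(chunk)
        if tier_name is not None and (name is None or name.group(1) != tier_name):
            continue
        body = chunk[cls.end():]
        # skip the tier's own xmin/xmax header values, keep the point numbers
        nums = [float(m) for m in _NUMBER.findall(body)]
        times = [t for t in nums]
        # drop the leading xmin/xmax pair when present as "number ="-free
        # headers; in the long format they are labelled xmin/xmax and are not
        # matched by _NUMBER, so nothing to drop here.
        return np.sort(np.asarray(times, dtype=float))
    raise ValueError(
        f"no point tier{f' named {tier_name!r}' if tier_name else ''} in {path}")
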