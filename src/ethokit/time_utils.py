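"""Time helpers: durations expressed in seconds.

All of ethokit stores time as seconds (floats); these helpers make call
sites read like the units they mean, e.g. ``time_window=days(1.5)``.
"""

from __future__ import annotations

import re

__all__ = ["days", "hours", "mins", "parse_duration", "parse_range", "format_duration"]

_SUFFIX_SECONDS = {"s": 1.0, "m": 60.0, "h": 3600.0, "d": 86400.0}

_DURATION_RE = re.compile(r"^\s*([+-]?\d+(?:\.\d+)?)\s*([smhd]?)\s*$")


def days(x: float) -> float:
    """Duration of *x* days, in seconds (``days(1.5) == 129600``)."""
    return 86400.0 * x


def hours(x: float) -> float:
    """Duration of *x* hours, in seconds."""
    return 3600.0 * x


def mins(x: float) -> float:
    """Duration of *x* minutes, in seconds."""
    return 60.0 * x


def parse_duration(text: str | float) -> float:
    """Parse a duration string like ``"10m"``, ``"1.5d"``, ``"30"`` into seconds.

    Bare numbers are taken as seconds. Suffixes: s, m, h, d.
    """
    if isinstance(text, (int, float)):
        return float(text)
    m = _DURATION_RE.match(text)
    if m is None:
        raise ValueError(f"cannot parse duration: {text!r}")
    value, suffix = m.groups()
    return float(value) * _SUFFIX_SECONDS.get(suffix or "s", 1.0)


def parse_range(text: str) -> tuple[float, float]:
    """Parse a period range like ``"16h:32h"`` into (seconds, seconds)."""
    parts = text.split(":")
    if len(parts) != 2:
        raise ValueError(f"range must be '<lo>:<hi>', got {text!r}")
    lo, hi = (parse_duration(p) for p in parts)
    if not lo < hi:
        raise ValueError(f"range must be increasing, got {text!r}")
    return lo, hi


def format_duration(seconds: float) -> str:
    """Human-readable duration, largest exact unit first (for logs/reports)."""
    for suffix, scale in (("d", 86400.0), ("h", 3600.0), ("m", 60.0)):
        if seconds != 0 and (2 * seconds) % scale == 0:
            return f"{seconds / scale:g}{suffix}"
    return f"{seconds:g}s"
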