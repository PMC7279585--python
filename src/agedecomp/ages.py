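"""Parsing and ordering of age-group labels.

Labels like ``"<5"``, ``"5-9"``, ``"95+"``, ``">=65"`` are understood; any
set of labels that cannot be parsed is kept in its given order.
"""
from __future__ import annotations

import re

__all__ = ["age_lower_bound", "age_midpoint", "order_age_groups"]

_RANGE = re.compile(r"^(\d+)\s*[-–]\s*(\d+)$")
_OPEN_UPPER = re.compile(r"^(?:>=\s*(\d+)|(\d+)\s*\+)$")
_OPEN_LOWER = re.compile(r"^<\s*(\d+)$")
_SINGLE = re.compile(r"^(\d+)$")


def _norm(label: str) -> str:
    return str(label).strip().replace("≥", ">=").replace("≤", "<=")


def age_lower_bound(label: str) -> float | None:
    """Lower age bound of a group label in years, or None if unparseable."""
    t = _norm(label)
    if m := _OPEN_LOWER.match(t):
        return 0.0
    if m := _RANGE.match(t):
        return float(m.group(1))
    if m := _OPEN_UPPER.match(t):
        return float(m.group(1) or m.group(2))
    if m := _SINGLE.match(t):
        return float(m.group(1))
    return None


def age_midpoint(label: str, open_width: float = 5.0) -> float | None:
    """Representative age (years) for a group; open intervals get half of
    ``open_width`` beyond their bound."""
    t = _norm(label)
    if m := _OPEN_LOWER.match(t):
        return float(m.group(1)) / 2.0
    if m := _RANGE.match(t):
        lo, hi = float(m.group(1)), float(m.group(2))
        # "5-9" means [5, 10): midpoint 7.5
        return (lo + hi + 1.0) / 2.0
    if m := _OPEN_UPPER.match(t):
        return float(m.group(1) or m.group(2)) + open_width / 2.0
    if m := _SINGLE.match(t):
        return float(m.group(1)) + open_width / 2.0
    return None


def order_age_groups(labels) -> list[str]:
    """Return labels sorted by age where parseable, else in given order."""
    labels = list(dict.fromkeys(labels))
    keys = [age_lower_bound(x) for x in labels]
    if any(k is None for k in keys):
        return labels
    return [lab for _, lab in sorted(zip(keys, labels))]
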