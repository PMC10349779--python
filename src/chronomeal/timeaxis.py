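"""Clock-time parsing and the two linear time axes used throughout.

Naive averaging of clock times fails across midnight (mean of 23:00 and
01:00 is not 12:00).  Two conventions fix this:

* the **noon-anchored axis** ``[12, 36)`` for sleep variables: a clock
  time before noon belongs to the *following* calendar day, so 01:13
  becomes 25.217.  All averaging of sleep onset/offset/midsleep happens
  on this axis.
* the **within-day axis** for eating events: an event recorded after
  midnight but before ``rollover_hour`` (default 04:00) belongs to the
  *previous* recall day and is mapped to ``hour + 24``.

Both axes are plain decimal hours, so ordinary arithmetic and weighted
means apply; results are reduced ``mod 24`` only for reporting.
"""

from __future__ import annotations

import re

import numpy as np

HHMM_RE = re.compile(r"^(\d{1,2}):(\d{2})(?::(\d{2}))?$")

#: Events with clock time below this hour count as late-night intake of
#: the previous recall day.
DEFAULT_ROLLOVER_HOUR = 4.0


def parse_clock(text: str) -> float:
    """Parse ``"HH:MM"`` (or ``"HH:MM:SS"``, or a decimal-hours string)
    into decimal hours in ``[0, 24)``.

    Raises ``ValueError`` for out-of-range or malformed input
    (e.g. ``"25:30"``).
    """
    s = str(text).strip()
    m = HHMM_RE.match(s)
    if m:
        hh, mm = int(m.group(1)), int(m.group(2))
        ss = int(m.group(3) or 0)
        if hh > 23 or mm > 59 or ss > 59:
            raise ValueError(f"clock time out of range: {text!r}")
        return hh + mm / 60 + ss / 3600
    try:
        value = float(s)
    except ValueError:
        raise ValueError(f"unparseable clock time: {text!r}") from None
    if not 0 <= value < 24:
        raise ValueError(f"decimal clock time out of [0, 24): {text!r}")
    return value


def format_clock(hours: float) -> str:
    """Format decimal hours (any axis) as ``"HH:MM"`` on the 24 h clock."""
    total_min = int(round(float(hours) * 60)) % (24 * 60)
    return f"{total_min // 60:02d}:{total_min % 60:02d}"


def to_noon_axis(clock_hours):
    """Map clock hours to the noon-anchored axis [12, 36)."""
    h = np.asarray(clock_hours, dtype=float)
    out = np.where(h < 12, h + 24, h)
    return float(out) if np.isscalar(clock_hours) or out.ndim == 0 else out


def to_day_axis(clock_hours, rollover_hour: float = DEFAULT_ROLLOVER_HOUR):
    """Map clock hours to the within-day axis (late-night -> hour+24)."""
    h = np.asarray(clock_hours, dtype=float)
    out = np.where(h < rollover_hour, h + 24, h)
    return float(out) if np.isscalar(clock_hours) or out.ndim == 0 else out


def mod24(hours):
    """Reduce axis hours back to clock hours in [0, 24) for reporting."""
    h = np.asarray(hours, dtype=float) % 24.0
    return float(h) if np.isscalar(hours) or h.ndim == 0 else h
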