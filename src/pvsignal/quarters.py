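"""FAERS quarter arithmetic ("2013Q4" .. "2025Q2") and file naming."""

from __future__ import annotations

import datetime as dt
import re

_QUARTER_RE = re.compile(r"^(\d{4})Q([1-4])$")


def parse_quarter(label: str) -> tuple[int, int]:
    m = _QUARTER_RE.match(label.strip())
    if not m:
        raise ValueError(f"malformed quarter label {label!r}; expected e.g. '2013Q4'")
    return int(m.group(1)), int(m.group(2))


def quarter_label(year: int, q: int) -> str:
    return f"{year}Q{q}"


def quarter_range(start: str, end: str) -> list[str]:
    """Inclusive list of quarter labels from *start* to *end*."""
    y0, q0 = parse_quarter(start)
    y1, q1 = parse_quarter(end)
    if (y0, q0) > (y1, q1):
        raise ValueError(f"quarter range start {start!r} is after end {end!r}")
    out = []
    y, q = y0, q0
    while (y, q) <= (y1, q1):
        out.append(quarter_label(y, q))
        q += 1
        if q == 5:
            y, q = y + 1, 1
    return out

def quarter_bounds(label: str) -> tuple[dt.date, dt.date]:
    """First and last calendar day of the quarter."""
    year, q = parse_quarter(label)
    start = dt.date(year, 3 * (q - 1) + 1, 1)
    if q == 4:
        end = dt.date(year, 12, 31)
    else:
        end = dt.date(year, 3 * q + 1, 1) - dt.timedelta(days=1)
    return start, end


def file_suffix(label: str) -> str:
    """FAERS file suffix, e.g. '2014Q1' -> '14Q1' (DEMO14Q1.txt)."""
    year, q = parse_quarter(label)
    return f"{year % 100:02d}Q{q}"
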