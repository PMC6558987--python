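"""Versioned TSV event-log dialect for one bee's session.

A log is the complete timestamped record of a session: the position of
the bee along the arm, the arm the bee is in, every shock delivered and
received (with the current that flowed), odor and light on/off events,
door events and phase markers.  Timestamps are fixed-point with
millisecond resolution, stored internally as integer ms so that
``read_log(write_log(x)) == x`` holds bit-exactly.

The format is deliberately plain TSV with a versioned header so logs
are human-auditable and diff-able::

    # beemaze-log v1
    # key=value          (optional provenance metadata)
    t\tchannel\tarm\tvalue
    0.000\tdoor\t2\tinsert
    ...
"""

from __future__ import annotations

import io
from pathlib import Path
from typing import Iterable, NamedTuple

__all__ = [
    "LOG_VERSION",
    "CHANNELS",
    "EventRecord",
    "LogFormatError",
    "write_log",
    "read_log",
    "validate_records",
]

LOG_VERSION = "1"
_MAGIC = f"# beemaze-log v{LOG_VERSION}"

#: Channels a record may use.  ``arm`` is an arm id ("1".."3") or
#: "all" for maze-wide events.
CHANNELS = frozenset(
    {
        "position",
        "arm_entry",
        "shock_delivered",
        "shock_received",
        "current",
        "odor",
        "light",
        "door",
        "phase",
    }
)

_COLUMNS = ("t", "channel", "arm", "value")


class EventRecord(NamedTuple):
    """One timestamped log event; ``t_ms`` is integer milliseconds."""

    t_ms: int
    channel: str
    arm: str
    value: str

    @property
    def t(self) -> float:
        return self.t_ms / 1000.0


class LogFormatError(ValueError):
    """Malformed or invariant-violating log content."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        where = f" (line {line})" if line is not None else ""
        super().__init__(f"{message}{where}")


def validate_records(records: Iterable[EventRecord]) -> None:
    """Check the dialect invariants on a record stream.

    Records must be time-sorted, use known channels, every received
    shock must coincide with a delivered one, and every current reading
    must accompany a received shock.
    """
    last_t = None
    delivered: set[int] = set()
    received: set[int] = set()
    for i, rec in enumerate(records):
        if rec.channel not in CHANNELS:
            raise LogFormatError(f"unknown channel {rec.channel!r}", line=i + 1)
        if last_t is not None and rec.t_ms < last_t:
            raise LogFormatError("timestamps are not monotone", line=i + 1)
        last_t = rec.t_ms
        if rec.channel == "shock_delivered":
            delivered.add(rec.t_ms)
        elif rec.channel == "shock_received":
            received.add(rec.t_ms)
            if rec.t_ms not in delivered:
                raise LogFormatError(
                    "shock_received without a delivered shock at the same time",
                    line=i + 1,
                )
        elif rec.channel == "current" and rec.t_ms not in received:
            raise LogFormatError(
                "current reading without a received shock", line=i + 1
            )


def _format_t(t_ms: int) -> str:
    sign = "-" if t_ms < 0 else ""
    t_ms = abs(t_ms)
    return f"{sign}{t_ms // 1000}.{t_ms % 1000:03d}"


def write_log(
    records: Iterable[EventRecord],
    dest,
    meta: dict[str, str] | None = None,
) -> None:
    """Write records to ``dest`` (path or text stream) as versioned TSV."""
    records = list(records)
    validate_records(records)
    own = isinstance(dest, (str, Path))
    fh = open(dest, "w", encoding="utf-8", newline="\n") if own else dest
    try:
        fh.write(_MAGIC + "\n")
        for key, val in (meta or {}).items():
            fh.write(f"# {key}={val}\n")
        fh.write("\t".join(_COLUMNS) + "\n")
        for rec in records:
            fh.write(f"{_format_t(rec.t_ms)}\t{rec.channel}\t{rec.arm}\t{rec.value}\n")
    finally:
        if own:
            fh.close()


def read_log(src, validate: bool = True) -> tuple[list[EventRecord], dict[str, str]]:
    """Read a versioned TSV log; returns (records, metadata).

    Raises :class:`LogFormatError` with a line number on any malformed
    line, a version mismatch, or (if ``validate``) broken invariants.
    """
    own = isinstance(src, (str, Path))
    fh = open(src, "r", encoding="utf-8") if own else src
    try:
        lines = fh.read().splitlines()
    finally:
        if own:
            fh.close()
    if not lines or not lines[0].startswith("# beemaze-log "):
        raise LogFormatError("missing log magic header", line=1)
    if lines[0] != _MAGIC:
        raise LogFormatError(
            f"unsupported log version {lines[0].removeprefix('# beemaze-log ')!r}",
            line=1,
        )
    meta: dict[str, str] = {}
    header_idx = 1
    while header_idx < len(lines) and lines[header_idx].startswith("#"):
        key, _, val = lines[header_idx].lstrip("# ").partition("=")
        meta[key] = val
        header_idx += 1
    if header_idx >= len(lines) or lines[header_idx] != "\t".join(_COLUMNS):
        raise LogFormatError("missing column header", line=header_idx + 1)
    records: list[EventRecord] = []
    for i, line in enumerate(lines[header_idx + 1 :], start=header_idx + 2):
        parts = line.split("\t")
        if len(parts) != 4:
            raise LogFormatError(
                f"expected 4 tab-separated fields, got {len(parts)}", line=i
            )
        t_str, channel, arm, value = parts
        try:
            if "." in t_str:
                whole, frac = t_str.split(".")
                frac = (frac + "000")[:3]
                t_ms = int(whole) * 1000 + (-1 if whole.startswith("-") else 1) * int(frac)
            else:
                t_ms = int(t_str) * 1000
        except ValueError:
            raise LogFormatError(f"bad timestamp {t_str!r}", line=i) from None
        records.append(EventRecord(t_ms, channel, arm, value))
    if validate:
        validate_records(records)
    return records, meta


def log_to_string(records: Iterable[EventRecord], meta: dict[str, str] | None = None) -> str:
    """Render records to the TSV dialect in memory."""
    buf = io.StringIO()
    write_log(records, buf, meta=meta)
    return buf.getvalue()
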