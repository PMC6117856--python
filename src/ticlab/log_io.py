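"""Session-log TSV dialect: bit-exact reader/writer and archive naming.

Layout (UTF-8, LF line endings):

* header lines ``# key<TAB>value`` — ``format_version``, ``session_id``,
  ``user_id``, ``trainer_id``, ``condition``, ``masked``, ``start_ms``,
  plus ``dro_*`` / ``ncr_*`` engine-configuration keys so a log is
  self-contained for replay;
* one body line per event: ``timestamp_ms<TAB>kind<TAB>actor<TAB>payload``
  with the payload as semicolon-joined ``key=value`` pairs (``-`` if empty).

Writing the same closed record twice produces byte-identical files, archived
as ``session_<user_id>_<end time, ISO-8601 basic UTC>.tsv``.  Unknown event
kinds are preserved on read and reported in a warnings list; structural
problems (missing header keys, non-monotone timestamps, missing
``session_end``) are hard errors that name the offending line.
Gzip-compressed archives (``.gz``) are read transparently.
"""

from __future__ import annotations

import datetime
import gzip
import io
from pathlib import Path

from .ncr import NcrConfig
from .reward_core import DroConfig, state_from_kv
from .session import EVENT_KINDS, SessionEvent, SessionRecord

__all__ = ["FORMAT_VERSION", "LogFormatError", "archive_filename", "write_log", "read_log", "format_log"]

FORMAT_VERSION = "1"

_REQUIRED_HEADER_KEYS = (
    "format_version",
    "session_id",
    "user_id",
    "trainer_id",
    "condition",
    "masked",
    "start_ms",
)

_DRO_KEYS = ("levelup_multiplier", "cap_multiplier", "interval_seconds_per_level", "medal_cost_coins")
_NCR_KEYS = ("initial_mean_interval", "points_per_reward_multiplier", "rng_seed")


class LogFormatError(ValueError):
    """Structural problem in a session log file."""


def archive_filename(record: SessionRecord) -> str:
    """Deterministic archive name carrying the session end time."""
    if record.end_ms is None:
        raise LogFormatError("cannot archive an open session")
    end = datetime.datetime.fromtimestamp(record.end_ms / 1000, tz=datetime.timezone.utc)
    return f"session_{record.user_id}_{end.strftime('%Y%m%dT%H%M%SZ')}.tsv"


def _payload_str(payload: dict[str, str]) -> str:
    if not payload:
        return "-"
    return ";".join(f"{k}={v}" for k, v in payload.items())


def _parse_payload(text: str) -> dict[str, str]:
    if text == "-" or text == "":
        return {}
    payload: dict[str, str] = {}
    for item in text.split(";"):
        key, sep, value = item.partition("=")
        if not sep:
            raise ValueError(f"malformed payload item {item!r}")
        payload[key] = value
    return payload


def format_log(record: SessionRecord, *, user_view: bool = False) -> str:
    """Render a closed record in the TSV dialect.

    With ``user_view=True`` and a masked session, the condition header is
    blanked so exports shown to participants cannot unmask the allocation.
    """
    if record.end_ms is None:
        raise LogFormatError("cannot serialize an open session")
    condition = record.condition
    if user_view and record.masked:
        condition = "masked"
    lines = [
        f"# format_version\t{FORMAT_VERSION}",
        f"# session_id\t{record.session_id}",
        f"# user_id\t{record.user_id}",
        f"# trainer_id\t{record.trainer_id}",
        f"# condition\t{condition}",
        f"# masked\t{'true' if record.masked else 'false'}",
        f"# start_ms\t{record.start_ms}",
    ]
    for key in _DRO_KEYS:
        lines.append(f"# dro_{key}\t{getattr(record.dro_config, key)}")
    if record.ncr_config is not None and not user_view:
        for key in _NCR_KEYS:
            lines.append(f"# ncr_{key}\t{getattr(record.ncr_config, key)!r}")
    for ev in record.events:
        lines.append(f"{ev.timestamp_ms}\t{ev.kind}\t{ev.actor}\t{_payload_str(ev.payload)}")
    return "\n".join(lines) + "\n"


def write_log(record: SessionRecord, destination, *, user_view: bool = False) -> Path:
    """Archive a closed record under ``destination`` and return the path."""
    dest = Path(destination)
    dest.mkdir(parents=True, exist_ok=True)
    path = dest / archive_filename(record)
    path.write_bytes(format_log(record, user_view=user_view).encode("utf-8"))
    return path


def _open_text(path: Path) -> io.TextIOBase:
    raw = path.open("rb")
    magic = raw.read(2)
    raw.seek(0)
    if path.suffix == ".gz" or magic == b"\x1f\x8b":
        return io.TextIOWrapper(gzip.GzipFile(fileobj=raw), encoding="utf-8")
    return io.TextIOWrapper(raw, encoding="utf-8")


def read_log(path) -> tuple[SessionRecord, list[str]]:
    """Parse an archived session log.

    Returns the reconstructed record plus a list of non-fatal warnings
    (e.g. unknown event kinds preserved for forward compatibility).
    Raises :class:`LogFormatError` naming the first offending line for
    structural errors.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    header: dict[str, str] = {}
    events: list[SessionEvent] = []
    warnings: list[str] = []
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("# "):
                key, sep, value = line[2:].partition("\t")
                if not sep:
                    raise LogFormatError(f"{path}:{lineno}: malformed header line {line!r}")
                header[key] = value
                continue
            parts = line.split("\t")
            if len(parts) != 4:
                raise LogFormatError(f"{path}:{lineno}: expected 4 tab-separated fields, got {len(parts)}")
            ts_raw, kind, actor, payload_raw = parts
            try:
                ts = int(ts_raw)
                payload = _parse_payload(payload_raw)
                event = SessionEvent(ts, kind, actor, payload)
            except ValueError as exc:
                raise LogFormatError(f"{path}:{lineno}: {exc}") from exc
            if kind not in EVENT_KINDS:
                warnings.append(f"{path}:{lineno}: unknown event kind {kind!r} preserved")
            if events and ts < events[-1].timestamp_ms:
                raise LogFormatError(
                    f"{path}:{lineno}: timestamp {ts} precedes previous event at {events[-1].timestamp_ms}"
                )
            events.append(event)

    missing = [k for k in _REQUIRED_HEADER_KEYS if k not in header]
    if missing:
        raise LogFormatError(f"{path}: missing header key(s): {', '.join(missing)}")
    if not events or events[0].kind != "session_start":
        raise LogFormatError(f"{path}: first event must be session_start")
    n_ends = sum(1 for ev in events if ev.kind == "session_end")
    if n_ends == 0 or events[-1].kind != "session_end":
        raise LogFormatError(f"{path}: unterminated session (no trailing session_end)")
    if n_ends > 1:
        raise LogFormatError(f"{path}: multiple session_end events")

    dro_kwargs = {}
    for key in _DRO_KEYS:
        if f"dro_{key}" in header:
            dro_kwargs[key] = int(header[f"dro_{key}"])
    ncr_config = None
    if any(f"ncr_{k}" in header for k in _NCR_KEYS):
        ncr_config = NcrConfig(
            initial_mean_interval=float(header.get("ncr_initial_mean_interval", "1.0")),
            points_per_reward_multiplier=int(header.get("ncr_points_per_reward_multiplier", "5")),
            rng_seed=int(header.get("ncr_rng_seed", "0")),
        )

    end_event = events[-1]
    try:
        final_state = state_from_kv(end_event.payload.get("final_state", ""))
    except ValueError as exc:
        raise LogFormatError(f"{path}: bad final_state in session_end: {exc}") from exc

    record = SessionRecord(
        session_id=header["session_id"],
        user_id=header["user_id"],
        trainer_id=header["trainer_id"],
        condition=header["condition"],
        masked=header["masked"] == "true",
        start_ms=int(header["start_ms"]),
        dro_config=DroConfig(**dro_kwargs),
        ncr_config=ncr_config,
        events=events,
        end_ms=end_event.timestamp_ms,
        state=final_state,
    )
    return record, warnings
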