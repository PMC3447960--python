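"""Flat key-value configuration files and provenance logging for the CLI.

Config format: one ``key = value`` pair per line, ``#`` comments; values
are parsed as int, float, or string (in that order). Command-line flags
override file values.
"""
from __future__ import annotations

import json
import logging
import sys
from datetime import datetime, timezone

from .core import RodbendError

log = logging.getLogger("rodbend")


def parse_value(raw: str):
    raw = raw.strip()
    for cast in (int, float):
        try:
            return cast(raw)
        except ValueError:
            pass
    if raw.lower() in {"true", "false"}:
        return raw.lower() == "true"
    return raw


def read_config(path) -> dict:
    out = {}
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise RodbendError(f"{path}:{ln}: expected 'key = value'")
            key, value = line.split("=", 1)
            out[key.strip()] = parse_value(value)
    return out


def merge_config(file_cfg: dict, flag_cfg: dict) -> dict:
    """Flags win over file values; None flags are ignored."""
    merged = dict(file_cfg)
    merged.update({k: v for k, v in flag_cfg.items() if v is not None})
    return merged


def setup_logging(level: str = "INFO") -> None:
    logging.basicConfig(
        level=getattr(logging, level.upper(), logging.INFO),
        format="%(asctime)s %(name)s %(levelname)s %(message)s",
        stream=sys.stderr, force=True)


def write_provenance(path, command: str, params: dict) -> None:
    """Record what produced an output: command, parameters, versions."""
    import numpy
    import scipy

    from . import __version__
    record = {
        "command": command,
        "parameters": {k: (v if isinstance(v, (int, float, str, bool, type(None)))
                           else str(v)) for k, v in params.items()},
        "timestamp": datetime.now(timezone.utc).isoformat(),
        "versions": {"rodbend": __version__, "numpy": numpy.__version__,
                     "scipy": scipy.__version__,
                     "python": sys.version.split()[0]},
    }
    with open(path, "w") as fh:
        json.dump(record, fh, indent=2)
    log.info("provenance written to %s", path)
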