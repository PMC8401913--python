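"""Flat key/value configuration files.

Format: one ``key = value`` pair per line, ``#`` starts a comment. Values
are coerced to int, float, bool, comma-separated float lists, or left as
strings. A ``seed`` key is mandatory for commands that draw random numbers.
"""

from __future__ import annotations

from pathlib import Path

from .errors import ConfigurationError

__all__ = ["parse_config", "require_seed"]


def _coerce(raw: str):
    raw = raw.strip()
    low = raw.lower()
    if low in ("true", "false"):
        return low == "true"
    if "," in raw:
        try:
            return tuple(float(part) for part in raw.split(","))
        except ValueError:
            return raw
    try:
        return int(raw)
    except ValueError:
        pass
    try:
        return float(raw)
    except ValueError:
        return raw


def parse_config(path: str | Path) -> dict:
    """Parse a flat key=value config file into a typed dict."""
    cfg: dict = {}
    text = Path(path).read_text()
    for lineno, line in enumerate(text.splitlines(), start=1):
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ConfigurationError(f"{path}:{lineno}: expected 'key = value'")
        key, _, value = line.partition("=")
        cfg[key.strip()] = _coerce(value)
    return cfg


def require_seed(cfg: dict, override: int | None = None) -> int:
    """Resolve the run seed, preferring a CLI override; error if absent."""
    if override is not None:
        return int(override)
    if "seed" not in cfg:
        raise ConfigurationError("seed is mandatory (config key 'seed' or --seed)")
    return int(cfg["seed"])
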