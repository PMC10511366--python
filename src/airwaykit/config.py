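"""Flat key=value config files mirroring the dataclass parameters."""

from __future__ import annotations

from dataclasses import fields, is_dataclass

__all__ = ["load_config", "dump_config", "dataclass_defaults"]


def _parse_value(text: str):
    text = text.strip()
    if "," in text:
        return tuple(_parse_value(t) for t in text.split(","))
    for cast in (int, float):
        try:
            return cast(text)
        except ValueError:
            pass
    if text.lower() in ("true", "false"):
        return text.lower() == "true"
    return text


def load_config(path: str) -> dict:
    """Parse ``key = value`` lines; '#' starts a comment; commas make tuples."""
    out: dict = {}
    with open(path) as fh:
        for line in fh:
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"malformed config line: {line!r}")
            key, value = line.split("=", 1)
            out[key.strip()] = _parse_value(value)
    return out


def dataclass_defaults(obj) -> dict:
    if not is_dataclass(obj):
        raise TypeError("expected a dataclass instance")
    return {f.name: getattr(obj, f.name) for f in fields(obj)}


def dump_config(obj, prefix: str = "") -> str:
    lines = []
    for key, value in dataclass_defaults(obj).items():
        if isinstance(value, (tuple, list)):
            value = ",".join(str(v) for v in value)
        lines.append(f"{prefix}{key} = {value}")
    return "\n".join(lines)
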