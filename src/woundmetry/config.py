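"""Run configuration for the command-line pipeline.

A flat key:value text format (one ``key: value`` per line, ``#``
comments) that round-trips losslessly; every field has a documented
default so an empty file is a valid configuration.
"""
from __future__ import annotations

from dataclasses import dataclass, fields
from pathlib import Path

from .exceptions import SchemaError


@dataclass
class RunConfig:
    """Defaults for the segmentation and reporting pipeline.

    inclusion_rule: how boundary triangles are charged ('all_vertices'
        never counts skin as wound; 'majority' splits the boundary).
    color_weights / color_threshold / color_polarity: the vertex color
        rule score = weights . RGB, thresholded.
    min_component_area_cm2: connected components below this are treated
        as speckle and dropped (0 keeps everything).
    label_value: which label integer marks the wound.
    decimals: rounding for the human-readable CSV outputs (the JSON
        twins always keep full precision).
    seed: seed for any synthetic generation.
    """

    inclusion_rule: str = "all_vertices"
    color_weights: tuple = (1.0, -1.0, -1.0)
    color_threshold: float = 0.0
    color_polarity: str = "above"
    min_component_area_cm2: float = 0.0
    label_value: int = 1
    decimals: int = 2
    log_level: str = "INFO"
    seed: int = 0

    def to_file(self, path) -> None:
        lines = []
        for f in fields(self):
            v = getattr(self, f.name)
            if isinstance(v, tuple):
                v = ",".join(repr(x) for x in v)
            lines.append(f"{f.name}: {v}")
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        text = Path(path).read_text()
        known = {f.name: f for f in fields(cls)}
        kwargs = {}
        for lineno, raw in enumerate(text.splitlines(), 1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if ":" not in line:
                raise SchemaError(f"{path}:{lineno}: expected 'key: value'")
            key, value = (s.strip() for s in line.split(":", 1))
            if key not in known:
                raise SchemaError(f"{path}:{lineno}: unknown config key {key!r}")
            kwargs[key] = _parse(known[key].type, value)
        return cls(**kwargs)


def _parse(type_name, value: str):
    if type_name in ("int",):
        return int(value)
    if type_name in ("float",):
        return float(value)
    if type_name in ("tuple",):
        return tuple(float(x) for x in value.split(","))
    return value
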