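"""Key=value configuration files for the reasoning pipeline.

Example::

    granular_relations = on
    out_unit = month
    dialect = us
    axioms = death_last, instantaneous
    instantaneous_types = stent_implantation, death

``axioms = instantaneous`` without an explicit type list enables the
domain's point-event types.  Lines starting with ``#`` are comments.
"""

from __future__ import annotations

from typing import Tuple

from .reasoner import DomainAxiomSet, POINT_EVENT_TYPES, ReasonerConfig
from .temporal_model import EVENT_TYPES, Granularity

__all__ = ["load_config", "parse_config"]

_TRUE = {"on", "true", "yes", "1"}
_FALSE = {"off", "false", "no", "0"}


def _parse_bool(value: str, key: str) -> bool:
    v = value.strip().lower()
    if v in _TRUE:
        return True
    if v in _FALSE:
        return False
    raise ValueError(f"config key {key!r}: expected on/off, got {value!r}")


def parse_config(text: str) -> Tuple[ReasonerConfig, DomainAxiomSet]:
    granular = True
    out_unit = Granularity.MONTH
    dialect = "us"
    death_last = False
    instantaneous = False
    inst_types = None

    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        key, sep, value = line.partition("=")
        if not sep:
            raise ValueError(f"config line {lineno}: expected key=value, got {raw!r}")
        key = key.strip().lower()
        value = value.strip()
        if key == "granular_relations":
            granular = _parse_bool(value, key)
        elif key == "out_unit":
            out_unit = Granularity.parse(value)
        elif key == "dialect":
            if value not in ("us", "intl"):
                raise ValueError(f"config key 'dialect': expected us|intl, got {value!r}")
            dialect = value
        elif key == "axioms":
            names = {v.strip() for v in value.split(",") if v.strip()}
            unknown = names - {"death_last", "instantaneous"}
            if unknown:
                raise ValueError(f"unknown axioms: {sorted(unknown)}")
            death_last = "death_last" in names
            instantaneous = "instantaneous" in names
        elif key == "instantaneous_types":
            types = {v.strip() for v in value.split(",") if v.strip()}
            unknown = types - EVENT_TYPES
            if unknown:
                raise ValueError(f"unknown event types: {sorted(unknown)}")
            inst_types = frozenset(types)
        else:
            raise ValueError(f"unknown config key {key!r}")

    if instantaneous and inst_types is None:
        inst_types = POINT_EVENT_TYPES
    axioms = DomainAxiomSet(
        death_last=death_last,
        instantaneous_event_types=inst_types if instantaneous else frozenset(),
    )
    config = ReasonerConfig(granular_relations=granular, out_unit=out_unit, dialect=dialect)
    return config, axioms


def load_config(path) -> Tuple[ReasonerConfig, DomainAxiomSet]:
    with open(path, "r", encoding="utf-8") as fh:
        return parse_config(fh.read())
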