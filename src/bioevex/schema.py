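"""Task event-schema: event types, allowed roles, filler categories.

A schema enumerates the entity types of a corpus and, for every event type,
which argument roles it accepts, which filler categories (entity types and/or
event types) each role may take, and how many fillers of the role an event
must/can have. Schemas are supplied as YAML:

.. code-block:: yaml

    entity_types: [Gene, Cancer]
    event_types:
      Expression:
        Theme: {fillers: [Gene], min: 1, max: 1}
      Regulation:
        Theme: {fillers: [Gene, Cancer, Expression, Regulation], min: 1, max: 1}
        Cause: {fillers: [Gene, Expression, Regulation], min: 0, max: 1}
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import yaml

__all__ = ["RoleSpec", "EventSchema", "SchemaError"]


class SchemaError(ValueError):
    """Raised for malformed or internally inconsistent schema configs."""


@dataclass(frozen=True)
class RoleSpec:
    fillers: frozenset[str]
    min_count: int = 0
    max_count: int = 1

    def __post_init__(self) -> None:
        if self.min_count < 0 or self.max_count < self.min_count:
            raise SchemaError(
                f"invalid role multiplicity min={self.min_count} max={self.max_count}"
            )


@dataclass
class EventSchema:
    entity_types: frozenset[str]
    event_types: dict[str, dict[str, RoleSpec]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        known = set(self.entity_types) | set(self.event_types)
        for etype, roles in self.event_types.items():
            for role, spec in roles.items():
                unknown = spec.fillers - known
                if unknown:
                    raise SchemaError(
                        f"{etype}.{role}: unknown filler categories {sorted(unknown)}"
                    )

    # -- queries ----------------------------------------------------------

    def is_event_type(self, name: str) -> bool:
        return name in self.event_types

    def roles_for(self, event_type: str) -> dict[str, RoleSpec]:
        try:
            return self.event_types[event_type]
        except KeyError:
            raise SchemaError(f"unknown event type {event_type!r}") from None

    def allows(self, event_type: str, role: str, filler_category: str) -> bool:
        spec = self.event_types.get(event_type, {}).get(role)
        return spec is not None and filler_category in spec.fillers

    @property
    def role_labels(self) -> list[str]:
        """Sorted union of all role names across event types."""
        roles: set[str] = set()
        for specs in self.event_types.values():
            roles.update(specs)
        return sorted(roles)

    @property
    def event_type_labels(self) -> list[str]:
        return sorted(self.event_types)

    def validate_args(self, event_type: str, args: list[tuple[str, str]]) -> list[str]:
        """Check a (role, filler_category) list; return human-readable violations."""
        violations: list[str] = []
        specs = self.event_types.get(event_type)
        if specs is None:
            return [f"unknown event type {event_type!r}"]
        counts: dict[str, int] = {}
        for role, category in args:
            spec = specs.get(role)
            if spec is None:
                violations.append(f"role {role!r} not allowed for {event_type}")
                continue
            if category not in spec.fillers:
                violations.append(
                    f"filler category {category!r} not allowed for {event_type}.{role}"
                )
            counts[role] = counts.get(role, 0) + 1
        for role, spec in specs.items():
            n = counts.get(role, 0)
            if n < spec.min_count or n > spec.max_count:
                violations.append(
                    f"{event_type}.{role} count {n} outside [{spec.min_count}, {spec.max_count}]"
                )
        return violations

    # -- (de)serialization -------------------------------------------------

    @classmethod
    def from_dict(cls, raw: dict) -> "EventSchema":
        try:
            entity_types = frozenset(raw["entity_types"])
            event_types: dict[str, dict[str, RoleSpec]] = {}
            for etype, roles in raw["event_types"].items():
                event_types[etype] = {
                    role: RoleSpec(
                        fillers=frozenset(spec["fillers"]),
                        min_count=int(spec.get("min", 0)),
                        max_count=int(spec.get("max", 1)),
                    )
                    for role, spec in roles.items()
                }
        except (KeyError, TypeError) as exc:
            raise SchemaError(f"malformed schema config: {exc}") from exc
        return cls(entity_types=entity_types, event_types=event_types)

    @classmethod
    def from_yaml(cls, text: str) -> "EventSchema":
        return cls.from_dict(yaml.safe_load(text))

    @classmethod
    def from_file(cls, path: str | Path) -> "EventSchema":
        return cls.from_yaml(Path(path).read_text(encoding="utf-8"))

    def to_yaml(self) -> str:
        raw = {
            "entity_types": sorted(self.entity_types),
            "event_types": {
                etype: {
                    role: {
                        "fillers": sorted(spec.fillers),
                        "min": spec.min_count,
                        "max": spec.max_count,
                    }
                    for role, spec in roles.items()
                }
                for etype, roles in self.event_types.items()
            },
        }
        return yaml.safe_dump(raw, sort_keys=True)


def default_toy_schema() -> EventSchema:
    """Small schema with one flat and one nesting event type.

    Mirrors the common biomedical motif: a Gene_expression-like flat event
    with an entity Theme, and a Regulation-like event whose Theme/Cause may
    themselves be events.
    """
    return EventSchema.from_dict(
        {
            "entity_types": ["Gene", "Cancer"],
            "event_types": {
                "Expression": {
                    "Theme": {"fillers": ["Gene"], "min": 1, "max": 1},
                },
                "Regulation": {
                    "Theme": {
                        "fillers": ["Gene", "Cancer", "Expression", "Regulation"],
                        "min": 1,
                        "max": 1,
                    },
                    "Cause": {
                        "fillers": ["Gene", "Expression", "Regulation"],
                        "min": 0,
                        "max": 1,
                    },
                },
            },
        }
    )
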