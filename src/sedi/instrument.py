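"""Instrument catalogue: items, domains, sub-domains, response kinds, polarity.

The instrument is a teacher-completed checklist of 103 scored items covering
five developmental domains, plus any number of informational (never scored)
items.  The catalogue is configuration-driven: a YAML/JSON list of item
entries is validated into an :class:`InstrumentRegistry`, and a packaged
default registry ships with the library.

Each scored item carries two coordinates: the canonical letter-prefixed
``item_id`` (the section coordinate, e.g. ``"A2"``, ``"C43"``) and an integer
``seq_id`` (a single running sequence over the whole form).  The letter
coordinate is canonical and is what roster columns are matched on.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import yaml

__all__ = [
    "DOMAINS",
    "DOMAIN_NAMES",
    "INFORMATIONAL",
    "ItemDefinition",
    "InstrumentRegistry",
    "RegistryError",
    "load_registry",
    "default_registry",
    "validate_registry",
]

#: Scored domains, in reporting order.
DOMAINS = ("PHWB", "SC", "EM", "LC", "CGK")

#: Display names for the five scored domains.
DOMAIN_NAMES = {
    "PHWB": "Physical health and wellbeing",
    "SC": "Social competence",
    "EM": "Emotional maturity",
    "LC": "Language and cognitive development",
    "CGK": "Communication and general knowledge",
}

#: Sentinel domain for items that are collected but never scored.
INFORMATIONAL = "INFORMATIONAL"

#: Expected scored-item count per domain (strict-mode contract).
EXPECTED_DOMAIN_COUNTS = {"PHWB": 13, "SC": 26, "EM": 30, "LC": 26, "CGK": 8}

RESPONSE_KINDS = ("binary", "likert3", "categorical_info")


class RegistryError(ValueError):
    """Raised for a malformed or contract-violating registry configuration."""


@dataclass(frozen=True)
class ItemDefinition:
    """One checklist item.

    Parameters
    ----------
    item_id:
        Canonical section coordinate, e.g. ``"B17"``.
    seq_id:
        Sequential alias over the whole form (second numbering system).
    domain:
        One of :data:`DOMAINS`, or :data:`INFORMATIONAL`.
    response_kind:
        ``"binary"`` (yes/no), ``"likert3"`` (never/sometimes/often), or
        ``"categorical_info"`` for informational items.
    polarity:
        ``+1`` if a higher raw category indicates better development, ``-1``
        for reverse-worded items (e.g. problem behaviours such as "is shy").
    subdomain:
        Optional sub-scale label within the item's domain.
    wording:
        Item text; the packaged default carries placeholder wordings.
    """

    item_id: str
    seq_id: int
    domain: str
    response_kind: str
    polarity: int = 1
    subdomain: str | None = None
    wording: str = ""

    @property
    def scored(self) -> bool:
        return self.domain != INFORMATIONAL


@dataclass
class InstrumentRegistry:
    """Ordered, validated collection of :class:`ItemDefinition`."""

    items: list[ItemDefinition]
    domain_labels: dict = field(default_factory=lambda: dict(DOMAIN_NAMES))

    def __post_init__(self) -> None:
        self._by_id = {it.item_id: it for it in self.items}

    def __iter__(self):
        return iter(self.items)

    def __len__(self) -> int:
        return len(self.items)

    def __getitem__(self, item_id: str) -> ItemDefinition:
        return self._by_id[item_id]

    def __contains__(self, item_id: str) -> bool:
        return item_id in self._by_id

    def __eq__(self, other) -> bool:
        return isinstance(other, InstrumentRegistry) and self.items == other.items

    @property
    def scored_items(self) -> list[ItemDefinition]:
        return [it for it in self.items if it.scored]

    def domain_items(self, domain: str) -> list[ItemDefinition]:
        return [it for it in self.items if it.domain == domain]

    @property
    def domain_counts(self) -> dict:
        counts = {d: 0 for d in DOMAINS}
        for it in self.scored_items:
            counts[it.domain] += 1
        return counts

    @property
    def subdomain_map(self) -> dict:
        out: dict[str, list[str]] = {d: [] for d in DOMAINS}
        for it in self.scored_items:
            if it.subdomain and it.subdomain not in out[it.domain]:
                out[it.domain].append(it.subdomain)
        return out

    def subdomain_items(self, domain: str, subdomain: str) -> list[ItemDefinition]:
        return [
            it
            for it in self.items
            if it.domain == domain and it.subdomain == subdomain
        ]

    def to_yaml(self) -> str:
        """Serialize to the registry-config YAML dialect (round-trippable)."""
        entries = []
        for it in self.items:
            e = {
                "item_id": it.item_id,
                "seq_id": it.seq_id,
                "domain": it.domain,
                "response_kind": it.response_kind,
                "polarity": it.polarity,
                "wording": it.wording,
            }
            if it.subdomain is not None:
                e["subdomain"] = it.subdomain
            entries.append(e)
        return yaml.safe_dump({"items": entries}, sort_keys=False)


def _parse_entry(raw: dict, index: int) -> ItemDefinition:
    for key in ("item_id", "domain", "response_kind"):
        if key not in raw:
            raise RegistryError(f"registry entry {index}: missing field {key!r}")
    domain = str(raw["domain"])
    if domain not in DOMAINS and domain != INFORMATIONAL:
        raise RegistryError(
            f"registry entry {raw['item_id']!r}: unknown domain label {domain!r}"
        )
    kind = str(raw["response_kind"])
    if kind not in RESPONSE_KINDS:
        raise RegistryError(
            f"registry entry {raw['item_id']!r}: unknown response kind {kind!r}"
        )
    polarity = int(raw.get("polarity", 1))
    if polarity not in (1, -1):
        raise RegistryError(
            f"registry entry {raw['item_id']!r}: polarity must be +1 or -1"
        )
    return ItemDefinition(
        item_id=str(raw["item_id"]),
        seq_id=int(raw.get("seq_id", index)),
        domain=domain,
        response_kind=kind,
        polarity=polarity,
        subdomain=raw.get("subdomain"),
        wording=str(raw.get("wording", "")),
    )


def load_registry(source, strict: bool = True) -> InstrumentRegistry:
    """Parse and validate a registry configuration.

    Parameters
    ----------
    source:
        YAML/JSON text, a parsed mapping ``{"items": [...]}``, or a plain
        list of item entries.
    strict:
        When true (default), the per-domain scored-item counts must match
        the instrument contract (13, 26, 30, 26, 8).

    Raises
    ------
    RegistryError
        On duplicate ids, unknown domain labels, invariant violations, or
        (in strict mode) count mismatches.
    """
    if isinstance(source, str):
        parsed = yaml.safe_load(source)
    else:
        parsed = source
    if isinstance(parsed, dict):
        entries = parsed.get("items")
    else:
        entries = parsed
    if not isinstance(entries, list):
        raise RegistryError("registry config must provide a list of item entries")

    items = [_parse_entry(e, i) for i, e in enumerate(entries)]
    reg = InstrumentRegistry(items)

    issues = validate_registry(reg, strict=strict)
    if issues:
        raise RegistryError("invalid registry: " + "; ".join(issues))
    return reg


def validate_registry(reg: InstrumentRegistry, strict: bool = True) -> list[str]:
    """Check registry invariants; return human-readable issue strings.

    An empty list means the registry satisfies every rule.  This reports and
    never raises, so it can be used to audit hand-edited configurations.
    """
    issues: list[str] = []

    seen_ids: set[str] = set()
    seen_seq: set[int] = set()
    for it in reg.items:
        if it.item_id in seen_ids:
            issues.append(f"{it.item_id}: duplicate item_id")
        seen_ids.add(it.item_id)
        if it.seq_id in seen_seq:
            issues.append(f"{it.item_id}: duplicate seq_id {it.seq_id}")
        seen_seq.add(it.seq_id)
        if it.response_kind == "categorical_info" and it.domain != INFORMATIONAL:
            issues.append(
                f"{it.item_id}: categorical_info response kind on scored domain"
                f" {it.domain}"
            )
        if it.domain == INFORMATIONAL and it.response_kind != "categorical_info":
            issues.append(
                f"{it.item_id}: informational item must have categorical_info"
                " response kind"
            )

    # sub-domain labels must not be shared across domains
    sub_owner: dict[str, str] = {}
    for it in reg.scored_items:
        if it.subdomain is None:
            continue
        owner = sub_owner.setdefault(it.subdomain, it.domain)
        if owner != it.domain:
            issues.append(
                f"{it.item_id}: subdomain {it.subdomain!r} belongs to domain"
                f" {owner}, not {it.domain}"
            )

    if strict:
        counts = reg.domain_counts
        for d, expected in EXPECTED_DOMAIN_COUNTS.items():
            if counts[d] != expected:
                issues.append(
                    f"domain {d}: {counts[d]} scored items, expected {expected}"
                )
    return issues


def default_registry() -> InstrumentRegistry:
    """The packaged default catalogue (103 scored + informational items)."""
    text = resources.files("sedi.data").joinpath("default_registry.yaml").read_text()
    return load_registry(text)
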