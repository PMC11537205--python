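"""Ordered marker-gating rules mapping stain-call vectors to cell classes.

The default table transcribes the 14-class key-stain scheme used for
multiplexed-immunofluorescence (MxIF) phenotyping of intestinal tissue:
goblets are Muc2-positive regions; every nucleus class additionally requires
the pan-nuclear DAPI stain; specific markers (CgA, Sox9/OLFM4, PanCK +
NaKATPase, CD4, CD8 ...) take precedence over lineage-generic markers (CD45,
Vimentin), so a cell is only labelled "leukocyte (other)" or "stromal
(undetermined)" when no more specific rule fires.  Evaluation is strictly
first-match-wins and the packaged order is fixed; re-ordering rules may change
outputs, which is why the table is an *ordered* list and is config-overridable.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import yaml

from .errors import ConfigurationError

UNCLASSIFIED = "unclassified"

#: Canonical names of the 14 phenotype classes, in default rule order of first
#: appearance.
CLASS_NAMES: tuple[str, ...] = (
    "goblet",
    "enteroendocrine",
    "progenitor",
    "enterocyte",
    "helper T",
    "cytotoxic T",
    "CD3d+ CD4- CD8- T",
    "B",
    "macrophage",
    "monocyte",
    "myeloid (other)",
    "leukocyte (other)",
    "fibroblast",
    "stromal (undetermined)",
)

#: The 17 gating channels (key stains), DAPI included.
GATING_CHANNELS: tuple[str, ...] = (
    "DAPI",
    "Muc2",
    "PanCK",
    "NaKATPase",
    "Sox9",
    "OLFM4",
    "CgA",
    "SMA",
    "Vimentin",
    "CD45",
    "CD20",
    "CD3d",
    "CD4",
    "CD8",
    "CD68",
    "CD11b",
    "Lysozyme",
)


@dataclass(frozen=True)
class Rule:
    """One gating rule: a class name plus required-positive / required-negative channels."""

    class_name: str
    positive: frozenset[str]
    negative: frozenset[str] = frozenset()

    def matches(self, calls: Mapping[str, bool]) -> bool:
        for ch in self.positive:
            if ch not in calls:
                raise ConfigurationError(f"rule {self.class_name!r} references uncalled channel {ch!r}")
            if not calls[ch]:
                return False
        for ch in self.negative:
            if ch not in calls:
                raise ConfigurationError(f"rule {self.class_name!r} references uncalled channel {ch!r}")
            if calls[ch]:
                return False
        return True


@dataclass
class RuleTable:
    """Ordered, first-match-wins list of gating rules.

    Two rules may share a class name (OR semantics, e.g. progenitor via Sox9
    or via OLFM4); :meth:`class_names` returns the distinct class list.
    """

    rules: list[Rule] = field(default_factory=list)

    def __iter__(self):
        return iter(self.rules)

    def __len__(self) -> int:
        return len(self.rules)

    @property
    def class_names(self) -> list[str]:
        seen: dict[str, None] = {}
        for r in self.rules:
            seen.setdefault(r.class_name, None)
        return list(seen)

    @property
    def referenced_channels(self) -> set[str]:
        chans: set[str] = set()
        for r in self.rules:
            chans |= r.positive | r.negative
        return chans

    def assign(self, calls: Mapping[str, bool]) -> str:
        """Return the class of the first matching rule, or ``"unclassified"``."""
        for rule in self.rules:
            if rule.matches(calls):
                return rule.class_name
        return UNCLASSIFIED

    # -- serialization -----------------------------------------------------

    def to_records(self) -> list[dict]:
        return [
            {
                "class": r.class_name,
                "positive": sorted(r.positive),
                "negative": sorted(r.negative),
            }
            for r in self.rules
        ]

    @classmethod
    def from_records(cls, records: Iterable[Mapping]) -> "RuleTable":
        rules = [
            Rule(
                class_name=rec["class"],
                positive=frozenset(rec.get("positive", ())),
                negative=frozenset(rec.get("negative", ())),
            )
            for rec in records
        ]
        return cls(rules)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_records(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RuleTable":
        return cls.from_records(yaml.safe_load(Path(path).read_text()))

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_records(), indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "RuleTable":
        return cls.from_records(json.loads(Path(path).read_text()))


def default_rule_table(
    enterocyte_operator: str = "and",
    double_positive_policy: str = "first_match",
) -> RuleTable:
    """Build the packaged default 14-class rule table.

    Parameters
    ----------
    enterocyte_operator
        ``"and"`` (default) requires PanCK and NaKATPase jointly; ``"or"``
        encodes them as two adjacent rules.
    double_positive_policy
        ``"first_match"`` lets CD4+CD8+ T cells resolve by rule order (to
        helper T); ``"demote_to_parent"`` sends them to the generic
        ``"CD3d+ CD4- CD8- T"`` label instead.
    """
    if enterocyte_operator not in ("and", "or"):
        raise ConfigurationError(f"unknown enterocyte_operator {enterocyte_operator!r}")
    if double_positive_policy not in ("first_match", "demote_to_parent"):
        raise ConfigurationError(f"unknown double_positive_policy {double_positive_policy!r}")

    R = Rule
    f = frozenset
    rules: list[Rule] = [
        R("goblet", f({"Muc2"})),
        R("enteroendocrine", f({"DAPI", "CgA"})),
        R("progenitor", f({"DAPI", "Sox9"})),
        R("progenitor", f({"DAPI", "OLFM4"})),
    ]
    if enterocyte_operator == "and":
        rules.append(R("enterocyte", f({"DAPI", "PanCK", "NaKATPase"})))
    else:
        rules.append(R("enterocyte", f({"DAPI", "PanCK"})))
        rules.append(R("enterocyte", f({"DAPI", "NaKATPase"})))
    if double_positive_policy == "demote_to_parent":
        rules.append(R("CD3d+ CD4- CD8- T", f({"DAPI", "CD3d", "CD4", "CD8"})))
    # pure cascade: order performs the CD4/CD8 exclusion, so a CD4+CD8+
    # double positive resolves to helper T under the default policy
    rules += [
        R("helper T", f({"DAPI", "CD3d", "CD4"})),
        R("cytotoxic T", f({"DAPI", "CD3d", "CD8"})),
        R("CD3d+ CD4- CD8- T", f({"DAPI", "CD3d"})),
        R("B", f({"DAPI", "CD20"})),
        R("macrophage", f({"DAPI", "CD68"})),
        R("monocyte", f({"DAPI", "CD11b"})),
        R("myeloid (other)", f({"DAPI", "Lysozyme"})),
        R("leukocyte (other)", f({"DAPI", "CD45"})),
        R("fibroblast", f({"DAPI", "SMA"})),
        R("stromal (undetermined)", f({"DAPI", "Vimentin"})),
    ]
    return RuleTable(rules)


def count_rule_classes(rules: RuleTable) -> tuple[int, int]:
    """Return (number of distinct classes, number of distinct key stains referenced)."""
    return len(rules.class_names), len(rules.referenced_channels)
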