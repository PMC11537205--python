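"""Fine-to-parent class mapping for label-granularity-mismatch evaluation.

Fine-grained phenotype labels (helper T, enterocyte, ...) often have to be
scored against datasets annotated only with coarser parent classes
(lymphocyte, epithelial, connective ...).  A :class:`ClassMapping` records the
fine -> parent map plus the fine classes that have no counterpart at all in the
coarse vocabulary and are simply dropped from such an evaluation (goblet: the
coarse nucleus-only label sets contain no goblet regions).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

from .errors import MappingError

#: Six-name parent vocabulary used by the synthetic coarse-labeled sets.
#: "plasma" is part of the vocabulary but receives no fine class by default.
PARENT_CLASSES: tuple[str, ...] = (
    "epithelial",
    "lymphocyte",
    "connective",
    "myeloid",
    "leukocyte",
    "plasma",
)


@dataclass
class ClassMapping:
    """Total map from fine class names to parent class names, plus drops."""

    parent_of: dict[str, str]
    droppable: frozenset[str] = frozenset()

    def parent(self, fine_class: str) -> str:
        if fine_class in self.droppable:
            raise MappingError(f"class {fine_class!r} is droppable, not mapped")
        try:
            return self.parent_of[fine_class]
        except KeyError:
            raise MappingError(f"fine class {fine_class!r} is neither mapped nor droppable") from None

    def covers(self, fine_class: str) -> bool:
        return fine_class in self.parent_of or fine_class in self.droppable

    def siblings(self, fine_class: str) -> set[str]:
        """Fine classes (other than ``fine_class``) sharing its parent."""
        p = self.parent(fine_class)
        return {c for c, q in self.parent_of.items() if q == p and c != fine_class}

    @property
    def parents(self) -> set[str]:
        return set(self.parent_of.values())

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps({"parent_of": self.parent_of, "droppable": sorted(self.droppable)}, indent=2)
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "ClassMapping":
        payload = json.loads(Path(path).read_text())
        return cls(dict(payload["parent_of"]), frozenset(payload.get("droppable", ())))

    @classmethod
    def identity(cls, classes: Iterable[str]) -> "ClassMapping":
        return cls({c: c for c in classes})


def default_class_mapping() -> ClassMapping:
    """Default fine -> parent mapping.

    The five anchor pairs are helper T -> lymphocyte, enterocyte -> epithelial,
    progenitor -> epithelial, fibroblast -> connective and
    stromal (undetermined) -> connective; the remaining fine classes get their
    biologically natural parent, and goblet is droppable because nucleus-only
    coarse label sets have nothing for a goblet region to match.
    """
    return ClassMapping(
        parent_of={
            "helper T": "lymphocyte",
            "cytotoxic T": "lymphocyte",
            "CD3d+ CD4- CD8- T": "lymphocyte",
            "B": "lymphocyte",
            "enterocyte": "epithelial",
            "progenitor": "epithelial",
            "enteroendocrine": "epithelial",
            "fibroblast": "connective",
            "stromal (undetermined)": "connective",
            "macrophage": "myeloid",
            "monocyte": "myeloid",
            "myeloid (other)": "myeloid",
            "leukocyte (other)": "leukocyte",
        },
        droppable=frozenset({"goblet"}),
    )
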