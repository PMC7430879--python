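"""Core record types and controlled vocabularies.

Every interaction in the curated network is a directional edge annotated with
one of eight effects; every node belongs to one of five component classes.
Both vocabularies are closed by default: curation quality control depends on
rejecting terms outside them.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

#: The eight interaction effects. Positive: activate, recruit, promote
#: survival. Negative: inhibit, kill. Production: secrete. Fate: differentiate,
#: polarize.
EDGE_EFFECTS: frozenset[str] = frozenset(
    {
        "activate",
        "recruit",
        "promote survival",
        "inhibit",
        "kill",
        "secrete",
        "differentiate",
        "polarize",
    }
)

#: The five node classes of the curated network.
NODE_TYPES: frozenset[str] = frozenset(
    {"cell", "cytokine", "antibody", "effector molecule", "antigen"}
)

#: Species-specificity values allowed on nodes and edges.
SPECIES_VALUES: frozenset[str] = frozenset({"mouse", "human", "both"})


class SchemaError(ValueError):
    """A required column is missing from an input table."""


class VocabularyError(ValueError):
    """A value falls outside a closed controlled vocabulary."""


@dataclass
class EdgeRecord:
    """One curated directional interaction.

    ``source_node`` acts on ``target_node`` with ``edge_effect``; ``reference``
    records where in the source text the interaction was described. Optional
    annotations (receptor, activation states, product, immune process,
    anatomical location, proliferation outcome, species specificity) are kept
    when curated. Columns outside the known schema survive in ``extras``.
    """

    source_node: str
    target_node: str
    edge_effect: str
    reference: str = ""
    receptor: Optional[str] = None
    source_state: Optional[str] = None
    target_state: Optional[str] = None
    product: Optional[str] = None
    immune_process: Optional[str] = None
    location: Optional[str] = None
    proliferation: Optional[str] = None
    species_specificity: Optional[str] = None
    extras: dict = field(default_factory=dict)

    #: annotation fields merged during deduplication
    OPTIONAL_FIELDS = (
        "receptor",
        "source_state",
        "target_state",
        "product",
        "immune_process",
        "location",
        "proliferation",
        "species_specificity",
    )

    @property
    def key(self) -> tuple[str, str, str]:
        """The (source, target, effect) triple identifying a unique interaction."""
        return (self.source_node, self.target_node, self.edge_effect)

    def copy(self) -> "EdgeRecord":
        return replace(self, extras=dict(self.extras))


@dataclass
class NodeRecord:
    """One immune system component with its curated attributes."""

    name: str
    node_type: str
    subtype: str = ""
    species_specificity: Optional[str] = None
    ontology_link: Optional[str] = None
    extras: dict = field(default_factory=dict)

    def copy(self) -> "NodeRecord":
        return replace(self, extras=dict(self.extras))


@dataclass
class SpeciesDifferenceRecord:
    """One curated mouse/human difference.

    Categories: 1 — same component, different form/function/copy number;
    2 — different components with equivalent function; 3 — same component,
    different levels or expression pattern; 4 — no equivalent in one species.
    """

    description: str
    category: int
    affected_nodes: list[str]
    immune_process: str = ""
    reference: str = ""

    def __post_init__(self) -> None:
        if self.category not in (1, 2, 3, 4):
            raise VocabularyError(
                f"species-difference category must be 1-4, got {self.category!r}"
            )
        if not self.affected_nodes:
            raise ValueError("a species difference must name at least one node")
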