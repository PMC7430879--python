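"""Reading, validating, canonicalizing and deduplicating curated network tables.

The curated tables are UTF-8 CSV files with a header row. Column names are
matched case-insensitively through a configurable alias map so that minor
header variants ("Source Node", "source", "source_node") all resolve to the
same field. Loading preserves row order; unknown columns are kept as
per-record extras so nothing curated is silently dropped.
"""

from __future__ import annotations

import io
import json
import re
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

import pandas as pd

from .records import (
    EDGE_EFFECTS,
    NODE_TYPES,
    SPECIES_VALUES,
    EdgeRecord,
    NodeRecord,
    SchemaError,
    VocabularyError,
)

Source = Union[str, Path, io.IOBase]

# canonical field -> accepted header spellings (lower-cased, punctuation-light)
EDGE_COLUMN_ALIASES: dict[str, tuple[str, ...]] = {
    "source_node": ("source_node", "source node", "source", "from"),
    "target_node": ("target_node", "target node", "target", "to"),
    "edge_effect": ("edge_effect", "edge effect", "effect", "interaction type"),
    "reference": ("reference", "source text reference", "text reference", "citation"),
    "receptor": ("receptor", "receptors"),
    "source_state": ("source_state", "source state", "source activation state"),
    "target_state": ("target_state", "target state", "target activation state"),
    "product": ("product", "products"),
    "immune_process": ("immune_process", "immune process", "process"),
    "location": ("location", "anatomical location", "site"),
    "proliferation": ("proliferation", "proliferation of target"),
    "species_specificity": ("species_specificity", "species specificity", "species"),
}

NODE_COLUMN_ALIASES: dict[str, tuple[str, ...]] = {
    "name": ("name", "node", "node name"),
    "node_type": ("node_type", "node type", "type"),
    "subtype": ("subtype", "sub type", "sub-type"),
    "species_specificity": ("species_specificity", "species specificity", "species"),
    "ontology_link": ("ontology_link", "ontology link", "ontology", "external id"),
}

EDGE_REQUIRED = ("source_node", "target_node", "edge_effect", "reference")
NODE_REQUIRED = ("name", "node_type", "subtype")


def _normalize_header(name: str) -> str:
    return re.sub(r"[\s_\-]+", " ", str(name)).strip().lower()


def _resolve_columns(
    columns: Sequence[str],
    aliases: dict[str, tuple[str, ...]],
    required: Sequence[str],
    table: str,
) -> tuple[dict[str, str], list[str]]:
    """Map canonical field -> actual column; return also unmapped columns."""
    lookup: dict[str, str] = {}
    for canon, names in aliases.items():
        for alt in names:
            lookup[_normalize_header(alt)] = canon
    mapping: dict[str, str] = {}
    unknown: list[str] = []
    for col in columns:
        canon = lookup.get(_normalize_header(col))
        if canon is not None and canon not in mapping:
            mapping[canon] = col
        else:
            unknown.append(col)
    missing = [f for f in required if f not in mapping]
    if missing:
        raise SchemaError(
            f"{table} table is missing required column(s): {', '.join(missing)}"
        )
    return mapping, unknown


def _read_csv(source: Source) -> pd.DataFrame:
    try:
        return pd.read_csv(source, dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError:
        return pd.DataFrame()


def _opt(value: str) -> Optional[str]:
    value = value.strip()
    return value or None


def load_network_tables(
    edge_table_source: Source,
    node_table_source: Source,
    *,
    strict_vocabulary: bool = True,
) -> tuple[list[EdgeRecord], list[NodeRecord]]:
    """Load curated edge and node tables.

    Returns one :class:`EdgeRecord` per edge-table data row and one
    :class:`NodeRecord` per node-table row, in file order. Unknown columns are
    preserved per record in ``extras``. With ``strict_vocabulary`` (the
    default), an edge effect outside the eight-term vocabulary or a node type
    outside the five classes raises :class:`VocabularyError` naming the
    offending 0-based data-row index.
    """
    edges = load_edge_table(edge_table_source, strict_vocabulary=strict_vocabulary)
    nodes = load_node_table(node_table_source, strict_vocabulary=strict_vocabulary)
    return edges, nodes


def load_edge_table(source: Source, *, strict_vocabulary: bool = True) -> list[EdgeRecord]:
    df = _read_csv(source)
    if df.empty and df.columns.empty:
        return []
    mapping, unknown = _resolve_columns(
        df.columns, EDGE_COLUMN_ALIASES, EDGE_REQUIRED, "edge"
    )
    records: list[EdgeRecord] = []
    for i, row in enumerate(df.itertuples(index=False)):
        row = dict(zip(df.columns, row))
        effect = str(row[mapping["edge_effect"]]).strip()
        if strict_vocabulary and effect not in EDGE_EFFECTS:
            raise VocabularyError(
                f"row {i}: unknown edge effect {effect!r} "
                f"(expected one of {sorted(EDGE_EFFECTS)})"
            )
        rec = EdgeRecord(
            source_node=str(row[mapping["source_node"]]).strip(),
            target_node=str(row[mapping["target_node"]]).strip(),
            edge_effect=effect,
            reference=str(row[mapping["reference"]]).strip(),
            extras={c: row[c] for c in unknown},
        )
        for fld in EdgeRecord.OPTIONAL_FIELDS:
            if fld in mapping:
                setattr(rec, fld, _opt(str(row[mapping[fld]])))
        records.append(rec)
    return records


def load_node_table(source: Source, *, strict_vocabulary: bool = True) -> list[NodeRecord]:
    df = _read_csv(source)
    if df.empty and df.columns.empty:
        return []
    mapping, unknown = _resolve_columns(
        df.columns, NODE_COLUMN_ALIASES, NODE_REQUIRED, "node"
    )
    records: list[NodeRecord] = []
    for i, row in enumerate(df.itertuples(index=False)):
        row = dict(zip(df.columns, row))
        node_type = str(row[mapping["node_type"]]).strip().lower()
        if strict_vocabulary and node_type not in NODE_TYPES:
            raise VocabularyError(
                f"row {i}: unknown node type {node_type!r} "
                f"(expected one of {sorted(NODE_TYPES)})"
            )
        rec = NodeRecord(
            name=str(row[mapping["name"]]).strip(),
            node_type=node_type,
            subtype=str(row[mapping["subtype"]]).strip(),
            extras={c: row[c] for c in unknown},
        )
        for fld in ("species_specificity", "ontology_link"):
            if fld in mapping:
                setattr(rec, fld, _opt(str(row[mapping[fld]])))
        records.append(rec)
    return records


def write_edge_table(records: Iterable[EdgeRecord], path: Union[str, Path]) -> None:
    """Write edge records as CSV in the dialect :func:`load_edge_table` reads."""
    rows = []
    for r in records:
        row = {
            "source_node": r.source_node,
            "target_node": r.target_node,
            "edge_effect": r.edge_effect,
            "reference": r.reference,
        }
        for fld in EdgeRecord.OPTIONAL_FIELDS:
            row[fld] = getattr(r, fld) or ""
        row.update(r.extras)
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def write_node_table(records: Iterable[NodeRecord], path: Union[str, Path]) -> None:
    rows = []
    for r in records:
        row = {
            "name": r.name,
            "node_type": r.node_type,
            "subtype": r.subtype,
            "species_specificity": r.species_specificity or "",
            "ontology_link": r.ontology_link or "",
        }
        row.update(r.extras)
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def deduplicate_edges(records: Sequence[EdgeRecord]) -> list[EdgeRecord]:
    """Merge repeated mentions of the same interaction.

    Uniqueness is the (source, target, effect) triple. The retained record is
    the first mention, carrying the union of optional annotations (first
    non-empty value wins per field) and the "; "-joined references of all
    merged mentions. Output order is first-occurrence order. Idempotent.
    """
    merged: dict[tuple[str, str, str], EdgeRecord] = {}
    for rec in records:
        kept = merged.get(rec.key)
        if kept is None:
            merged[rec.key] = rec.copy()
            continue
        if rec.reference and rec.reference not in kept.reference.split("; "):
            kept.reference = (
                f"{kept.reference}; {rec.reference}" if kept.reference else rec.reference
            )
        for fld in EdgeRecord.OPTIONAL_FIELDS:
            if getattr(kept, fld) is None and getattr(rec, fld) is not None:
                setattr(kept, fld, getattr(rec, fld))
        for k, v in rec.extras.items():
            kept.extras.setdefault(k, v)
    return list(merged.values())


@dataclass
class Finding:
    """One quality-control finding."""

    severity: str  # "error" | "warning"
    rule: str
    index: Optional[int]
    message: str


@dataclass
class ValidationReport:
    """Outcome of the curation sense checks. Passes iff no error findings."""

    findings: list[Finding] = field(default_factory=list)

    @property
    def errors(self) -> list[Finding]:
        return [f for f in self.findings if f.severity == "error"]

    @property
    def warnings(self) -> list[Finding]:
        return [f for f in self.findings if f.severity == "warning"]

    @property
    def passed(self) -> bool:
        return not self.errors

    def to_json(self) -> str:
        return json.dumps(
            {
                "passed": self.passed,
                "n_errors": len(self.errors),
                "n_warnings": len(self.warnings),
                "findings": [vars(f) for f in self.findings],
            },
            indent=2,
        )

    def __str__(self) -> str:
        lines = [f"validation: {'PASS' if self.passed else 'FAIL'} "
                 f"({len(self.errors)} errors, {len(self.warnings)} warnings)"]
        for f in self.findings:
            where = f"record {f.index}" if f.index is not None else "table"
            lines.append(f"  [{f.severity}] {f.rule} @ {where}: {f.message}")
        return "\n".join(lines)


def _rule_endpoints_exist(edges, nodes, node_types):  # R1
    names = set(node_types)
    out = []
    for i, e in enumerate(edges):
        for endpoint in (e.source_node, e.target_node):
            if endpoint not in names:
                out.append(Finding(
                    "error", "R1", i,
                    f"edge endpoint {endpoint!r} absent from node table"))
    return out


def _rule_secretion_sense(edges, nodes, node_types):  # R2
    # A cell cannot be secreted, and only cells secrete.
    out = []
    for i, e in enumerate(edges):
        if e.edge_effect != "secrete":
            continue
        if node_types.get(e.target_node) == "cell":
            out.append(Finding(
                "error", "R2", i,
                f"nonsensical edge: secretion of a cell ({e.target_node!r})"))
        src_type = node_types.get(e.source_node)
        if src_type is not None and src_type != "cell":
            out.append(Finding(
                "error", "R2", i,
                f"secrete edge from non-cell source {e.source_node!r} "
                f"(type {src_type!r})"))
    return out


def _rule_duplicate_nodes(edges, nodes, node_types):  # R3
    seen: dict[str, int] = {}
    out = []
    for i, n in enumerate(nodes):
        if n.name in seen:
            out.append(Finding(
                "error", "R3", i,
                f"duplicate node name {n.name!r} (first at record {seen[n.name]})"))
        else:
            seen[n.name] = i
    return out


def _rule_isolated_nodes(edges, nodes, node_types):  # R4
    touched = {e.source_node for e in edges} | {e.target_node for e in edges}
    return [
        Finding("warning", "R4", i, f"node {n.name!r} participates in no edge")
        for i, n in enumerate(nodes)
        if n.name not in touched
    ]


def _rule_self_loops(edges, nodes, node_types):  # R5
    return [
        Finding("warning", "R5", i,
                f"self-interaction {e.source_node!r} -> itself ({e.edge_effect})")
        for i, e in enumerate(edges)
        if e.source_node == e.target_node
    ]


DEFAULT_RULES = {
    "R1": _rule_endpoints_exist,
    "R2": _rule_secretion_sense,
    "R3": _rule_duplicate_nodes,
    "R4": _rule_isolated_nodes,
    "R5": _rule_self_loops,
}


def validate_network(
    edges: Sequence[EdgeRecord],
    nodes: Sequence[NodeRecord],
    rules: Optional[dict] = None,
) -> ValidationReport:
    """Run curation sense checks; problems are reported, never thrown.

    Default rule set: R1 every edge endpoint exists in the node table (error);
    R2 "secrete" requires a cell-type source and a non-cell target (error);
    R3 duplicate node names (error); R4 isolated nodes (warning); R5
    self-interactions (warning). Pass ``rules`` as ``{id: callable or None}``
    to add custom rules or disable defaults (value ``None`` drops a rule).
    """
    active = dict(DEFAULT_RULES)
    if rules:
        for rid, fn in rules.items():
            if fn is None:
                active.pop(rid, None)
            else:
                active[rid] = fn
    node_types = {n.name: n.node_type for n in nodes}
    report = ValidationReport()
    for rid in sorted(active):
        report.findings.extend(active[rid](edges, nodes, node_types))
    return report


class OntologyMap:
    """Raw-term -> canonical-term mappings, partitioned by domain.

    Domains separate node names from immune-process, location and disease
    terms so an alias in one namespace never rewrites another. Each raw term
    maps to exactly one canonical term within its domain; a conflicting
    second mapping is a configuration error.
    """

    DOMAINS = ("node", "immune_process", "location", "disease")

    def __init__(self, mappings: Optional[dict[str, dict[str, str]]] = None):
        self._maps: dict[str, dict[str, str]] = {d: {} for d in self.DOMAINS}
        if mappings:
            for domain, pairs in mappings.items():
                for raw, canonical in pairs.items():
                    self.add(raw, canonical, domain=domain)

    def add(self, raw: str, canonical: str, domain: str = "node") -> None:
        if domain not in self._maps:
            raise ValueError(f"unknown ontology domain {domain!r}")
        raw, canonical = raw.strip(), canonical.strip()
        existing = self._maps[domain].get(raw)
        if existing is not None and existing != canonical:
            raise ValueError(
                f"conflicting ontology mappings for {raw!r} in domain {domain!r}: "
                f"{existing!r} vs {canonical!r}"
            )
        self._maps[domain][raw] = canonical

    def canonical(self, term: str, domain: str = "node") -> str:
        term = term.strip()
        return self._maps[domain].get(term, term)

    def __contains__(self, term: str) -> bool:
        return any(term.strip() in m for m in self._maps.values())

    def __len__(self) -> int:
        return sum(len(m) for m in self._maps.values())

    @classmethod
    def from_csv(cls, source: Source, domain_column: str = "domain") -> "OntologyMap":
        """Read a (raw, canonical[, domain]) CSV; domain defaults to "node"."""
        df = _read_csv(source)
        om = cls()
        if df.empty:
            return om
        cols = {_normalize_header(c): c for c in df.columns}
        raw_col = cols.get("raw") or df.columns[0]
        canon_col = cols.get("canonical") or df.columns[1]
        dom_col = cols.get(_normalize_header(domain_column))
        for _, row in df.iterrows():
            domain = str(row[dom_col]).strip() if dom_col else "node"
            om.add(str(row[raw_col]), str(row[canon_col]), domain=domain or "node")
        return om

    @classmethod
    def from_xml(cls, source: Source) -> "OntologyMap":
        """Minimal XML reader: any element with raw/canonical attributes or
        <raw>/<canonical> children, with an optional domain attribute."""
        tree = ET.parse(source)
        om = cls()
        for elem in tree.iter():
            raw = elem.get("raw")
            canonical = elem.get("canonical")
            if raw is None or canonical is None:
                raw_el = elem.find("raw")
                canon_el = elem.find("canonical")
                if raw_el is None or canon_el is None:
                    continue
                raw, canonical = raw_el.text or "", canon_el.text or ""
            domain = elem.get("domain", "node")
            om.add(raw, canonical, domain=domain)
        return om


def canonicalize_names(
    edges: Sequence[EdgeRecord],
    nodes: Sequence[NodeRecord],
    ontology: OntologyMap,
) -> tuple[list[EdgeRecord], list[NodeRecord], list[str]]:
    """Rewrite node names (and immune-process/location terms) to canonical form.

    Matching is exact and case-sensitive after whitespace trimming. Names
    absent from the ontology pass through unchanged and are returned in the
    unmapped-name report (sorted, unique).
    """
    unmapped: set[str] = set()

    def canon_name(name: str) -> str:
        name = name.strip()
        out = ontology.canonical(name, "node")
        if out == name and name not in ontology:
            unmapped.add(name)
        return out

    new_edges = []
    for e in edges:
        e = e.copy()
        e.source_node = canon_name(e.source_node)
        e.target_node = canon_name(e.target_node)
        if e.product:
            e.product = canon_name(e.product)
        if e.immune_process:
            e.immune_process = ontology.canonical(e.immune_process, "immune_process")
        if e.location:
            e.location = ontology.canonical(e.location, "location")
        new_edges.append(e)
    new_nodes = []
    for n in nodes:
        n = n.copy()
        n.name = canon_name(n.name)
        new_nodes.append(n)
    return new_edges, new_nodes, sorted(unmapped)
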