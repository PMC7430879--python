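"""Mouse/human species-difference catalog: loading, summaries, node overlay.

Each catalog row is one curated difference between the mouse and human immune
systems, classified into categories 1-4 (1: same component, different
form/function/copy number; 2: different components, equivalent function;
3: different levels/expression; 4: no equivalent in one species) and
annotated with the affected network nodes and immune process.
"""

from __future__ import annotations

import io
import re
from pathlib import Path
from typing import Sequence, Union

import pandas as pd

from .graph_stats import ImmuneNetwork
from .records import SpeciesDifferenceRecord, SchemaError, VocabularyError

Source = Union[str, Path, io.IOBase]

_CATALOG_ALIASES = {
    "description": ("description", "difference", "difference description"),
    "category": ("category", "difference category", "class"),
    "affected_nodes": ("affected_nodes", "affected nodes", "nodes", "node",
                       "nodes involved", "node or nodes involved"),
    "immune_process": ("immune_process", "immune process", "process"),
    "reference": ("reference", "citation", "source", "page"),
}


def load_difference_catalog(
    source: Source,
    *,
    node_delimiter: str = ";",
) -> list[SpeciesDifferenceRecord]:
    """Load the species-difference catalog CSV, one record per row.

    ``category`` must parse as an integer in 1-4 (otherwise a
    :class:`VocabularyError` naming the 0-based row); multi-node cells are
    split on ``node_delimiter``.
    """
    try:
        df = pd.read_csv(source, dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError:
        return []
    if df.columns.empty:
        return []
    norm = {re.sub(r"[\s_\-]+", " ", c).strip().lower(): c for c in df.columns}
    mapping: dict[str, str] = {}
    for canon, alts in _CATALOG_ALIASES.items():
        for alt in alts:
            if alt.replace("_", " ") in norm:
                mapping[canon] = norm[alt.replace("_", " ")]
                break
    for required in ("description", "category", "affected_nodes"):
        if required not in mapping:
            raise SchemaError(
                f"difference catalog is missing required column: {required}"
            )
    records: list[SpeciesDifferenceRecord] = []
    for i, row in df.iterrows():
        raw_cat = str(row[mapping["category"]]).strip()
        try:
            category = int(raw_cat)
        except ValueError:
            raise VocabularyError(f"row {i}: category {raw_cat!r} is not an integer")
        if category not in (1, 2, 3, 4):
            raise VocabularyError(f"row {i}: category must be 1-4, got {category}")
        nodes = [
            n.strip()
            for n in str(row[mapping["affected_nodes"]]).split(node_delimiter)
            if n.strip()
        ]
        if not nodes:
            raise VocabularyError(f"row {i}: no affected nodes listed")
        records.append(
            SpeciesDifferenceRecord(
                description=str(row[mapping["description"]]).strip(),
                category=category,
                affected_nodes=nodes,
                immune_process=str(row.get(mapping.get("immune_process", ""), "")).strip()
                if "immune_process" in mapping else "",
                reference=str(row.get(mapping.get("reference", ""), "")).strip()
                if "reference" in mapping else "",
            )
        )
    return records


def write_difference_catalog(
    records: Sequence[SpeciesDifferenceRecord],
    path: Union[str, Path],
    *,
    node_delimiter: str = ";",
) -> None:
    pd.DataFrame(
        [
            {
                "description": r.description,
                "category": r.category,
                "affected_nodes": node_delimiter.join(r.affected_nodes),
                "immune_process": r.immune_process,
                "reference": r.reference,
            }
            for r in records
        ]
    ).to_csv(path, index=False)


def category_summary(records: Sequence[SpeciesDifferenceRecord]) -> dict[int, int]:
    """Counts per category 1-4; values sum to the record count."""
    counts = {1: 0, 2: 0, 3: 0, 4: 0}
    for r in records:
        counts[r.category] += 1
    return counts


def node_difference_overlay(
    net: ImmuneNetwork,
    records: Sequence[SpeciesDifferenceRecord],
) -> tuple[pd.DataFrame, list[str]]:
    """Per-node difference counts and per-category fractions.

    Each record contributes 1 to every node it affects. Network nodes absent
    from the catalog get 0. Catalog node names that do not map onto network
    nodes (e.g. an unspecified-T-cell aggregate) are kept as overlay-only
    rows flagged ``in_network=False`` and also returned in the unmatched
    report. Rows sorted by descending count, then name.
    """
    counts: dict[str, dict[int, int]] = {}
    for r in records:
        for node in r.affected_nodes:
            per = counts.setdefault(node, {1: 0, 2: 0, 3: 0, 4: 0})
            per[r.category] += 1
    rows = []
    unmatched = sorted(n for n in counts if not net.has_node(n))
    for node in net.nodes:
        per = counts.get(node, {1: 0, 2: 0, 3: 0, 4: 0})
        rows.append((node, True, per))
    for node in unmatched:
        rows.append((node, False, counts[node]))
    out = []
    for node, in_net, per in rows:
        total = sum(per.values())
        out.append({
            "node": node,
            "in_network": in_net,
            "count": total,
            **{
                f"frac_cat{c}": (per[c] / total if total else 0.0)
                for c in (1, 2, 3, 4)
            },
        })
    df = pd.DataFrame(out).sort_values(
        ["count", "node"], ascending=[False, True]
    ).reset_index(drop=True)
    return df, unmatched
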