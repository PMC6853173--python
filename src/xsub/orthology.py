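"""Human <-> mouse gene mapping under the highest-homology rule.

One-to-many orthologue relations are resolved by keeping, for each source
gene, the partner with the highest homology percentage; ties at equal
homology are broken by ascending partner gene id so the mapping is
deterministic.  Genes without a partner are reported, never silently
dropped.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd

from xsub.errors import XsubError
from xsub.io import validate_orthology

logger = logging.getLogger(__name__)

__all__ = ["OrthologyIndex", "resolve_orthologues", "translate_de_table"]


@dataclass
class OrthologyIndex:
    """Bidirectional lookup built from an orthology table.

    Each direction maps a gene to its candidate partners as a list of
    ``(partner, homology_pct)`` sorted by descending homology then ascending
    partner id.
    """

    human_to_mouse: dict[str, list[tuple[str, float]]]
    mouse_to_human: dict[str, list[tuple[str, float]]]

    @classmethod
    def from_table(cls, table: pd.DataFrame) -> "OrthologyIndex":
        validate_orthology(table, source="OrthologyIndex.from_table")
        h2m: dict[str, list[tuple[str, float]]] = {}
        m2h: dict[str, list[tuple[str, float]]] = {}
        for human, mouse, hom in table[["human_gene", "mouse_gene", "homology_pct"]].itertuples(
            index=False
        ):
            h2m.setdefault(human, []).append((mouse, float(hom)))
            m2h.setdefault(mouse, []).append((human, float(hom)))
        for lookup in (h2m, m2h):
            for partners in lookup.values():
                partners.sort(key=lambda ph: (-ph[1], ph[0]))
        return cls(human_to_mouse=h2m, mouse_to_human=m2h)

    def lookup(self, direction: str) -> dict[str, list[tuple[str, float]]]:
        if direction in ("human2mouse", "human_to_mouse"):
            return self.human_to_mouse
        if direction in ("mouse2human", "mouse_to_human"):
            return self.mouse_to_human
        raise XsubError(f"unknown orthology direction {direction!r}")


def resolve_orthologues(
    genes: list[str], index: OrthologyIndex, direction: str
) -> tuple[dict[str, str], list[str]]:
    """Map each gene to its single best orthologue.

    Returns ``(mapping, unmapped)``: for one-to-many relations the partner
    with maximal homology wins (ties by ascending partner id); genes without
    any partner appear in ``unmapped`` in input order.
    """
    lookup = index.lookup(direction)
    mapping: dict[str, str] = {}
    unmapped: list[str] = []
    for gene in genes:
        partners = lookup.get(gene)
        if partners:
            mapping[gene] = partners[0][0]
        else:
            unmapped.append(gene)
    return mapping, unmapped


def translate_de_table(de: pd.DataFrame, index: OrthologyIndex, direction: str) -> pd.DataFrame:
    """Re-express a DE table in the partner species' gene namespace.

    Unmapped genes are dropped (count logged).  When two source genes map to
    the same target, the row with the smaller adjusted p is kept (ties by
    smaller raw p, then source gene id).
    """
    mapping, unmapped = resolve_orthologues(list(de.index), index, direction)
    if unmapped:
        logger.info("translate_de_table: dropped %d unmapped gene(s)", len(unmapped))
    out = de.loc[list(mapping)].copy()
    out["_target"] = [mapping[g] for g in out.index]
    out = (
        out.assign(_source=out.index)
        .sort_values(["p_adj", "p_value", "_source"], kind="stable")
        .drop_duplicates(subset="_target", keep="first")
    )
    n_collisions = len(mapping) - len(out)
    if n_collisions:
        logger.info("translate_de_table: resolved %d many-to-one collision(s)", n_collisions)
    out = out.set_index("_target").drop(columns="_source")
    out.index.name = "gene"
    return out.sort_index()
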