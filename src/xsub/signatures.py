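"""Gene-signature construction from differential-expression results.

A signature is an ordered gene list with signed log-fold-change weights,
selected from a DE table by significance rank under a strict |logFC|
threshold.  Subtype templates stack one up-regulated signature per molecular
subtype (e.g. top 75 genes at logFC > 0.75 for each CMS) into a genes x
subtypes weight matrix used for correlation-based subtype assignment.

A Welch-t DE engine on log expression is provided so synthetic cohorts can
be analysed without an external DE tool; DE tables from any tool are
accepted as first-class input through :mod:`xsub.io`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from xsub.errors import XsubError
from xsub.survstats import bh_adjust

logger = logging.getLogger(__name__)

__all__ = [
    "GeneSignature",
    "SubtypeTemplate",
    "welch_de",
    "select_top_signature",
    "build_subtype_templates",
    "serrated_signature",
]


@dataclass
class GeneSignature:
    """Ordered gene list with signed logFC weights and selection provenance."""

    name: str
    genes: list[str]
    weights: np.ndarray
    n_requested: int | None = None
    lfc_threshold: float | None = None
    direction: str | None = None
    source: str | None = None

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if len(self.genes) != self.weights.size:
            raise XsubError(f"signature {self.name!r}: genes/weights length mismatch")
        if len(set(self.genes)) != len(self.genes):
            raise XsubError(f"signature {self.name!r}: duplicate genes")
        if not np.isfinite(self.weights).all():
            raise XsubError(f"signature {self.name!r}: non-finite weights")

    def __len__(self) -> int:
        return len(self.genes)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"weight": self.weights, "rank": np.arange(1, len(self.genes) + 1)},
            index=pd.Index(self.genes, name="gene"),
        )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, name: str) -> "GeneSignature":
        frame = frame.sort_values("rank") if "rank" in frame.columns else frame
        return cls(name=name, genes=list(frame.index), weights=frame["weight"].to_numpy())


@dataclass
class SubtypeTemplate:
    """Per-subtype signature weights over the union template gene set.

    ``weights`` is genes x subtypes; a cell is the subtype's logFC where the
    gene was selected for that subtype and 0 elsewhere.  ``total_selected``
    is the sum of per-subtype selection counts (75 genes for each of four
    subtypes gives 300 even when selections overlap); the union size is
    ``len(weights.index)``.
    """

    weights: pd.DataFrame
    signatures: dict[str, GeneSignature] = field(repr=False, default_factory=dict)

    @property
    def subtypes(self) -> list[str]:
        return list(self.weights.columns)

    @property
    def genes(self) -> list[str]:
        return list(self.weights.index)

    @property
    def total_selected(self) -> int:
        return int(sum(len(sig) for sig in self.signatures.values()))


def welch_de(expr: pd.DataFrame, group_a: list[str], group_b: list[str]) -> pd.DataFrame:
    """Two-sample Welch-t differential expression on log-scale values.

    logFC = mean(A) - mean(B) per gene (already log units); p from Welch's
    unequal-variance t; adjusted p by Benjamini-Hochberg.  Genes with zero
    variance in both groups get p = 1 with logFC as computed.
    """
    group_a, group_b = list(group_a), list(group_b)
    if set(group_a) & set(group_b):
        raise XsubError("welch_de: groups overlap")
    if len(group_a) < 2 or len(group_b) < 2:
        raise XsubError("welch_de: each group needs >=2 samples")
    missing = (set(group_a) | set(group_b)) - set(expr.columns)
    if missing:
        raise XsubError(f"welch_de: sample(s) not in matrix: {sorted(missing)[:5]}")

    a = expr[group_a].to_numpy()
    b = expr[group_b].to_numpy()
    lfc = a.mean(axis=1) - b.mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t, p = stats.ttest_ind(a, b, axis=1, equal_var=False)
    degenerate = (a.var(axis=1) == 0) & (b.var(axis=1) == 0)
    p = np.where(degenerate, 1.0, p)
    t = np.where(degenerate, 0.0, t)
    de = pd.DataFrame(
        {
            "log_fc": lfc,
            "p_value": p,
            "p_adj": bh_adjust(p),
            "mean_expr": expr[group_a + group_b].mean(axis=1).to_numpy(),
        },
        index=expr.index.copy(),
    )
    de.index.name = "gene"
    return de


def _rank_candidates(de: pd.DataFrame) -> pd.DataFrame:
    # ascending adjusted p, ties by descending |logFC|, then ascending gene id
    keyed = de.assign(_abs_lfc=de["log_fc"].abs(), _gene=de.index)
    return keyed.sort_values(
        ["p_adj", "_abs_lfc", "_gene"], ascending=[True, False, True], kind="stable"
    )


def select_top_signature(
    de: pd.DataFrame,
    n: int,
    lfc_threshold: float = 0.0,
    direction: str = "up",
    name: str = "signature",
) -> GeneSignature:
    """Select the n most significant genes passing a strict logFC threshold.

    ``direction`` is ``"up"`` (logFC > threshold), ``"down"``
    (logFC < -threshold) or ``"both"`` (|logFC| > threshold — "most
    significantly regulated" regardless of sign).  Candidates are ranked by
    ascending adjusted p, ties broken by descending |logFC| then ascending
    gene id.  If fewer than n genes qualify, all of them are returned with a
    warning.
    """
    if n < 1:
        raise XsubError(f"select_top_signature: n must be >= 1, got {n}")
    if lfc_threshold < 0:
        raise XsubError("select_top_signature: lfc_threshold must be >= 0")
    lfc = de["log_fc"]
    if direction == "up":
        mask = lfc > lfc_threshold
    elif direction == "down":
        mask = lfc < -lfc_threshold
    elif direction == "both":
        mask = lfc.abs() > lfc_threshold
    else:
        raise XsubError(f"select_top_signature: unknown direction {direction!r}")

    candidates = _rank_candidates(de.loc[mask])
    if len(candidates) < n:
        logger.warning(
            "select_top_signature(%s): only %d of %d requested genes qualify "
            "(direction=%s, |logFC| > %g)",
            name, len(candidates), n, direction, lfc_threshold,
        )
    chosen = candidates.head(n)
    return GeneSignature(
        name=name,
        genes=list(chosen.index),
        weights=chosen["log_fc"].to_numpy(),
        n_requested=n,
        lfc_threshold=lfc_threshold,
        direction=direction,
    )


def build_subtype_templates(
    per_subtype_de: dict[str, pd.DataFrame],
    n_per_subtype: int = 75,
    lfc_threshold: float = 0.75,
) -> SubtypeTemplate:
    """Build a subtype weight-matrix template from one up-regulation DE table per subtype.

    Each subtype contributes its top ``n_per_subtype`` up-regulated genes at
    strict logFC > ``lfc_threshold``; the template gene list is the union and
    each column holds that subtype's logFC on its selected genes, 0 elsewhere.
    """
    if len(per_subtype_de) < 2:
        raise XsubError("build_subtype_templates: need >=2 subtypes")
    signatures: dict[str, GeneSignature] = {}
    for subtype, de in per_subtype_de.items():
        sig = select_top_signature(
            de, n=n_per_subtype, lfc_threshold=lfc_threshold, direction="up", name=subtype
        )
        if len(sig) == 0:
            raise XsubError(
                f"build_subtype_templates: no qualifying up-regulated genes for {subtype!r}"
            )
        signatures[subtype] = sig

    union: list[str] = list(
        dict.fromkeys(g for sig in signatures.values() for g in sig.genes)
    )
    weights = pd.DataFrame(
        0.0, index=pd.Index(union, name="gene"), columns=list(signatures)
    )
    for subtype, sig in signatures.items():
        weights.loc[sig.genes, subtype] = sig.weights
    return SubtypeTemplate(weights=weights, signatures=signatures)


def serrated_signature(
    de_serrated_vs_tubular: pd.DataFrame, wnt_target_genes: list[str]
) -> GeneSignature:
    """Signed signature of WNT-target regulation in serrated vs tubular adenomas.

    The DE table is restricted to the supplied WNT target genes; all
    overlapping genes are kept with their logFC as weight (no significance
    filter), supporting heatmap-style comparison of WNT-pathway activation.
    """
    if not wnt_target_genes:
        raise XsubError("serrated_signature: WNT target list is empty")
    wnt_target_genes = list(dict.fromkeys(wnt_target_genes))
    present = [g for g in wnt_target_genes if g in de_serrated_vs_tubular.index]
    if not present:
        raise XsubError("serrated_signature: no WNT target gene found in the DE table")
    absent = len(wnt_target_genes) - len(present)
    if absent:
        logger.warning("serrated_signature: %d WNT target gene(s) absent from DE table", absent)
    sub = de_serrated_vs_tubular.loc[present]
    return GeneSignature(
        name="serrated_vs_tubular",
        genes=present,
        weights=sub["log_fc"].to_numpy(),
        direction="both",
        source="serrated_vs_tubular",
    )
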