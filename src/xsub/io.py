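"""Readers and writers for the tabular formats the pipeline exchanges.

All formats are plain text with fixed, documented headers:

==============  =========  ==========================================================
format          layout     columns
==============  =========  ==========================================================
expression TSV  TSV        ``gene`` then one column per sample; log-scale values
clinical CSV    CSV        ``sample,time,event,cms,cris,batch`` (last three optional)
orthology TSV   TSV        ``human_gene, mouse_gene, homology_pct``
DE TSV          TSV        ``gene, log_fc, p_value, p_adj[, mean_expr]``
GMT             TSV lines  ``name<TAB>description<TAB>gene1<TAB>gene2...``
==============  =========  ==========================================================

Readers validate strictly and raise :class:`~xsub.errors.FormatError` naming
the file and the offending row/identifier; they never coerce or impute.
Missing optional clinical fields are encoded as ``NA``.  Gene identifiers are
opaque case-sensitive strings.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from xsub.errors import FormatError

logger = logging.getLogger(__name__)

CMS_LABELS = ("CMS1", "CMS2", "CMS3", "CMS4")
CRIS_LABELS = ("CRIS-A", "CRIS-B", "CRIS-C", "CRIS-D", "CRIS-E")

DE_COLUMNS = ("log_fc", "p_value", "p_adj")


def _find_duplicates(values) -> list:
    seen: set = set()
    dups: list = []
    for v in values:
        if v in seen and v not in dups:
            dups.append(v)
        seen.add(v)
    return dups


# ---------------------------------------------------------------------------
# expression matrices
# ---------------------------------------------------------------------------

def validate_expression(expr: pd.DataFrame, source: str = "<memory>") -> pd.DataFrame:
    """Check the expression-matrix invariants (unique ids, finite values, >=2 samples)."""
    dup_genes = _find_duplicates(expr.index)
    if dup_genes:
        raise FormatError(f"{source}: duplicated gene id(s): {dup_genes[:5]}")
    dup_samples = _find_duplicates(expr.columns)
    if dup_samples:
        raise FormatError(f"{source}: duplicated sample id(s): {dup_samples[:5]}")
    if expr.shape[1] < 2:
        raise FormatError(f"{source}: expression matrix needs >=2 samples, got {expr.shape[1]}")
    values = expr.to_numpy()
    if not np.issubdtype(values.dtype, np.number):
        bad = expr.columns[[not np.issubdtype(dt, np.number) for dt in expr.dtypes]]
        raise FormatError(f"{source}: non-numeric expression column(s): {list(bad)[:5]}")
    if not np.isfinite(values).all():
        gene_idx, sample_idx = np.argwhere(~np.isfinite(values))[0]
        raise FormatError(
            f"{source}: non-finite value at gene {expr.index[gene_idx]!r}, "
            f"sample {expr.columns[sample_idx]!r}"
        )
    return expr


def read_expression_tsv(path: str | Path) -> pd.DataFrame:
    """Read a genes x samples log-expression matrix.

    First column holds gene ids (header ``gene``), remaining columns one
    sample each.  Returns a float DataFrame indexed by gene.
    """
    path = Path(path)
    try:
        expr = pd.read_csv(path, sep="\t", index_col=0)
    except ValueError as exc:
        raise FormatError(f"{path}: unparseable expression TSV: {exc}") from exc
    expr.index = expr.index.astype(str)
    expr.columns = expr.columns.astype(str)
    for col in expr.columns:
        if not np.issubdtype(expr[col].dtype, np.number):
            bad_rows = expr.index[pd.to_numeric(expr[col], errors="coerce").isna()]
            raise FormatError(
                f"{path}: non-numeric cell in column {col!r}, row(s) {list(bad_rows[:3])}"
            )
    return validate_expression(expr.astype(float), source=str(path))


def write_expression_tsv(expr: pd.DataFrame, path: str | Path) -> None:
    """Write a matrix in the layout :func:`read_expression_tsv` expects (round-trip safe)."""
    validate_expression(expr, source="write_expression_tsv")
    # default float repr round-trips exactly
    expr.to_csv(path, sep="\t", index_label="gene")


# ---------------------------------------------------------------------------
# clinical tables
# ---------------------------------------------------------------------------

def validate_clinical(
    clin: pd.DataFrame,
    source: str = "<memory>",
    cms_labels: tuple[str, ...] = CMS_LABELS,
    cris_labels: tuple[str, ...] = CRIS_LABELS,
) -> pd.DataFrame:
    dups = _find_duplicates(clin.index)
    if dups:
        raise FormatError(f"{source}: duplicated sample id(s): {dups[:5]}")
    if "time" not in clin.columns or "event" not in clin.columns:
        raise FormatError(f"{source}: clinical table requires 'time' and 'event' columns")
    times = clin["time"].to_numpy(dtype=float)
    if np.isnan(times).any():
        bad = clin.index[np.isnan(times)]
        raise FormatError(f"{source}: missing survival time for sample(s) {list(bad[:5])}")
    if (times < 0).any():
        bad = clin.index[times < 0]
        raise FormatError(f"{source}: negative survival time for sample(s) {list(bad[:5])}")
    if not clin["event"].isin([0, 1, True, False]).all():
        bad = clin.index[~clin["event"].isin([0, 1, True, False])]
        raise FormatError(f"{source}: event flag must be 0/1, offending sample(s) {list(bad[:5])}")
    for col, allowed in (("cms", cms_labels), ("cris", cris_labels)):
        if col in clin.columns:
            labels = clin[col].dropna()
            unknown = sorted(set(labels) - set(allowed))
            if unknown:
                raise FormatError(f"{source}: unknown {col} label(s): {unknown[:5]}")
    return clin


def read_clinical_csv(
    path: str | Path,
    cms_labels: tuple[str, ...] = CMS_LABELS,
    cris_labels: tuple[str, ...] = CRIS_LABELS,
) -> pd.DataFrame:
    """Read a per-sample clinical table (``sample,time,event[,cms][,cris][,batch]``).

    ``NA`` encodes a missing optional label.  Unknown subtype labels are
    rejected; pass custom vocabularies for non-default cohorts.
    """
    path = Path(path)
    clin = pd.read_csv(path, index_col="sample", na_values=["NA"], keep_default_na=False)
    clin.index = clin.index.astype(str)
    clin["event"] = clin["event"].astype(int)
    clin["time"] = pd.to_numeric(clin["time"], errors="coerce")
    validate_clinical(clin, source=str(path), cms_labels=cms_labels, cris_labels=cris_labels)
    clin["event"] = clin["event"].astype(bool)
    return clin


def write_clinical_csv(clin: pd.DataFrame, path: str | Path) -> None:
    out = clin.copy()
    out["event"] = out["event"].astype(int)
    out.to_csv(path, index_label="sample", na_rep="NA")


# ---------------------------------------------------------------------------
# orthology tables
# ---------------------------------------------------------------------------

def validate_orthology(orth: pd.DataFrame, source: str = "<memory>") -> pd.DataFrame:
    required = {"human_gene", "mouse_gene", "homology_pct"}
    missing = required - set(orth.columns)
    if missing:
        raise FormatError(f"{source}: orthology table missing column(s) {sorted(missing)}")
    hom = orth["homology_pct"].to_numpy(dtype=float)
    if np.isnan(hom).any() or (hom < 0).any() or (hom > 100).any():
        bad = orth.index[np.isnan(hom) | (hom < 0) | (hom > 100)]
        raise FormatError(f"{source}: homology_pct outside [0, 100] at row(s) {list(bad[:5])}")
    pair_dups = orth.duplicated(subset=["human_gene", "mouse_gene"])
    if pair_dups.any():
        bad = orth.loc[pair_dups, ["human_gene", "mouse_gene"]].iloc[0]
        raise FormatError(
            f"{source}: duplicated (human, mouse) pair ({bad['human_gene']!r}, {bad['mouse_gene']!r})"
        )
    return orth


def read_orthology_tsv(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    orth = pd.read_csv(path, sep="\t", dtype={"human_gene": str, "mouse_gene": str})
    return validate_orthology(orth, source=str(path))


def write_orthology_tsv(orth: pd.DataFrame, path: str | Path) -> None:
    validate_orthology(orth, source="write_orthology_tsv")
    orth.to_csv(path, sep="\t", index=False, float_format="%.10g")


# ---------------------------------------------------------------------------
# differential-expression tables
# ---------------------------------------------------------------------------

def validate_de(de: pd.DataFrame, source: str = "<memory>") -> pd.DataFrame:
    missing = set(DE_COLUMNS) - set(de.columns)
    if missing:
        raise FormatError(f"{source}: DE table missing column(s) {sorted(missing)}")
    dups = _find_duplicates(de.index)
    if dups:
        raise FormatError(f"{source}: duplicated gene id(s): {dups[:5]}")
    for col in ("p_value", "p_adj"):
        p = de[col].to_numpy(dtype=float)
        if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
            bad = de.index[np.isnan(p) | (p < 0) | (p > 1)]
            raise FormatError(f"{source}: {col} outside [0, 1] for gene(s) {list(bad[:5])}")
    if not np.isfinite(de["log_fc"].to_numpy(dtype=float)).all():
        bad = de.index[~np.isfinite(de["log_fc"].to_numpy(dtype=float))]
        raise FormatError(f"{source}: non-finite log_fc for gene(s) {list(bad[:5])}")
    return de


def read_de_tsv(path: str | Path) -> pd.DataFrame:
    """Read a per-gene DE table (``gene, log_fc, p_value, p_adj[, mean_expr]``)."""
    path = Path(path)
    de = pd.read_csv(path, sep="\t", index_col="gene")
    de.index = de.index.astype(str)
    return validate_de(de, source=str(path))


def write_de_tsv(de: pd.DataFrame, path: str | Path) -> None:
    validate_de(de, source="write_de_tsv")
    de.to_csv(path, sep="\t", index_label="gene")


# ---------------------------------------------------------------------------
# gene sets (GMT)
# ---------------------------------------------------------------------------

def read_gmt(path: str | Path) -> dict[str, list[str]]:
    """Read a GMT gene-set file into an ordered ``{name: [genes]}`` mapping.

    Standard GMT semantics: one set per line, fields tab-separated, field 1
    the set name, field 2 a free-text description (discarded), remaining
    fields gene ids.  Duplicate genes within a line are collapsed (order
    kept, warning logged); duplicate set names are an error.
    """
    path = Path(path)
    sets: dict[str, list[str]] = {}
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"{path}:{lineno}: GMT line needs >=3 tab-separated fields, got {len(fields)}"
                )
            name, genes = fields[0], fields[2:]
            if name in sets:
                raise FormatError(f"{path}:{lineno}: duplicate gene-set name {name!r}")
            deduped = list(dict.fromkeys(genes))
            if len(deduped) < len(genes):
                logger.warning(
                    "%s:%d: %d duplicate gene(s) collapsed in set %r",
                    path, lineno, len(genes) - len(deduped), name,
                )
            if not deduped:
                raise FormatError(f"{path}:{lineno}: gene set {name!r} is empty")
            sets[name] = deduped
    return sets


def write_gmt(sets: dict[str, list[str]], path: str | Path, description: str = "na") -> None:
    with open(path, "w") as handle:
        for name, genes in sets.items():
            handle.write("\t".join([name, description, *genes]) + "\n")
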