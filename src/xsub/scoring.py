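"""Per-sample and per-model scores.

Three scoring families recur in the analysis:

* **z-sum panel scores** (NOTCH-score, WNT-score, KPN/KP-score): expression
  is standardized gene-wise across the cohort and summed over a fixed gene
  panel.
* **signature-correlation scores**: expression is mean-centred gene-wise and
  each sample is scored by the Pearson correlation of its centred profile
  with a signature's logFC weight vector; samples are classified by fixed
  thresholds (default > 0.1 high / <= 0.1 low).
* **model-subtype correlation**: Pearson correlation between a mouse model's
  logFC vector (translated to human genes) and each subtype's template
  weights over the shared template genes.

Marker-based infiltration scores (mean marker expression, standardized per
cell type) and a simple per-batch gene-wise centering are included as the
cohort-preparation steps the scores assume.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from xsub.errors import XsubError
from xsub.signatures import GeneSignature, SubtypeTemplate

logger = logging.getLogger(__name__)

__all__ = [
    "NOTCH_PANEL",
    "WNT_PANEL",
    "zscore_by_gene",
    "panel_sum_score",
    "median_stratify",
    "correlation_score_samples",
    "classify_by_correlation",
    "model_subtype_correlation",
    "infiltration_scores",
    "center_by_batch",
]

# NOTCH-pathway receptor/ligand/target panel
NOTCH_PANEL: tuple[str, ...] = (
    "JAG1", "JAG2", "DLL1", "DLL3", "DLL4",
    "NOTCH1", "NOTCH2", "NOTCH3", "NOTCH4",
    "HES1", "HES2", "HEY1", "HEY2", "DTX1",
)

# WNT-pathway target panel
WNT_PANEL: tuple[str, ...] = (
    "ASCL2", "AXIN2", "BMP4", "MRTO4", "HILPDA",
    "NOP16", "KITLG", "LGR5", "MYC", "NOP2",
    "PPIF", "SOX4", "PAAF1", "ZIC2", "ZNRF3",
)

PANELS: dict[str, tuple[str, ...]] = {"notch": NOTCH_PANEL, "wnt": WNT_PANEL}


def zscore_by_gene(expr: pd.DataFrame) -> pd.DataFrame:
    """Standardize each gene row to mean 0, sample sd 1 (ddof=1) across samples.

    Zero-variance rows become all zero (warning logged) rather than NaN.
    """
    if expr.shape[1] < 2:
        raise XsubError("zscore_by_gene: need >=2 samples")
    values = expr.to_numpy(dtype=float)
    mu = values.mean(axis=1, keepdims=True)
    sd = values.std(axis=1, ddof=1, keepdims=True)
    flat = sd[:, 0] == 0
    if flat.any():
        logger.warning("zscore_by_gene: %d zero-variance gene(s) set to 0", int(flat.sum()))
    sd[flat] = 1.0
    z = (values - mu) / sd
    z[flat] = 0.0
    return pd.DataFrame(z, index=expr.index.copy(), columns=expr.columns.copy())


def panel_sum_score(
    expr: pd.DataFrame, panel, signs=None, name: str = "panel"
) -> pd.Series:
    """z-sum score: per sample, the (signed) sum of gene-wise standardized expression.

    Panel genes absent from the matrix are dropped with a warning; with all
    genes present the cohort mean of the score is 0 by construction.
    """
    panel = list(panel)
    if signs is None:
        signs = {}
    present = [g for g in panel if g in expr.index]
    if not present:
        raise XsubError(f"panel_sum_score({name}): no panel gene present; panel = {panel}")
    n_absent = len(panel) - len(present)
    if n_absent:
        logger.warning("panel_sum_score(%s): %d panel gene(s) absent", name, n_absent)
    z = zscore_by_gene(expr.loc[present])
    sign_vec = np.array([signs.get(g, 1.0) for g in present])
    scores = pd.Series(sign_vec @ z.to_numpy(), index=expr.columns.copy(), name=name)
    return scores


def median_stratify(scores: pd.Series, strata: pd.Series | None = None) -> pd.Series:
    """Label samples ``high`` (score > median) or ``low`` (score <= median).

    With ``strata`` given (e.g. KRAS status or CMS label), the median is
    computed within each stratum — the "within-group median" convention.
    """
    if len(scores) < 2:
        raise XsubError("median_stratify: need >=2 samples")
    if strata is None:
        med = scores.median()
        labels = np.where(scores > med, "high", "low")
        return pd.Series(labels, index=scores.index, name="group")
    strata = strata.reindex(scores.index)
    if strata.isna().any():
        raise XsubError("median_stratify: every sample needs a stratum label")
    out = pd.Series(index=scores.index, dtype=object, name="group")
    for _, idx in scores.groupby(strata).groups.items():
        med = scores.loc[idx].median()
        out.loc[idx] = np.where(scores.loc[idx] > med, "high", "low")
    return out


def correlation_score_samples(expr: pd.DataFrame, signature: GeneSignature) -> pd.Series:
    """Score each sample by Pearson correlation with a signature weight vector.

    The matrix is restricted to the signature genes present (>= 3 required)
    and mean-centred gene-wise; the score is the correlation between a
    sample's centred profile and the signature's logFC weights.
    """
    present = [g for g in signature.genes if g in expr.index]
    if len(present) < 3:
        raise XsubError(
            f"correlation_score_samples: only {len(present)} signature gene(s) in matrix (need >=3)"
        )
    n_absent = len(signature.genes) - len(present)
    if n_absent:
        logger.warning(
            "correlation_score_samples(%s): %d signature gene(s) absent", signature.name, n_absent
        )
    weight = pd.Series(signature.weights, index=signature.genes).loc[present].to_numpy()
    sub = expr.loc[present].to_numpy(dtype=float)
    centred = sub - sub.mean(axis=1, keepdims=True)  # gene-wise mean-centring

    x = centred - centred.mean(axis=0, keepdims=True)
    w = weight - weight.mean()
    denom = np.sqrt((x**2).sum(axis=0)) * np.sqrt((w**2).sum())
    if (denom == 0).any() or np.linalg.norm(w) == 0:
        raise XsubError("correlation_score_samples: zero variance in sample profile or weights")
    scores = (w @ x) / denom
    return pd.Series(scores, index=expr.columns.copy(), name=signature.name)


def classify_by_correlation(
    scores: pd.Series,
    pos_threshold: float = 0.1,
    neg_threshold: float = -0.1,
    mode: str = "two_group",
) -> pd.Series:
    """Assign correlation-score groups.

    ``two_group`` (default, the survival-figure convention): ``high`` when
    score > pos_threshold, else ``low``.  ``three_group``: ``positive``
    (> pos), ``negative`` (< neg), ``unassigned`` otherwise.
    """
    if neg_threshold > pos_threshold:
        raise XsubError("classify_by_correlation: neg_threshold must be <= pos_threshold")
    if mode == "two_group":
        labels = np.where(scores > pos_threshold, "high", "low")
    elif mode == "three_group":
        labels = np.where(
            scores > pos_threshold,
            "positive",
            np.where(scores < neg_threshold, "negative", "unassigned"),
        )
    else:
        raise XsubError(f"classify_by_correlation: unknown mode {mode!r}")
    return pd.Series(labels, index=scores.index, name="group")


def model_subtype_correlation(
    model_signatures: dict[str, pd.DataFrame], template: SubtypeTemplate
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Correlate each mouse model's logFC vector with each subtype template column.

    For a (model, subtype) cell, the template genes present in the model's DE
    table define the vectors; genes absent from the model table are dropped
    for that cell and the per-cell gene count is recorded.

    Returns ``(r, n)``: models x subtypes Pearson correlations and the gene
    count behind each cell.
    """
    subtypes = template.subtypes
    r = pd.DataFrame(index=list(model_signatures), columns=subtypes, dtype=float)
    n = pd.DataFrame(index=list(model_signatures), columns=subtypes, dtype=int)
    for model, de in model_signatures.items():
        shared = [g for g in template.genes if g in de.index]
        if len(shared) < 3:
            raise XsubError(
                f"model_subtype_correlation: model {model!r} shares only "
                f"{len(shared)} gene(s) with the template (need >=3)"
            )
        lfc = de.loc[shared, "log_fc"].to_numpy(dtype=float)
        for subtype in subtypes:
            w = template.weights.loc[shared, subtype].to_numpy(dtype=float)
            if np.std(lfc) == 0 or np.std(w) == 0:
                raise XsubError(
                    f"model_subtype_correlation: zero variance for ({model!r}, {subtype!r})"
                )
            r.loc[model, subtype] = float(np.corrcoef(lfc, w)[0, 1])
            n.loc[model, subtype] = len(shared)
    return r, n


def infiltration_scores(
    expr: pd.DataFrame, marker_sets: dict[str, list[str]]
) -> pd.DataFrame:
    """Marker-mean infiltration scores, standardized per cell type.

    Raw score = mean log expression of the cell type's marker genes present
    in the matrix, per sample; each cell-type row is then z-standardized
    across samples.  Returns cell types x samples.
    """
    rows = {}
    for celltype, markers in marker_sets.items():
        present = [g for g in markers if g in expr.index]
        if not present:
            raise XsubError(f"infiltration_scores: no marker of set {celltype!r} in matrix")
        if len(present) < len(markers):
            logger.warning(
                "infiltration_scores(%s): %d marker(s) absent",
                celltype, len(markers) - len(present),
            )
        rows[celltype] = expr.loc[present].mean(axis=0)
    raw = pd.DataFrame(rows).T
    raw.index.name = "cell_type"
    return zscore_by_gene(raw)


def center_by_batch(expr: pd.DataFrame, batches: pd.Series) -> pd.DataFrame:
    """Remove additive batch effects by per-gene, per-batch mean centering.

    Global per-gene means are re-added so overall gene means are preserved.
    Every sample needs a batch label and every batch >=2 samples.
    """
    batches = batches.reindex(expr.columns)
    if batches.isna().any():
        missing = list(expr.columns[batches.isna()])[:5]
        raise XsubError(f"center_by_batch: missing batch label for sample(s) {missing}")
    counts = batches.value_counts()
    singletons = counts[counts < 2]
    if len(singletons):
        raise XsubError(f"center_by_batch: singleton batch(es) {list(singletons.index)}")
    out = expr.copy().astype(float)
    global_mean = out.mean(axis=1)
    for _, samples in out.columns.to_series().groupby(batches).groups.items():
        batch_mean = out[samples].mean(axis=1)
        out[samples] = out[samples].sub(batch_mean, axis=0)
    return out.add(global_mean, axis=0)
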