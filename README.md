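# xsub — cross-species subtyping of intestinal-tumor transcriptomes

`xsub` maps mouse intestinal-cancer expression signatures onto the human
colorectal-cancer (CRC) molecular subtypes and turns the result into
patient-level scores and survival stratification. It is aimed at
computational biologists who have differential-expression (DE) profiles
from genetically engineered mouse models (GEMMs) — e.g. the metastatic
KPN genotype (KrasG12D; Trp53-null; Notch1-ICD) — and want to ask which
human subtype (CMS1–4, CRIS-A–E) each model resembles and whether a
model-derived signature predicts recurrence-free survival.

The core computations:

* **Subtype templates** — per subtype, the top *n* most significantly
  up-regulated genes with logFC > *t* (defaults n = 75, t = 0.75) from a
  one-vs-rest DE table; the template is the union gene list with each
  subtype's logFC as its weight column (4 × 75 = 300 selected genes for
  CMS, 5 × 75 = 375 for CRIS).
* **Orthology translation** — mouse↔human gene mapping with the
  highest-homology-percentage rule for one-to-many relations.
* **Model–subtype correlation** — Pearson *r* between a model's logFC
  vector and each template column over their shared genes; two
  correlations are compared with Fisher's r-to-z,
  z = (atanh r₁ − atanh r₂)/√(1/(n₁−3) + 1/(n₂−3)).
* **Patient scores** — z-sum panel scores (NOTCH-, WNT-, KPN/KP-score:
  Σ of gene-wise standardized expression over a fixed panel) and
  signature-correlation scores (Pearson *r* of a sample's gene-wise
  mean-centred profile with the signature weights), classified at the 0.1
  threshold or the within-group median.
* **Survival** — Kaplan-Meier product-limit curves and the unweighted
  log-rank test.
* **Auxiliaries** — marker-mean immune-infiltration scores standardized
  per cell type, metastasis-incidence summaries with 2×2 chi-square,
  2^(−ΔCT) qPCR expression, and an IUPAC motif scanner for putative RBPJ
  sites in promoter sequences.

A synthetic-data module generates cohorts with subtype-specific gene
blocks, batch effects and score-linked censored survival, plus mouse
profiles and orthology tables, so the full pipeline runs and is tested
without any external download. See `docs/methods.md` for the model
details and `docs/formats.md` for the file formats.

## Worked example

```python
from xsub import scoring, signatures, survstats, synthetic

# synthetic cohort: 300 patients, 1000 genes, four CMS-like subtypes
cfg = synthetic.CohortSimConfig(n_samples=300, n_genes=1000,
                                genes_per_subtype_block=150, seed=42)
expr, clin = synthetic.simulate_cohort(cfg)

# one-vs-rest DE per subtype -> 75-gene templates at logFC > 0.75
per_subtype = {
    label: signatures.welch_de(
        expr,
        list(clin.index[clin.cms == label]),
        list(clin.index[clin.cms != label]))
    for label in cfg.subtype_labels
}
template = signatures.build_subtype_templates(per_subtype,
                                              n_per_subtype=75,
                                              lfc_threshold=0.75)
print(f"template: {template.total_selected} selected genes,"
      f" union {len(template.genes)}")

# a KPN-like mouse model overlapping 70% of the CMS4-analog block
mouse = synthetic.simulate_mouse_profiles(
    synthetic.MouseSimConfig(target_subtype="CMS4",
                             overlap_fraction=0.7, seed=1),
    cfg.blocks(), gene_universe=cfg.genes)
r, n = scoring.model_subtype_correlation({"KPN": mouse}, template)
print(r.round(3).to_string())

# 500-gene signature -> per-patient correlation scores -> survival
sig = signatures.select_top_signature(mouse, n=500, direction="both",
                                      name="KPN_signature")
scores = scoring.correlation_score_samples(expr, sig)
groups = scoring.classify_by_correlation(scores)   # high: score > 0.1
print(groups.value_counts().to_dict())
lr = survstats.logrank_test(clin.time, clin.event, groups)
print(f"log-rank chi2 = {lr.statistic:.2f}, p = {lr.p_value:.3g}")
```

Output:

```
template: 300 selected genes, union 300
      CMS1   CMS2   CMS3   CMS4
KPN -0.266 -0.231 -0.235  0.726
{'low': 229, 'high': 71}
log-rank chi2 = 137.39, p = 9.91e-32
```

The model correlates most strongly with its planted target subtype
(r = 0.73 against CMS4 vs. negative r elsewhere), 71 of 300 patients
exceed the 0.1 correlation-score threshold, and — because the simulated
hazard is tied to the CMS4-analog block score — the high group shows
markedly worse recurrence-free survival (log-rank p ≈ 1e-31).

The same analysis runs from the shell; every stage reads and writes plain
text files:

```bash
xsub run --out-dir run1 --seed 42          # full 6-stage pipeline
xsub incidence --site liver                # packaged GEMM incidence table
xsub motifscan --fasta promoter.fa --motif TGGGAA --out hits.csv
```

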