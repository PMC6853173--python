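# File formats

All inputs and outputs are plain text. Readers validate strictly and raise
errors naming the file, row and rule violated; nothing is coerced or
imputed.

## Expression TSV

Tab-separated, header row `gene<TAB><sample1><TAB><sample2>...`, one gene
per row. Values are log-scale expression, finite, numeric. Gene and sample
ids must be unique; at least 2 samples.

```
gene	s0001	s0002
g00001	7.1324	6.8893
g00002	8.0211	8.3402
```

## Clinical CSV

Comma-separated with header `sample,time,event,cms,cris,batch`.
`time` = follow-up in days (>= 0); `event` = 1 (event) / 0 (censored);
`cms` in CMS1–CMS4 or `NA`; `cris` in CRIS-A–CRIS-E or `NA`; `batch` free
label or `NA`. Custom subtype vocabularies can be passed to the reader.

## Orthology TSV

Tab-separated, header `human_gene	mouse_gene	homology_pct`. Homology in
[0, 100]; (human, mouse) pairs unique. One-to-many relations are listed as
multiple rows.

## DE TSV

Tab-separated, header `gene	log_fc	p_value	p_adj` (optional `mean_expr`).
`log_fc` in log2 units, finite; p-values in [0, 1]; genes unique.

## Signature TSV

Tab-separated, header `gene	weight	rank`. Weight is the signed logFC;
rank is the 1-based selection order.

## GMT

Standard gene-set format: one set per line,
`name<TAB>description<TAB>gene1<TAB>gene2...` (>= 3 fields). Duplicate genes
within a line are collapsed; duplicate set names are an error.

## GEMM cohort CSV

Header `animal_id,genotype,survival_days,event,sites`. `genotype` in
{PN, AP, APN, KP, KPN}; `sites` a semicolon-joined subset of
{liver, lung, lymph-node, diaphragm, peritoneum}, empty for no metastasis.

## Motif hits CSV

Header `seq_id,start,strand,match,tss_relative_start`. `start` is 1-based
on the forward strand; minus-strand hits are occurrences of the motif's
reverse complement reported at their forward-strand start;
`tss_relative_start` is filled when a TSS offset is supplied.

## JSON outputs

* `survival.json` — per group: `n`, `time` (ascending distinct event
  times) and `survival` (product-limit estimates); plus `logrank` with
  `statistic`, `p_value`, `df`.
* `mapping_summary.json` — per model: `input_genes`, `mapped_genes`.
* `report.json` (pipeline) — `seed`, `parameters`, `stages_completed`,
  `template` (`total_selected`, `union_genes`), `model_assignment`
  (model → argmax subtype), `logrank_p`, `correlation_matrix_shape`,
  `warnings`.

All counts are plain integers, all coordinates 1-based, all probabilities
floats in [0, 1].
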