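# glycoreg

Discovery of subtype-specific glycosylation genes and their upstream
regulators from multi-omic breast-cancer cohorts.

## The problem

Triple-negative breast cancer (TNBC, here the basal-like subtype) lacks
the receptors targeted by standard breast-cancer therapy. Glycosylation is
broadly altered in cancer, so glycosylation-related genes ("glycogenes")
enriched specifically in TNBC are attractive therapeutic leads — but
finding them requires combining differential expression, pathway
enrichment and predictive modelling across several independent expression
cohorts, and then asking *why* the candidates are dysregulated: copy-number
alteration (CNA), DNA methylation (DM), or transcription-factor (TF)
activity.

`glycoreg` implements that two-phase workflow as a tested, reusable
library and CLI for anyone analysing gene-by-sample expression matrices
with TNBC / non-TNBC / normal labels plus gene-level CNA and DM layers and
TF ChIP evidence:

**Phase A — candidate discovery.** Four criteria:
1. empirical-Bayes moderated-t differential expression in two contrasts
   (TNBC vs non-TNBC, TNBC vs normal), direction-concordant across all
   datasets, top 50% by mean |t̃|;
2. ensemble gene-set enrichment (exact hypergeometric over-representation
   + rank-sum of member t-statistics, mean-rank/Fisher combination) with
   direction concordance, extracting member genes whose own direction
   matches the set's;
3. sparse logistic classification of TNBC status with a gene
   co-membership graph penalty,
   `(1/n)Σ log(1+e^{-y(b₀+xβ)}) + λ₁‖β‖₁ + λ₂ βᵀLβ`,
   over repeated stratified resamples — genes selected in ≥ 2 datasets
   pass;
4. retain only glycogenes with anabolic or catabolic function.

**Phase B — regulatory attribution.** Per-group Spearman correlation of
expression with CNA and DM, magnitude classes
(strong ≥ 0.450 / moderate 0.300–0.449 / weak 0.100–0.299 / low-no < 0.100),
the differential-regulation statistic
`δCor = |Cor(g,reg)_TNBC − Cor(g,reg)_non-TNBC|` with Mann–Whitney testing
per pathway; then per-gene lasso stability selection over ChIP-bound TFs
(100 subsample repetitions, CNA/DM as unpenalized covariates,
frequency threshold optimized by held-out R²), bipartite TF→gene networks
per group, the TNBC-specific differential network (set subtraction), and
master regulators (TFs with ≥ 4 differential targets).

A synthetic multi-omic cohort generator with planted truth (DE genes,
pathway shifts, CNA/DM couplings, group-specific TF edges) makes every
stage testable without any external download. See `docs/methods.md` for
models, defaults and limitations.

## Worked example

```python
import glycoreg as gr

cfg = gr.SimulationConfig(
    n_genes=60, n_tfs=5, n_per_group=100, n_cohorts=3,
    de_fraction=0.1, de_effect=2.0, noise_sd=1.0,
    n_null_sets=10, null_set_size=6, n_cna_driven=5, n_dm_driven=5,
    n_tnbc_only_edges=0, n_shared_edges=0,
    planted_pathways=[gr.PlantedPathway("planted_up", 7, 1, 1.5)],
    seed=1,
)
cohorts, truth = gr.simulate_cohorts(cfg)
result = gr.run_pipeline(cohorts, truth.gene_sets, truth.catalog, seed=1)
print("common DE genes:", len(result.common_de))
print("criterion 1 (top 50% DE):", sorted(result.c1_genes))
print("criterion 2 (enriched-pathway genes):", result.c2_genes)
print("final candidates:", result.final_genes)
```

prints

```
common DE genes: 14
criterion 1 (top 50% DE): ['G0000', 'G0001', 'G0002', 'G0003', 'G0004', 'G0005', 'G0008']
criterion 2 (enriched-pathway genes): ['G0006', 'G0007', 'G0008', 'G0009', 'G0010', 'G0011', 'G0012']
final candidates: ['G0000', 'G0004', 'G0005', 'G0006', 'G0007', 'G0010', 'G0011', 'G0012']
```

Reading the numbers: 14 genes are differentially expressed in the same
direction in both contrasts of all three simulated cohorts; the top half
(7, by mean |moderated t|) pass criterion 1. The planted 7-gene
up-regulated pathway (`G0006`–`G0012`) is detected by the enrichment
ensemble and its direction-concordant members pass criterion 2. The final
list is the union of the criteria restricted to genes flagged anabolic or
catabolic — e.g. `G0008` passes criteria 1–3 but carries no
anabolic/catabolic flag in this simulation's catalog, so criterion 4
removes it:

```python
planted = set(truth.gene_sets["planted_up"])
flagged = {g for g in planted if truth.catalog.is_flagged(g)}
print("of which anabolic/catabolic:", sorted(flagged))
print("recovered in final list:", sorted(planted & set(result.final_genes)))
```

```
of which anabolic/catabolic: ['G0006', 'G0007', 'G0010', 'G0011', 'G0012']
recovered in final list: ['G0006', 'G0007', 'G0010', 'G0011', 'G0012']
```

— every planted pathway gene that is eligible for criterion 4 reaches the
final report.

The same workflow is available from the shell over TSV/GMT/BED files:

```bash
glycoreg simulate --seed 5 --out sim/
glycoreg de --expression sim/D1_expression.tsv --samples sim/D1_samples.tsv \
            --expression sim/D2_expression.tsv --samples sim/D2_samples.tsv \
            --expression sim/D3_expression.tsv --samples sim/D3_samples.tsv --out de/
glycoreg enrich --de-table de/de_D1.tsv --de-table de/de_D2.tsv \
                --de-table de/de_D3.tsv --gmt sim/gene_sets.gmt --out enr/
glycoreg regulation --expression sim/D1_expression.tsv --cna sim/D1_cna.tsv \
                    --dm sim/D1_dm.tsv --samples sim/D1_samples.tsv --out reg/
glycoreg tfnet --expression sim/D1_expression.tsv \
               --tf-expression sim/D1_tf_expression.tsv \
               --cna sim/D1_cna.tsv --dm sim/D1_dm.tsv \
               --samples sim/D1_samples.tsv \
               --peaks sim/peaks.bed --tss sim/tss.tsv --out tf/
glycoreg run-all --config cfg.yaml --seed 2 --out out/   # phase A end to end
glycoreg config-schema                                   # YAML schema
```

## Acceptance script

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes the whole workflow from scratch at the given seed: it simulates
three cohorts, runs phase A (differential expression → enrichment →
graph-regularized prediction → candidate selection, with all stage tables
and a manifest), then runs phase B on a TF-driven simulation (correlation
and δCor tables, Mann–Whitney tests, binding-map annotation, stability
selection in both groups, differential network and master regulators),
logging stage summaries to stderr and writing the results JSON to the
path given by `--out`.
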