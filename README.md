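# mvdsig

Deriving a **microvessel density (MVD) gene signature** from clustered
single-cell RNA-seq plus a paired bulk-expression / IHC model panel, and
using it — together with a T cell–inflamed gene expression profile
(Tcell_inf_GEP) — to characterize tumor microenvironments and their
response to antiangiogenic and immune-checkpoint therapy.

MVD (stained vessels per unit tumor area) predicts sensitivity to
antiangiogenic drugs, but IHC measurements are unavailable for most
transcriptomic cohorts. This package is for computational biologists who
want a reproducible, testable implementation of the signature-derivation
recipe: it ships every stage as a library function, a thin `mvdsig` CLI,
and a synthetic-data generator with planted ground truth so the whole
pipeline is verifiable without animal or patient data.

## The method

1. **EC markers.** In labeled single-cell data, genes enriched in the
   endothelial-cell (EC) cluster: Mann–Whitney U versus all other cells on
   library-size-normalized expression, Benjamini–Hochberg adjusted
   *P* < 0.05 and log₂ fold change > 1.
2. **Correlation ranking.** Across a panel of tumor models with replicate
   bulk TPM and paired MVD(IHC), rank candidates by Pearson *r* between
   per-model mean log₂(TPM+1) and mean MVD(IHC); keep the top 20 (plus any
   well-known EC markers such as *Kdr*, *Cdh5*, *Tek*).
3. **Specificity filter.** Keep genes whose single-cell expression is
   concentrated in the EC cluster (a numeric specificity index replaces
   manual inspection), truncate to six genes.
4. **Score.** For a sample with expression x, the MVD gene score is

   score(x) = (1/|G|) Σ_{g∈G} log₂(TPM_g + 1)

   and samples are classified MVD-high/low × Tcell_inf_GEP-high/low by
   cohort medians (strictly above = high), or models by the top quartile
   of per-model means (≥ threshold = high; 12 models → 3 high).
5. **Efficacy.** Tumor volume TV = 0.5 × length × width²; antitumor
   activity ΔT/C = (T_t − T₁)/(C_t − C₁) × 100 on arm means, with the
   regression branch (T_t − T₁)/T₁ × 100 when treated volumes fall below
   baseline; Welch *t* tests (BH-adjusted across models) link subgroups to
   activity.

## Worked example

```sh
python examples/02_derive_signature.py
```

```
EC-enriched candidate genes (adj P<0.05, log2FC>1): 40
...
derived signature (6 genes): G0597, G0954, G0282, G0691, G0165, G0291
of which planted EC markers: 6/6
```

All six derived genes are planted EC markers — the derivation recovered
the simulated vasculature axis. Scoring the panel
(`examples/03_score_and_classify.py`) prints

```
MVD gene score vs MVD(IHC) across 12 models: r = 0.96 (P = 3.9e-07)
```

the in-sample correlation between the transcriptomic score and the
simulated IHC measurement (inflated by gene selection on the same panel;
the held-out value sits near the calibrated population 0.8 — see
`docs/methods.md`). Relating subgroups to efficacy
(`examples/04_efficacy.py`), with an antiangiogenic effect planted in
MVD-high models only:

```
Welch t, MVD-high vs MVD-low ΔT/C: t = -59.33, df = 8.7, P = 1.2e-12
group means: high = 2.9, low = 75.8
```

ΔT/C near zero (growth arrest) in MVD-high models versus ≈76 in MVD-low
models: high vessel density marks sensitivity to the antiangiogenic arm.

The same stages are available from the shell:

```sh
mvdsig run --scenario panel12 --outdir runs/demo --seed 1
mvdsig score --expression runs/demo/panel.expression.tsv \
             --signature runs/demo/mvd_signature.yaml --out scores.tsv
```

## Layout

* `src/mvdsig/synthetic.py` — planted-truth generators (profiles,
  single-cell counts, model panel, growth curves)
* `src/mvdsig/markers.py` — normalization, marker test, BH, selection
* `src/mvdsig/signature.py` — correlation ranking, specificity, assembly
* `src/mvdsig/scoring.py` — scores, thresholds, quadrants, proportions
* `src/mvdsig/efficacy.py` — TV, ΔT/C, Welch tests, group comparisons
* `src/mvdsig/io.py`, `src/mvdsig/pipeline.py`, `src/mvdsig/cli.py` —
  plain-text IO, orchestration with manifests, CLI
* `docs/methods.md` — model assumptions, conventions, calibration, limits
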