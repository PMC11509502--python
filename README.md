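# proteopair

Paired two-tissue label-free proteome comparison built around binary
appearance patterns. Given a protein × sample intensity table and a paired
design (each subject contributes one sample per condition), the pipeline:

- binarizes intensities (1 = observed with any positive intensity),
- detects **condition-unique proteins** (present in ≥ a threshold fraction of
  subjects in one condition, absent from the other) with a pooled
  two-proportion z-test,
- runs three-way **paired differential expression** per protein (paired t,
  Wilcoxon signed-rank with exact small-sample p-values, proportion test)
  with Benjamini–Hochberg FDR control per test family,
- aggregates the three rank lists by **min-rank** into one ranked protein
  list,
- computes sample-level structure: 3D **PCA** of the binary appearance
  matrix and the observed/expected **overabundance** curve with its plug-in
  FDR estimate,
- scores user-supplied gene sets (GMT) against the ranked list with the
  **minimum-hypergeometric (mHG)** statistic, including its exact p-value by
  dynamic programming.

A seeded synthetic generator (`proteopair.synthetic_data`) produces paired
proteomes with planted condition-unique and intensity-shifted proteins plus
annotation sets, so every stage is testable offline.

## CLI

```sh
# full analysis on real tables
proteopair run --intensities proteins.tsv --design design.csv \
    [--gmt sets.gmt] --out results/ [--min-fraction 0.4] \
    [--transform raw|log2p1] [--seed 0]

# generate a synthetic paired proteome and analyze it end-to-end
proteopair simulate [--config params.yaml] --out results/ --seed 0

# appearance-only analysis of the built-in 23-protein unique-protein fixture
proteopair fixture --out results/

# enrichment of a GMT against an existing ranked list
proteopair enrich --ranked results/ranked_proteins.tsv --gmt sets.gmt --out enr/
```

Input formats: intensity TSV (header row with a protein-id column, default
`Protein IDs`, plus one non-negative numeric column per sample; blank/NaN
cells are treated as 0 = not observed), design CSV with columns
`subject,sample,condition` (exactly two conditions, one sample per subject
per condition), and standard GMT gene sets.

Outputs per run: TSVs for per-sample counts, unique proteins, differential
expression, overabundance, PCA embedding, ranked list and enrichment; PNG
plots (per-sample counts, 3D PCA, overabundance, volcano); `summary.json`;
`run.log`. Runs are byte-reproducible per seed.

## Library example

```python
from proteopair import (
    read_intensity_table, read_design, binarize,
    detect_unique_proteins, run_differential_expression, min_rank_list,
)

m = read_intensity_table("proteins.tsv")
d = read_design("design.csv")
unique = detect_unique_proteins(binarize(m), d, min_fraction=0.4)
ranked = min_rank_list(run_differential_expression(m, d))
```

## Tests and acceptance report

```sh
python -m pytest -q tests/            # unit + property + acceptance suite
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

The acceptance script recomputes the headline quantities (proportion-test
p-values for the published presence counts, unique-protein counts on the
built-in fixture, plug-in FDR estimates) from scratch and writes them as
JSON.
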