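# pepqc

Quality control for mass-spectrometry-based immunopeptidomics.

Immunoaffinity purification of MHC (HLA) molecules followed by LC-MS/MS
yields per-sample lists of presented peptides — the immunopeptidome.
Before any biological interpretation, two questions need an answer per
sample: *did the isolation enrich genuine MHC ligands*, and *do the
peptides match the binding specificity of the sample's alleles*?  `pepqc`
answers both automatically for one sample or for hundreds, producing a
portable HTML report and a machine-readable metrics file per batch.

## What it computes

For each sample (peptide list + MHC class + up to six alleles):

* **Preprocessing** — flanking residues (`P.KAPDNRETL.V` → `KAPDNRETL`)
  and chemical-modification annotations (`M(ox)…`, `C[+57.021]…`) are
  stripped, non-canonical sequences removed, duplicates collapsed.
* **LF (length fraction)** — the fraction of all peptides whose length is
  in the class-appropriate range (8–12 for class I, 9–22 for class II).
  Genuine class I ligands are mostly 9-mers; co-isolated proteolytic
  fragments are longer, so a low LF signals contamination.
* **%rank annotation** — every in-range peptide is scored per allele with
  an eluted-ligand percent rank (lower = stronger) and called
  **SB** (strong binder), **WB** (weak binder) or **NB** (non-binder):
  class I SB ≤ 0.5, WB ≤ 2.0; class II SB ≤ 2.0, WB ≤ 10.  A peptide's
  aggregate call across alleles is its best call.  Scores come from a
  deterministic PSSM-based mock predictor, or from NetMHCpan-4.0/4.1 /
  NetMHCIIpan-4.0 output files via a text adapter.
* **BF (binding fraction)** — the fraction of in-range peptides called SB
  or WB: an index of MHC specificity.  LF and BF near 1 mean a clean,
  allele-specific isolation.
* **Motif deconvolution** — a Gibbs sampler groups peptides into motif
  clusters while aligning their 9-residue binding cores, both
  *unsupervised* (1–6 candidate groups, best chosen by Kullback–Leibler
  distance) and *allele-specific* (one group per allele's predicted
  binders, 1–5 groups for the all-NB remainder; subsets under 20 peptides
  are skipped).
* **Sequence logos** — Hobohm-1-weighted, pseudocount-corrected Shannon or
  KLD logos of every motif group.
* **Report** — a self-contained `report.html` (length histograms, QC
  table, UpSet intersections, binding bar plots, capped and
  lexicographically sorted %rank heatmaps, motif logos), editable PDF
  figures, all underlying data tables, and `sample_metrics.txt`.

## Worked example

Generate a small synthetic two-sample cohort (one clean sample, one with
50 % long contaminant peptides) and run the pipeline:

```python
from pepqc import synthetic_data as sd

motifs = sd.builtin_motifs()
cohort = sd.CohortSpec(samples=[
    sd.SampleSpec("tumor_a", [motifs["SYN-A"], motifs["SYN-B"]],
                  n_binders_per_allele=150),
    sd.SampleSpec("plasma_b", [motifs["SYN-A"]],
                  n_binders_per_allele=150, contaminant_fraction=0.5),
], rng_seed=42)
sd.build_cohort(cohort, "demo/peptides")
```

```bash
pepqc demo/peptides/tumor_a.txt demo/peptides/plasma_b.txt \
      --alleles SYN-A,SYN-B --class I --output demo/qc --seed 1
```

```
report: demo/qc/report.html
samples: 2
```

`demo/qc/sample_metrics.txt` then contains:

```
sample	total_peptides	lf_score	bf_score
tumor_a	300	1.00	0.93
plasma_b	300	0.50	0.95
```

Reading: `tumor_a` is a clean ligandome — every peptide is 8–12 residues
(LF 1.00) and 93 % of them are predicted binders of its two alleles.
`plasma_b` has LF 0.50: half its peptides are longer than 12 residues
(the injected contaminants), exactly the signature of co-isolated
proteolytic background; the in-range half is still allele-specific
(BF 0.95).  The run log also notes that the SYN-B allele subset was
discarded for `plasma_b` (no SYN-B binders in the sample, as expected).
The HTML report shows the same numbers together with the length
histograms, heatmaps and motif logos.

Real peptide lists work the same way: pass `.txt`/`.csv`/`.tsv` files
(use `--column` to pick the sequence column), or a YAML config with
per-sample alleles (`pepqc --config run.yaml`).  To use real predictions,
run NetMHCpan/NetMHCIIpan yourself and feed the output through
`pepqc.binding.parse_external_rank_output`.

## Layout

| module | role |
| --- | --- |
| `pepqc.peptide_io` | reading and normalizing peptide lists |
| `pepqc.binding` | %rank prediction (mock + external adapter), SB/WB/NB calls |
| `pepqc.metrics` | LF/BF scores, length histograms, UpSet intersections, metrics file |
| `pepqc.motif_cluster` | Gibbs-sampling motif deconvolution and KLD model selection |
| `pepqc.logo` | Hobohm-1 weighting, pseudocounts, Shannon/KLD logos |
| `pepqc.report` | heatmap ordering, figures, HTML report bundle |
| `pepqc.synthetic_data` | ground-truth synthetic cohorts |
| `pepqc.cli` | `pepqc` command-line entry point |

See `docs/methods.md` for the underlying models, parameter choices and
known limitations.
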