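# atf6rg — ATF6-responsive gene analysis

ATF6 is an ER-membrane-tethered transcription factor that is cleaved upon ER
stress and activates unfolded-protein-response genes by binding bipartite ER
stress response elements (ERSE I: `CCAAT`-N9-`CCACG/A`; ERSE II:
`ATTGG`-N1-`CCACG`) in target promoters. Comparing wild-type and
*ATF6*-knockout human cells (mesenchymal stem cells, embryonic stem cells,
white adipocytes) with and without a 12-h tunicamycin (TM) challenge
distinguishes two responsive-gene classes:

* **CARGs** (constitutive ATF6-responsive genes) — significantly
  downregulated in the knockout at *both* early and late culture passage,
  without any stressor;
* **IARGs** (induced ATF6-responsive genes) — upregulated by TM in wild-type
  cells *and* blunted in the knockout under TM.

`atf6rg` implements the full computational side of such a study as a tested,
seed-reproducible pipeline for statisticians and genomicists who want the
analysis logic without a 100-GB alignment stack:

1. **NB differential expression** — for counts $K_{gj}$ with mean
   $\mu_{gj}$ and dispersion $\alpha_g$ (Var $= \mu + \alpha\mu^2$):
   median-of-ratios size factors, gene-wise method-of-moments dispersions
   shrunk toward a Cox–Reid pooled common dispersion, a two-group Wald test
   on $\log_2$ fold change ($z = \widehat{\mathrm{lfc}} / \mathrm{SE}$ vs.
   $\mathcal N(0,1)$), Benjamini–Hochberg FDR, and FPKM
   ($10^9 \cdot K_{gj} / (L_g N_j)$).
2. **Set logic** — CARG/IARG derivation as per-contrast DEG intersections,
   CARG∩IARG overlap, and the 3-cell-type Venn partition of IARGs.
3. **ERSE scanning** — exact and mismatch-tolerant bipartite motif matching
   over TSS-anchored promoter windows (−10 kb … +2 kb), strand-aware, with a
   closed-form background-rate calibration.
4. **ChIP promoter signal** — input-subtracted per-million density
   normalization, $t_i/\Sigma t \cdot 10^6 - c_i/\Sigma c \cdot 10^6$ on the
   union interval grid, and H3K4me3 promoter-window summaries per gene set.
5. **Synthetic data with planted truth** — an NB count simulator over the
   factorial study design, promoter sequences with planted ERSEs, and
   H3K4me3-like treat/control tracks, so every stage is testable end to end
   and recovery (sensitivity, empirical FDR) is measurable against ground
   truth.

Standard text formats are used throughout: counts and sample sheets as TSV,
promoters as FASTA, TSS tables as BED6, ChIP tracks as bedGraph, gene sets
as TXT + JSON.

## Worked example

```python
from atf6rg.pipeline import run_pipeline

config = {
    "seed": 1,
    "outdir": "example_out",
    "synthetic": {"cell_types": ["hMSC"], "n_reps": 3},
}
bundle = run_pipeline(config)

rec = bundle.recovery["hMSC"]
print(f"CARG recovery: sensitivity={rec['carg_down']['sensitivity']:.3f} ...")
```

prints

```
CARG recovery: sensitivity=0.829 FDR=0.000 (174 called / 210 planted)
IARG recovery: sensitivity=0.944 FDR=0.013 (153 called / 160 planted)
CARG & IARG shared genes: 8
promoters with a canonical ERSE: 417 / 467 scanned
           n_genes  mean_WT  mean_KO  pvalue
gene_set
CARG_hMSC      174   0.4089   0.0035  0.0000
IARG_hMSC      151   0.4123   0.0067  0.0000
null           100  -0.0005   0.0023  0.6343
```

Reading: of 210 planted CARGs (200 pure + 10 that are also IARGs), 174 were
recovered at the default thresholds (BH q < 0.05, |log2FC| ≥ log2 1.5) with
no false positives; 8 of the 10 dual-class genes survive differential
expression in both branches and land in the CARG∩IARG overlap. Scanning
finds the canonical ERSE planted in most responsive-gene promoters (the
remainder and the ~0.05 expected spurious hits per 12-kb window follow the
analytic background rate). The H3K4me3 promoter signal is higher in WT than
knockout at CARG/IARG promoters (paired t-test across genes) and flat at
null genes.

The same run is available from the shell:

```sh
atf6rg all --config run.yaml --seed 1 --out example_out
```

with `run.yaml` holding the config block above; subcommands `simulate`,
`de`, `sets`, `scan`, `chip` execute the pipeline up to that stage. Outputs
are per-contrast DE tables, gene-set TXT/JSON with Venn region counts,
motif-hit tables, ChIP summaries, a recovery report, and a `manifest.json`
(seed, thresholds, sha256 of every output) that makes reruns bit-identical.

User data can replace the simulator: supply `inputs: {counts: ..., samples:
..., promoters: ..., tss: ..., chip_tracks: ...}` instead of the
`synthetic:` block.

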