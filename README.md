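# shscreen

Gene-centric follow-up of GWAS loci with pooled shRNA dropout screens.

Genome-wide association studies nominate loci, not genes. One way to close
that gap for cell-intrinsic traits — here, red-blood-cell traits read out
during in vitro erythropoiesis — is to knock down every plausible candidate
gene at every associated locus at once with a pooled shRNA library, track
hairpin abundances by sequencing across a differentiation time course, and
ask which genes' suppression changes cell fitness or differentiation.
`shscreen` implements that analysis end to end, together with a synthetic
data generator with known ground truth so every stage is testable without
any external data:

1. **Locus → candidate genes.** Each sentinel SNP is expanded to its LD
   block (all panel SNPs with r² ≥ 0.8, r² = squared Pearson correlation of
   unphased dosages), the block is extended outward to the inner edges of
   the nearest flanking recombination hotspots, and every gene whose
   regulatory *wingspan* — 110 kb upstream of the transcription start,
   40 kb downstream of the transcription end, strand-aware — overlaps the
   extended window is nominated. Coordinates are 0-based half-open
   throughout.
2. **Counts → response.** Hairpin counts get a pseudocount of 1, are
   normalized to counts per million and log2-transformed; the model
   response is y = log2CPM(day t) − log2CPM(day 4 baseline) per hairpin
   and donor replicate.
3. **Per-gene longitudinal mixed model.** For each gene,
   `y ~ 0 + day + (per-day random effect | hairpin)`: a categorical fixed
   effect per post-baseline day (cumulative log2FC) plus a per-hairpin
   random term absorbing knockdown-efficiency and off-target deviations,
   fitted by REML. Each coefficient gets a Wald χ²(1 df) test;
   Benjamini–Hochberg adjustment is applied jointly across all gene × day
   tests.
4. **Dual-threshold hit calling.** A gene is a hit when some day shows
   |fitted slope| > 0.1 log2FC/day *and* q < 0.1 — filtering out both
   noisy large effects and confident minuscule ones. Hits are summarized
   per locus.
5. **Permutation validation.** Four permutation-null statistics compare
   the hit set against annotation axes (essentiality scores, a
   gold-standard gene list via rank sums, coding-variant overlap with an
   exact hypergeometric cross-check, per-stage expression z-scores), plus
   a Fisher-exact comparison with eQTL-window-based nomination. Empirical
   p values use the add-one estimator and are never zero.

## Worked example

Run the whole pipeline on a simulated screen (200 genes at 50 loci, 6
hairpins per gene, 3 donor replicates, days 4–16, 10% of genes carrying a
true dropout/enrichment slope):

```sh
shscreen run --outdir example --seed 7
```

prints

```
shscreen run summary
====================
genes tested:        200
hit genes:           21 (7 depleted, 14 enriched)
loci with >=1 hit:   20 / 50
hits per locus:      1 hit(s): 19 loci, 2 hit(s): 1 loci
day-4 representation: 100.0% of 1211 hairpins >= 5.0 log2 CPM
enrichment coding_overlap: p = 0.02598
enrichment essentiality_genome: p = 1e-05
enrichment essentiality_library: p = 7e-05
enrichment gold_rank_sum: p = 1e-05
enrichment stage1: p = 0.912
enrichment stage2: p = 0.6854
enrichment stage3: p = 5e-05
enrichment stage4: p = 0.7834
enrichment stage5: p = 0.9987
```

Reading this: the simulation planted effects in 10% of genes (≈20); the
caller recovered 21 hits spread over 20 loci. The annotation generator
wires essentiality, the gold list, coding flags and stage-3 expression to
the true effect genes, so all four validation axes light up — tiny p for
essentiality/gold/stage-3, a modest one for the sparser coding-variant
overlap — while the non-active stages stay null. `example/` holds every
stage table (TSV), QC and enrichment JSONs, and a `manifest.json` with
config echo, row counts, wall times and output checksums. Rerunning with
the same seed reproduces every table byte for byte.

Each stage is also available separately (`simulate`, `nominate`,
`preprocess`, `fit`, `call-hits`, `enrich`, `report`) and as library
functions (`shscreen.fit_gene`, `shscreen.nominate_all`, ...).

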