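# hiddenstops

Statistics of **off-frame stop codons (OSCs)** — stop triplets (TAA/TAG/TGA)
read in the +1 or +2 frame of coding sequences, also called *hidden stops* —
for anyone evaluating frameshift-robustness ("ambush") arguments on bacterial
transcriptomes or synthetic coding sequence.

The package implements the two classic analyses end-to-end:

1. **Codon usage vs OSC potential.** Every sense codon can complete an
   off-frame stop with a neighboring codon in *w(c) ∈ {0,…,6}* distinct
   (stop, junction-offset) ways. Per organism we correlate relative codon
   usage with *w* (Spearman ρ over the 61 sense codons, plus an OLS slope),
   then regress the per-organism slope on genomic GC content across a panel.
   Because stop codons are AT-rich, this relationship is driven almost
   entirely by GC content.

2. **Observed vs expected off-frame counts.** For each organism we count
   occurrences of any target codon in the +1/+2 frames (never spanning
   transcript boundaries), train an order-*k*, 3-periodic Markov model
   (*k* ∈ {2, 5}: the "2–3" and "5–3" models) on the same filtered
   transcripts, generate *N* = 200 length-matched randomized replicate
   transcriptomes, and summarize the excess as the log ratio

   ```
   L = ln( O / mean(E₁…E_N) )
   ```

   with an empirical one-sided rank p-value, p ≥ 1/(N+1). Panel summaries
   report the percentage of organisms with L > 0, the mean L, and the
   OLS regression of L on GC content — for the pooled stop set and for each
   of the 64 codons individually, so stop-codon excesses can be judged
   against the sense-codon background.

A synthetic-transcriptome generator (GC-driven codon law, optional
dicodon-level off-frame enrichment of a chosen codon at effect size δ)
makes every stage testable without downloading genomes.

## Worked example

Simulate a 3-organism GC gradient, scan it, and run the usage analysis:

```
hiddenstops simulate --outdir demo --seed 5 --gc-grid 0.35,0.5,0.65 \
    --n-transcripts 100 --length-codons 200
hiddenstops scan --manifest demo/manifest.tsv --order 2 --replicates 200 \
    --seed 5 --outdir demo/scan
hiddenstops usage --manifest demo/manifest.tsv --outdir demo/usage
```

or equivalently in Python (the library is the primary interface):

```python
import numpy as np
import hiddenstops as hs

panel = hs.generate_panel(np.linspace(0.3, 0.7, 9), master_seed=1,
                          n_transcripts=150, length_codons=150)
organisms = [hs.filter_transcripts(t)[0] for _, t in panel]

results = [hs.usage_vs_potential(hs.codon_usage(t), organism_id=t.organism_id,
                                 gc=hs.gc_content(t)) for t in organisms]
print(hs.slope_vs_gc(results))

scans = hs.scan_panel(organisms, orders=(2,), n_replicates=100, base_seed=7920)
for order, s in hs.panel_summaries(scans):
    if s.target == "ALL_STOPS":
        print(s)
```

On this synthetic null panel the `scripts/acceptance.py` driver (same
computation) prints:

```
usage panel (9 organisms): slope=-0.01911 intercept=0.009849 R^2=0.9997 sig_pos=4 sig_neg=4
order 2 ALL_STOPS: pct_excess=33.3 mean_L=-5.325e-04 gc_slope=-5.919e-03 r=-0.301
order 2 TGA: pct_excess=66.7 mean_L=-5.967e-05 gc_slope=-9.173e-03 r=-0.278
```

Reading the numbers: the per-organism usage-vs-potential slope falls almost
perfectly linearly with GC (R² ≈ 1.0, negative slope — high-GC organisms
*disfavor* high-potential codons), with significant positive Spearman
correlations only at the AT-rich end; and because these organisms contain no
built-in off-frame enrichment, the excess statistic is properly calibrated:
mean L ≈ 0 and the fraction of organisms with L > 0 hovers around chance.

## Input expectations

Per-organism CDS FASTA (one record per transcript, coding strand, frame 0).
Filtering drops transcripts whose length is not a multiple of 3, that contain
non-ACGT characters, or that contain an internal in-frame stop, and strips one
terminal stop codon; no minimum-length cutoff is applied. Organisms with
reassigned stop codons must be excluded by the caller (only the standard code
ships as default).

## Outputs

TSV throughout (floats at 6 significant digits): `per_organism_excess.tsv`
(organism_id, gc, order, target, observed, expected_mean, expected_sd,
log_ratio, p_emp, p_norm, significant, p_bonferroni), `panel_summary.tsv`
(order, target, n_organisms, n_undefined, pct_excess, mean_log_ratio,
gc_slope, gc_intercept, gc_pearson_r), `usage_potential.tsv`,
`usage_panel.tsv`, `filter_report.tsv`, plus a serialized `run_config.json`
per run. `hiddenstops panel-merge` recombines per-organism tables from split
runs.

## Acceptance driver

`python scripts/acceptance.py --seed <int> --out results/acceptance.json`
re-runs the whole pipeline from scratch on a seeded synthetic GC panel —
generation, filtering, usage analysis, order-2 scan with replicate nulls —
prints the panel summaries, and writes the results JSON.

See `docs/methods.md` for the model details, parameter defaults, the
synthetic generator's scope, and known limitations.
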