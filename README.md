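# mrnafate

Transcriptome-wide dissection of mRNA fate under deadenylase-complex
(Ccr4-Not / CNOT1) perturbation: half-life estimation from transcriptional
shutoff time courses with robust outlier removal, codon and amino-acid
composition statistics and their association with stability changes,
translational-efficiency (TE) classification and metagene occupancy deltas
from ribosome-profiling position tables, condition-dependent ribosome
pause-site calling, gradient-boosted feature-influence attribution, and
ERCC-anchored ER/cytosol localization clustering. A synthetic-data module
generates all inputs with known ground truth, so the full pipeline runs
and is tested without any external download.

## The models in brief

- **Decay.** y(t) = y0 e^(-kt) per transcript and condition, fitted to
  time courses normalized to 100 at 0 h (timepoints 0, 0.5, 1, 2, 4, 8,
  16 h; three replicates pooled). A Huber IRLS fit on relative residuals
  precedes an FDR-style outlier test: weighted residuals
  r = |obs - exp|/exp, robust scale RSDR = P68(|r|) * N/(N - K), step-down
  thresholds alpha_i = Q (N - (i - 1))/N (largest residual tested at Q/N),
  t-scores r/RSDR, at most 20% of points flagged. Final plain least
  squares on retained points; t1/2 = ln(2)/k.
- **Codon-stability association.** Spearman rho between each sense
  codon's frequency and the per-transcript log2 fold change in half-life,
  annotated by wobble-position nucleotide (G/C- vs A/U-ending).
- **TE.** log2FC TE = log2FC RPF - log2FC RNA (median-of-ratios
  normalization, 0.5 pseudocount); classes increased (> 0.2), decreased
  (< -0.2), none (|te| < 0.1), unclassified between.
- **Pauses.** A pause is a codon (outside the first 15 / last 5 codons)
  whose abundance-normalized occupancy exceeds 10x its mRNA's mean;
  across conditions a site is sustained (paused in both), resolved
  (control-only, drop > 10x the mRNA's average delta decrease), or
  induced (knockdown-only, rise > 10x the average delta increase).
- **Influence.** Gradient-boosted trees (200 trees, depth 6, shrinkage
  0.005, 10-fold CV diagnostics) on de-correlated features (|r| <= 0.7);
  relative influence = split-improvement attribution normalized to 100.
- **Localization.** ERCC spike-in totals equalized across fractions, CPM,
  2-means on log2(CPM+1); half-life clustering with k at the log-WSS
  elbow.

See `docs/methods.md` for assumptions, parameter defaults, and design
rationale.

## Worked example

Simulate a small experiment, fit half-lives, and classify TE:

```sh
mrnafate --seed 5 simulate --n-transcripts 80 --out-dir demo
mrnafate decay-fit --counts demo/decay_course.tsv --out demo/fits.tsv
mrnafate te --rpf demo/rpf_counts.tsv --rna demo/rna_counts.tsv --out demo/te.tsv
```

prints

```
wrote synthetic dataset (80 transcripts) to demo
fitted 160 courses (159 ok); median half-life 14.5 h
te_class
increased       33
decreased       23
none            14
unclassified    10
```

The 160 courses are 80 transcripts x 2 conditions. The median over *both*
conditions (14.5 h) sits between the control median (~6.7 h by
construction) and the globally stabilized knockdown half-lives (mean
Δlog2 ≈ 2.1). The TE classes reflect the planted ±1 log2 shifts in
balanced thirds; at n = 80 with planted pause peaks a handful of "none"
transcripts land in the unclassified 0.1-0.2 gap.

The same operations are importable as a library:

```python
from mrnafate.synthetic import SimulationSpec, simulate_transcriptome, simulate_decay_course
from mrnafate.decay import normalize_to_t0, fit_all, log2fc_table

spec = SimulationSpec(n_transcripts=500, seed=1)
transcripts, truth = simulate_transcriptome(spec)
courses, _ = normalize_to_t0(simulate_decay_course(spec, truth))
fits = fit_all(courses)                    # y0, k, half_life, outliers per course
log2fc = log2fc_table(fits)                # knockdown vs control stability change
```

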