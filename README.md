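# twindiverge

Comparative transcriptome evolution between two closely related species —
the kind of analysis run on a pair of recently diverged sister taxa (for
example, congeneric hermit crab species once thought to be color morphs)
whose coding-sequence divergence is low (dS ≈ 0.02–0.03) and whose
tissue-level expression has begun to drift apart.

The package implements the full downstream analysis that follows assembly
and quantification:

- **Orthology** — reciprocal best hits (RBH) by bit score from two
  directed similarity-search tables define "one-to-one" gene pairs;
  remaining genes are classed as other homologs or species-unique.
- **Coding regions** — six-frame ORF extraction (stop-to-stop, ≥ 50 aa)
  with longest-ORF selection and stop-codon stripping.
- **Codon alignments** — global pairwise protein alignment, back-translation
  to codon alignments, complete deletion of gap/unknown columns,
  concatenation, codon-position partitioning and first-of-4-window
  subsampling.
- **Selection** — pairwise dN/dS by two estimators: NG86
  (equal-weight site/pathway counting with Jukes–Cantor correction,
  d = −¾ ln(1 − 4p/3)) and YN00 (κ- and F3x4-frequency-weighted counting
  with K80 corrections, κ estimated from four-fold/zero-fold degenerate
  sites, ω iterated to convergence). Each transcript is classified by the
  error-interval rule: *positive* if dN − dN_err > dS + dS_err,
  *purifying* if dS − dS_err > dN + dN_err, else *neutral*.
- **Expression** — expected-count noise filtering, TMM normalization,
  log2 CPM, selection of the two most consistent replicates per
  species × tissue, cross-species Pearson/Spearman correlation over
  one-to-one genes, DEG overlap between tissues, and Fisher exact tests of
  species bias.
- **Enrichment** — keyword-derived gene sets (e-value ≤ 0.001 hits against
  a reference) and upper-tail hypergeometric term enrichment with
  Bonferroni correction (significant at adjusted p < 0.05).
- **Simulation** — generators for all of the above with ground truth: a
  codon substitution process (rates ∝ π_j · κ^[ts] · ω^[nonsyn], stop
  codons unreachable), ortholog catalogs with planted duplications and
  losses, negative-binomial count matrices for a
  2 species × 2 tissues × 3 replicates design, and annotations with one
  planted enriched term.

## Worked example

Evolve a 5,000-codon ortholog pair at the divergence typical of recently
split sister species (target dS 0.025, κ = 2, ω = 0.25) and estimate its
divergence with the YN00 method:

```python
from twindiverge import SimulationParams, simulate_codon_pair
from twindiverge import selection as sel

params = SimulationParams.with_target_ds(0.025, length=5000, kappa=2.0,
                                         omega=0.25, seed=42)
cds_a, cds_b, truth = simulate_codon_pair(params)
rec = sel.yn00_estimate(cds_a, cds_b, pair_id="demo")
print(f"kappa = {rec.kappa:.2f}")
print(f"dS = {rec.dS:.4f} +/- {rec.dS_err:.4f}")
print(f"dN = {rec.dN:.4f} +/- {rec.dN_err:.4f}")
print(f"omega = {rec.omega:.3f}")
print(f"class = {sel.classify_record(rec).value}")
```

prints

```
kappa = 1.95
dS = 0.0247 +/- 0.0025
dN = 0.0057 +/- 0.0007
omega = 0.230
class = purifying
```

The estimator recovers the generating κ, dS and ω within sampling error,
and the error-interval rule calls the pair purifying, as expected for
ω = 0.25: dS − dS_err = 0.0222 exceeds dN + dN_err = 0.0064.

A command-line interface mirrors the library:
`twindiverge orthology|coding|dnds|expression|geneset|enrich|simulate`
(see `twindiverge --help`).

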