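# Methods

This note records the models, the defaults and the numerical choices
behind each analysis stage, what the synthetic-data generators emulate,
and the known limitations.

## Orthology

Best hits are selected per query by maximal bit score. Bit-score ties are
broken by smaller e-value, then longer alignment length, then
lexicographically smaller subject id; this makes the output deterministic
where the underlying search tool leaves the order unspecified. When one
query has several rows (HSPs) against the same subject, the row with the
maximal bit score represents the pair before best-hit selection — the
simplest consistent reduction.

"Homology" means presence of any row in the hit table: significance
thresholds are assumed to have been applied when the table was produced by
the search engine, so the module applies none of its own. The homology
classes (unique / one-to-one / other homolog) partition the query set.

Limitations: no many-to-many resolution, no synteny, no clustering-based
orthogroups — RBH only.

## Coding regions

ORFs are maximal stop-to-stop segments in all six frames; an initial ATG
is **not** required because assembled transcripts are frequently
5'-truncated. The minimum length (default 50 amino acids) counts sense
codons only; a bounding stop codon is retained in the reported CDS and
removed later by `strip_stop`. Coding selection is the longest-ORF rule
with deterministic ties (5'-most start, then + strand). This is a
deliberate simplification of likelihood-based coding prediction: it keeps
the pipeline self-contained, at the cost of occasionally preferring a long
untranslated frame over a shorter true coding frame.

## Codon alignments

Pairwise global protein alignment uses Needleman–Wunsch (Biopython's
PairwiseAligner) with BLOSUM62 and affine gaps, open 10 / extend 1 under
the convention that a gap of length k costs open + k·extend; simple
match/mismatch scoring is available for didactic cases. Traceback is
deterministic (the aligner's first reported alignment). Back-translation
replaces each residue by its source codon and each gap by `---`, verifying
that every degapped row translates its CDS exactly.

Column preprocessing: "complete deletion" removes every column containing
a gap or an unknown residue in any row — X for proteins, any codon
containing N for nucleotides — and operates on whole codons in codon
alignments; it is idempotent. Gap/unknown deletion is applied per cluster
*before* concatenation. Subsampling keeps the first column of each
4-column moving window (columns 1, 5, 9, …), so a width-w alignment
yields ceil(w/4) columns.

## Divergence estimation

Both estimators consume a pair of aligned, gapless coding sequences
(after column deletion), compressed internally to codon-pair counts.
Columns containing a stop or ambiguous codon are skipped and flagged.
Pairs with fewer than 50 gapless codons are excluded from transcript-level
analyses.

**NG86.** Per codon, each position contributes the fraction of its
admissible single-nucleotide changes that are synonymous; changes to stop
codons are excluded and the fraction renormalised over the admissible
changes, so every codon still contributes exactly 3 sites. Site totals S
and N are averaged over the two sequences. Differences between codons are
averaged over all minimal mutational pathways that avoid stop codons (if
every pathway is blocked, the constraint is relaxed for that pair —
a vanishingly rare case). Proportions pS = Sd/S and pN = Nd/N are
corrected with Jukes–Cantor, d = −¾ ln(1 − 4p/3), with the large-sample
standard error sqrt(p(1−p)/L) / (1 − 4p/3), L = S or N. Proportions at or
beyond the correction domain (p ≥ 3/4) produce flagged records that are
excluded downstream rather than clamped — clamping would distort medians.

**YN00.** κ is estimated once from positions whose degeneracy class
(four-fold or zero-fold) agrees between the two codons, via the
two-parameter K80 correction with the two classes combined weighted by
site counts (κ = 2·d_ts/d_tv); degenerate cases fall back to κ = 2. Site
counts weight each possible change by the mutation rate π_target ·
κ^[transition] (F3x4 codon frequencies from the pooled nucleotide
composition at each codon position); per codon, the synonymous site count
is 3 × (synonymous mutation rate / total mutation rate). Differences are
counted by weighting each minimal pathway by its rate product under the
current (κ, ω) — ω multiplying nonsynonymous steps — and dS, dN are
corrected with K80 on the transition/transversion proportions at
synonymous and nonsynonymous sites. ω starts at 1 and (with
t = 3(S·dS + N·dN)/(S+N)) is iterated until successive dS and dN change
by < 1e-8, at most 100 iterations; κ stays at its degenerate-site
estimate throughout, since the counts it is estimated from do not change
across iterations. Standard errors use the delta method on the aggregate
proportions (pS, pN) with the Jukes–Cantor response derivative — a
deliberate, documented stand-in for the reference tool's unpublished
formulas, accurate at the low divergences this package targets.

**Classification.** Positive iff dN − dN_err > dS + dS_err; purifying iff
dS − dS_err > dN + dN_err; else neutral. The rule is scale-invariant.
Undefined records are *unclassified*, not neutral. Elevated dN/dS can also
reflect relaxed purifying selection; the class labels make no attempt to
distinguish the two.

## Expression

The noise filter drops genes whose expected counts *summed over samples*
fall below 2 (a gene summing exactly 2 is kept). The per-sample reading
would be stricter; the total is the weaker and is the documented choice.

TMM follows the published trimmed-mean-of-M-values procedure: reference
sample by 75th-percentile count fraction closest to the mean; genes with a
zero in either sample excluded; 30% two-sided trim on M, 5% on A;
precision weighting by the inverse asymptotic variance of M; factors
centred to geometric mean 1. The implementation reproduces Bioconductor
edgeR's `calcNormFactors` to ~1e-6 on a frozen reference matrix (see the
expression tests). Normalization is log2(CPM + 1) on TMM-effective library
sizes — finite at zero and monotone within a sample.

Replicate consistency is operationalised as the pair with maximal Pearson
correlation of log2-normalized values within each species × tissue group
(ties: lexicographically smallest pair). Cross-species correlation is
computed over the group-mean expression of one-to-one genes. The Fisher
exact test is two-sided (tables no more probable than observed), with
p = 1 by convention at a zero margin. Differential-expression fitting
itself is consumed from external tables; this module implements only the
downstream statistics.

## Enrichment

Upper-tail hypergeometric only — the analyses report overrepresentation,
not depletion. The population is restricted to genes with at least one
term; terms with no annotated gene are dropped; Bonferroni's m is the
number of terms actually tested after those exclusions. Fold enrichment is
(k/n)/(K/N). Annotation maps are used as given — no propagation up the
ontology graph, since no traversal procedure is assumed. Significance is
adjusted p < 0.05, strict.

## Simulators

*Codon pairs.* A continuous-time codon model with rates q_ij ∝ π_j ·
κ^[transition] · ω^[nonsynonymous] for single-nucleotide changes between
sense codons (stop codons unreachable), normalised to one expected
substitution per codon per unit t at stationarity; the process is
reversible with stationary distribution π. An ancestor drawn from π
evolves independently for t/2 along each lineage by exact event-level
(Gillespie) simulation, which also yields per-event truth labels.
`SimulationParams.with_target_ds` converts a target dS into t through the
process' synonymous rate and mutation-weighted synonymous site count.
Defaults mirror the regime of recently diverged sister species: dS ≈
0.025, ω = 0.25, κ = 2, uniform codon frequencies.

*Ortholog catalogs.* True pairs evolved at the default divergence, with
hit tables synthesised from the planted structure. A planted duplication
adds a species-A paralog whose bit scores break reciprocity in both
directions (the partner's best hit is the paralog; the paralog's best hit
is a wrong partner), so such pairs are unrecoverable as one-to-one and
never produce a false positive. Losses add species-unique genes
(Binomial(n_pairs, loss_fraction) per species) with no hits.

*Counts.* Negative-binomial (var = m + φm²) with gene-wise log2 baselines
Normal(6, 2), dispersion φ = 0.05, tissue effects Normal(0, 1), and the
species-B latent expression correlated with species A at exactly the
configured ρ (the shared biological deviation is rescaled so the planted
correlation is the parameter itself). Planted species effects of
|log2FC| ~ Uniform(1, 3) affect a configurable per-tissue fraction with a
configurable up-in-A probability; the truth tables double as externally
fitted DE tables. The third replicate of each group carries extra noise
(σ = 0.4) so replicate selection has signal. Measured cross-species
correlations sit slightly below ρ (by ~0.03 at these settings) because
counting noise attenuates the latent correlation.

*Annotations.* Random term memberships (sizes Uniform{20..200}) over
5,000 genes plus one planted 100-gene term whose members enter the
200-gene study set with 5× relative weight; factor 1 makes it a null.

What the generators do **not** emulate: assembly artifacts (chimeras,
fragmentation, redundant isoforms), indels and alignment error, GC or
codon-usage heterogeneity along sequences, mappability or length biases in
counts, and correlated terms in annotations. Passing tests therefore
demonstrate correctness of the statistical machinery under the assumed
generative structure, not robustness to upstream artifacts of real data.

## Problem sizes

The tests and the acceptance script use desk-scale batches: 200 pairs of
5,000 codons for method concordance and medians, 50 pairs of 20,000
codons per ω batch for recovery and classifier calibration, 500-pair
catalogs, 2,000-gene count matrices, and 10 seeds / 200 null resamples
for enrichment power and calibration. These sizes keep the full run in a
few minutes while leaving Monte-Carlo error well inside the asserted
margins.
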