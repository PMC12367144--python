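"""Gene-set construction and hypergeometric term enrichment.

Gene sets can be built from similarity-search hits against a keyword-derived
reference (e.g. pigmentation genes gathered by an ontology keyword search)
at an e-value cutoff.  Term enrichment in a study set is tested with the
upper-tail hypergeometric probability, Bonferroni-corrected over the terms
actually tested.
"""

from __future__ import annotations

from dataclasses import dataclass

from scipy import stats

from .io_formats import HitRecord, TermAnnotation

DEFAULT_EVALUE_MAX = 0.001
SIGNIFICANCE_THRESHOLD = 0.05


@dataclass
class GeneSet:
    """A named set of gene ids with free-text provenance."""

    name: str
    members: set[str]
    provenance: str = ""


@dataclass(frozen=True)
class EnrichmentResult:
    """Hypergeometric enrichment of one term in a study set.

    k of n study genes carry the term; K of N population genes do.
    """

    term_id: str
    k: int
    n: int
    K: int
    N: int
    fold_enrichment: float
    p: float
    p_adj: float
    significant: bool


def build_keyword_gene_set(
    name: str,
    hits: list[HitRecord],
    evalue_max: float = DEFAULT_EVALUE_MAX,
) -> GeneSet:
    """Query ids with at least one hit at e-value <= ``evalue_max`` against
    the keyword-derived reference."""
    members = {h.query_id for h in hits if h.e_value <= evalue_max}
    return GeneSet(name, members,
                   provenance=f"similarity hits at e-value <= {evalue_max}")


def hypergeom_enrichment(
    study: set[str],
    population: set[str],
    annotation: TermAnnotation,
) -> list[EnrichmentResult]:
    """Upper-tail hypergeometric enrichment of every annotated term.

    The population is restricted to genes with at least one term and the
    study set to the population; terms with no annotated gene in the
    population are dropped.  p = P(X >= k) for X hypergeometric(N, K, n);
    fold enrichment = (k/n) / (K/N).  Bonferroni correction uses the number
    of terms actually tested.
    """
    if not study <= population:
        raise ValueError("study set must be a subset of the population")
    annotated = annotation.annotated_genes()
    population = population & annotated
    study = study & population
    if not study:
        raise ValueError("study set is empty after restriction to "
                         "annotated genes")
    N, n = len(population), len(study)
    tested = {t: genes & population for t, genes in annotation.terms.items()}
    tested = {t: genes for t, genes in tested.items() if genes}
    m = len(tested)
    results = []
    for term, genes in sorted(tested.items()):
        K = len(genes)
        k = len(genes & study)
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        fold = (k / n) / (K / N)
        p_adj = bonferroni_adjust([p], m)[0]
        results.append(EnrichmentResult(
            term_id=term, k=k, n=n, K=K, N=N, fold_enrichment=fold,
            p=p, p_adj=p_adj,
            significant=p_adj < SIGNIFICANCE_THRESHOLD))
    return results


def bonferroni_adjust(p_values: list[float], m: int | None = None
                      ) -> list[float]:
    """Bonferroni correction: p_adj = min(1, m * p), order preserved."""
    if m is None:
        m = len(p_values)
    out = []
    for p in p_values:
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"p-value {p} outside [0, 1]")
        out.append(min(1.0, m * p))
    return out


def significant_terms(results: list[EnrichmentResult]
                      ) -> list[EnrichmentResult]:
    """Terms with adjusted p < 0.05, sorted ascending by adjusted p."""
    kept = [r for r in results if r.p_adj < SIGNIFICANCE_THRESHOLD]
    return sorted(kept, key=lambda r: (r.p_adj, r.p, r.term_id))
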