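"""Cross-species expression comparison over one-to-one genes.

Pipeline pieces: the expected-count noise filter, trimmed-mean-of-M-values
(TMM) scaling factors, log2 counts-per-million normalization, selection of
the two most consistent replicates per species x tissue group, cross-species
correlation of group means over ortholog pairs, overlap of differential
calls across tissues, and Fisher exact tests of species bias.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import CountMatrix, DifferentialResult
from .orthology import OrthologPair


@dataclass
class NormalizationFactors:
    """Per-sample TMM scaling factors (geometric mean 1) and the effective
    library sizes (library size x factor)."""

    factors: pd.Series
    library_sizes: pd.Series

    @property
    def effective_library_sizes(self) -> pd.Series:
        return self.library_sizes * self.factors


@dataclass(frozen=True)
class ContingencyTable2x2:
    """A labelled 2x2 table of nonnegative integer cells."""

    cells: tuple[tuple[int, int], tuple[int, int]]
    row_labels: tuple[str, str] = ("row1", "row2")
    col_labels: tuple[str, str] = ("col1", "col2")

    def __post_init__(self) -> None:
        for row in self.cells:
            for v in row:
                if v < 0 or int(v) != v:
                    raise ValueError("cells must be nonnegative integers")


def filter_low_expected_counts(matrix: CountMatrix,
                               threshold: float = 2.0) -> CountMatrix:
    """Drop genes whose expected counts summed over samples fall below
    ``threshold``; a gene summing exactly to the threshold is kept."""
    keep = matrix.values.sum(axis=1) >= threshold
    return CountMatrix(matrix.values.loc[keep].copy(),
                       matrix.metadata.copy())


def _tmm_pair_factor(obs: np.ndarray, ref: np.ndarray,
                     lib_obs: float, lib_ref: float,
                     logratio_trim: float = 0.3,
                     sum_trim: float = 0.05) -> float:
    """TMM factor of one sample against the reference (log2 scale -> 2**f).

    Genes with zero in either sample are excluded; M values (log ratios)
    are trimmed by ``logratio_trim`` on each side and A values (average
    abundance) by ``sum_trim``; the trimmed mean is precision-weighted by
    the inverse asymptotic variance of M.
    """
    mask = (obs > 0) & (ref > 0)
    obs, ref = obs[mask], ref[mask]
    if obs.size == 0:
        return 1.0
    p_obs, p_ref = obs / lib_obs, ref / lib_ref
    m = np.log2(p_obs / p_ref)
    a = 0.5 * np.log2(p_obs * p_ref)
    w = (lib_obs - obs) / (lib_obs * obs) + (lib_ref - ref) / (lib_ref * ref)
    finite = np.isfinite(m) & np.isfinite(a)
    m, a, w = m[finite], a[finite], w[finite]
    if m.size == 0 or np.max(np.abs(m)) < 1e-6:
        return 1.0
    n = m.size
    lo_m, hi_m = np.floor(n * logratio_trim) + 1, n + 1 - (np.floor(n * logratio_trim) + 1)
    lo_a, hi_a = np.floor(n * sum_trim) + 1, n + 1 - (np.floor(n * sum_trim) + 1)
    rank_m = stats.rankdata(m, method="average")
    rank_a = stats.rankdata(a, method="average")
    keep = (rank_m >= lo_m) & (rank_m <= hi_m) & \
           (rank_a >= lo_a) & (rank_a <= hi_a)
    if not keep.any():
        return 1.0
    f = np.nansum(m[keep] / w[keep]) / np.nansum(1.0 / w[keep])
    if not np.isfinite(f):
        f = 0.0
    return float(2.0 ** f)


def tmm_factors(matrix: CountMatrix,
                reference_sample: str | None = None) -> NormalizationFactors:
    """Trimmed-mean-of-M-values scaling factors, centred to geometric mean 1.

    The reference sample, unless given, is the one whose 75th-percentile
    count fraction is closest to the samples' mean.
    """
    values = matrix.values
    lib = values.sum(axis=0)
    zero = lib[lib <= 0]
    if len(zero):
        raise ValueError(f"sample(s) with zero total counts: {list(zero.index)}")
    if reference_sample is None:
        q75 = values.apply(lambda col: np.quantile(col[col > 0], 0.75)
                           if (col > 0).any() else 0.0)
        frac = q75 / lib
        reference_sample = (frac - frac.mean()).abs().idxmin()
    ref = values[reference_sample].to_numpy(dtype=float)
    lib_ref = float(lib[reference_sample])
    factors = {}
    for sample in values.columns:
        if sample == reference_sample:
            factors[sample] = 1.0
        else:
            factors[sample] = _tmm_pair_factor(
                values[sample].to_numpy(dtype=float), ref,
                float(lib[sample]), lib_ref)
    f = pd.Series(factors)[values.columns]
    f = f / np.exp(np.mean(np.log(f)))
    return NormalizationFactors(f, lib.astype(float))


def log2_normalize(matrix: CountMatrix, factors: NormalizationFactors,
                   pseudocount: float = 1.0) -> pd.DataFrame:
    """log2(CPM + pseudocount) with TMM effective library sizes.

    Finite at zero counts and monotone in counts within a sample.
    """
    eff = factors.effective_library_sizes[matrix.values.columns]
    cpm = matrix.values / eff * 1e6
    return np.log2(cpm + pseudocount)


def select_consistent_replicates(matrix: CountMatrix,
                                 normalized: pd.DataFrame | None = None
                                 ) -> dict[tuple[str, str], tuple[str, str]]:
    """For each species x tissue group, the two replicates with maximal
    Pearson correlation of log2-normalized expression.

    Ties take the lexicographically smallest sample-id pair; a group with
    exactly two replicates returns both.
    """
    if normalized is None:
        normalized = log2_normalize(matrix, tmm_factors(matrix))
    out: dict[tuple[str, str], tuple[str, str]] = {}
    meta = matrix.metadata
    for (species, tissue), grp in meta.groupby(["species", "tissue"],
                                               sort=True):
        samples = sorted(grp.index)
        if len(samples) < 2:
            raise ValueError(
                f"group ({species}, {tissue}) has fewer than 2 replicates")
        best_pair = None
        best_r = -np.inf
        for s1, s2 in itertools.combinations(samples, 2):
            r = float(np.corrcoef(normalized[s1], normalized[s2])[0, 1])
            if r > best_r + 1e-12:
                best_r, best_pair = r, (s1, s2)
        out[(species, tissue)] = best_pair
    return out


def cross_species_correlation(
    normalized: pd.DataFrame,
    samples_a: list[str],
    samples_b: list[str],
    pairs: list[OrthologPair],
    method: str = "pearson",
) -> float:
    """Correlation of mean expression over ortholog pairs.

    ``samples_a``/``samples_b`` are the (replicate-selected) columns for the
    two species; gene rows are matched through the one-to-one pairs, and
    the per-species means are correlated.
    """
    usable = [(p.id_a, p.id_b) for p in pairs
              if p.id_a in normalized.index and p.id_b in normalized.index]
    if len(usable) < 3:
        raise ValueError("need at least 3 shared ortholog pairs")
    ids_a = [a for a, _ in usable]
    ids_b = [b for _, b in usable]
    x = normalized.loc[ids_a, samples_a].mean(axis=1).to_numpy()
    y = normalized.loc[ids_b, samples_b].mean(axis=1).to_numpy()
    if method == "pearson":
        return float(stats.pearsonr(x, y).statistic)
    if method == "spearman":
        return float(stats.spearmanr(x, y).statistic)
    raise ValueError(f"unknown correlation method {method!r}")


def deg_overlap(deg_head: list[DifferentialResult],
                deg_leg: list[DifferentialResult]) -> dict:
    """Overlap of significant up-calls between two tissues, per direction.

    Positive log2 fold change = higher in species A.  Returns shared /
    tissue-exclusive counts for each direction plus the underlying sets.
    """
    def split(results, label):
        up_a, up_b = set(), set()
        seen: dict[str, float] = {}
        for r in results:
            if r.gene_id in seen and seen[r.gene_id] != r.log2_fold_change:
                raise ValueError(
                    f"conflicting duplicate entries for {r.gene_id} in {label}")
            seen[r.gene_id] = r.log2_fold_change
            if r.significant and r.log2_fold_change > 0:
                up_a.add(r.gene_id)
            elif r.significant and r.log2_fold_change < 0:
                up_b.add(r.gene_id)
        return up_a, up_b

    head_a, head_b = split(deg_head, "head table")
    leg_a, leg_b = split(deg_leg, "leg table")
    return {
        "up_a": {
            "shared": len(head_a & leg_a),
            "head_only": len(head_a - leg_a),
            "leg_only": len(leg_a - head_a),
        },
        "up_b": {
            "shared": len(head_b & leg_b),
            "head_only": len(head_b - leg_b),
            "leg_only": len(leg_b - head_b),
        },
        "sets": {"head_up_a": head_a, "head_up_b": head_b,
                 "leg_up_a": leg_a, "leg_up_b": leg_b},
    }


def species_bias_table(deg: list[DifferentialResult],
                       members: set[str]) -> ContingencyTable2x2:
    """2x2 table of DEG direction (up in A / up in B) against membership in
    a gene set (e.g. pigmentation genes)."""
    in_a = in_b = out_a = out_b = 0
    for r in deg:
        if not r.significant or r.log2_fold_change == 0:
            continue
        up_a = r.log2_fold_change > 0
        member = r.gene_id in members
        if up_a and member:
            in_a += 1
        elif up_a:
            out_a += 1
        elif member:
            in_b += 1
        else:
            out_b += 1
    return ContingencyTable2x2(
        ((in_a, in_b), (out_a, out_b)),
        row_labels=("in_set", "not_in_set"), col_labels=("up_a", "up_b"))


def direction_by_tissue_table(deg_head: list[DifferentialResult],
                              deg_leg: list[DifferentialResult]
                              ) -> ContingencyTable2x2:
    """2x2 table of DEG direction (up in A / up in B) by tissue."""
    def counts(results):
        up_a = sum(1 for r in results
                   if r.significant and r.log2_fold_change > 0)
        up_b = sum(1 for r in results
                   if r.significant and r.log2_fold_change < 0)
        return up_a, up_b

    ha, hb = counts(deg_head)
    la, lb = counts(deg_leg)
    return ContingencyTable2x2(((ha, hb), (la, lb)),
                               row_labels=("head", "leg"),
                               col_labels=("up_a", "up_b"))


def fisher_bias_test(table: ContingencyTable2x2) -> float:
    """Two-sided Fisher exact p for a 2x2 table.

    Sums the probabilities of all margin-fixed tables no more probable
    than the observed one; a zero margin gives p = 1.
    """
    cells = np.asarray(table.cells, dtype=int)
    if cells.sum(axis=0).min() == 0 or cells.sum(axis=1).min() == 0:
        return 1.0
    return float(stats.fisher_exact(cells, alternative="two-sided")[1])
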