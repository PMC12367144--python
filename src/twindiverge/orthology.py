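"""Reciprocal-best-hit orthology between two species.

Two directed hit tables (A queried against B, and B against A) are reduced
to best hits by bit score, and mutual best hits are reported as "one-to-one"
ortholog pairs.  Queries are further partitioned into homology classes:
unique (no hit at all), one_to_one (member of a reciprocal-best pair) and
other_homolog (hits exist but not reciprocal-best).
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

from .io_formats import HitRecord


class HomologyClass(str, Enum):
    unique = "unique"
    one_to_one = "one_to_one"
    other_homolog = "other_homolog"


@dataclass(frozen=True)
class OrthologPair:
    """A reciprocal-best-hit pair with its supporting scores and coverages."""

    id_a: str
    id_b: str
    bit_ab: float
    bit_ba: float
    coverage_a: float | None = None
    coverage_b: float | None = None


def _hit_sort_key(hit: HitRecord):
    # maximal bit score; ties: smaller e-value, longer alignment,
    # lexicographically smaller subject id
    return (-hit.bit_score, hit.e_value, -hit.alignment_length,
            hit.subject_id)


def collapse_hsps(hits: list[HitRecord]) -> dict[tuple[str, str], HitRecord]:
    """Reduce multiple rows (HSPs) per query-subject pair to the row with
    the maximal bit score (ties broken as for best hits)."""
    best: dict[tuple[str, str], HitRecord] = {}
    for hit in hits:
        key = (hit.query_id, hit.subject_id)
        if key not in best or _hit_sort_key(hit) < _hit_sort_key(best[key]):
            best[key] = hit
    return best


def best_hits(hits: list[HitRecord]) -> dict[str, HitRecord]:
    """For each query, the hit with maximal bit score.

    Ties are broken deterministically: smaller e-value, then longer
    alignment, then lexicographically smaller subject id.
    """
    per_pair = collapse_hsps(hits)
    best: dict[str, HitRecord] = {}
    for hit in per_pair.values():
        q = hit.query_id
        if q not in best or _hit_sort_key(hit) < _hit_sort_key(best[q]):
            best[q] = hit
    return best


def alignment_coverage(hit: HitRecord, query_length: int) -> float:
    """Fraction of the query covered by the hit's aligned span."""
    if query_length < hit.query_end:
        raise ValueError(
            f"query_end {hit.query_end} exceeds query length {query_length}")
    return (hit.query_end - hit.query_start + 1) / query_length


def reciprocal_best_hits(
    hits_ab: list[HitRecord],
    hits_ba: list[HitRecord],
    query_lengths_a: dict[str, int] | None = None,
    query_lengths_b: dict[str, int] | None = None,
) -> list[OrthologPair]:
    """One-to-one ortholog pairs: mutual best hits by bit score.

    ``hits_ab`` has species-A queries, ``hits_ba`` species-B queries.  An id
    appearing as a query in both tables indicates colliding namespaces and
    is an error.  Optional query-length maps add alignment coverages.
    """
    queries_a = {h.query_id for h in hits_ab}
    queries_b = {h.query_id for h in hits_ba}
    shared = queries_a & queries_b
    if shared:
        raise ValueError(
            f"ids present in both species' query namespaces: {sorted(shared)[:5]}")
    best_ab = best_hits(hits_ab)
    best_ba = best_hits(hits_ba)
    pairs: list[OrthologPair] = []
    for a, hit_ab in sorted(best_ab.items()):
        b = hit_ab.subject_id
        hit_ba = best_ba.get(b)
        if hit_ba is not None and hit_ba.subject_id == a:
            cov_a = cov_b = None
            if query_lengths_a is not None and a in query_lengths_a:
                cov_a = alignment_coverage(hit_ab, query_lengths_a[a])
            if query_lengths_b is not None and b in query_lengths_b:
                cov_b = alignment_coverage(hit_ba, query_lengths_b[b])
            pairs.append(
                OrthologPair(a, b, hit_ab.bit_score, hit_ba.bit_score,
                             cov_a, cov_b))
    return pairs


def classify_homology(
    query_ids: list[str],
    hits: list[HitRecord],
    rbh_pairs: list[OrthologPair],
    species: str = "a",
) -> dict[str, HomologyClass]:
    """Partition queries into unique / one_to_one / other_homolog.

    ``species`` selects which side of the OrthologPair the queries live on.
    """
    with_hits = {h.query_id for h in hits}
    in_rbh = {p.id_a if species == "a" else p.id_b for p in rbh_pairs}
    out: dict[str, HomologyClass] = {}
    for q in query_ids:
        if q in in_rbh:
            out[q] = HomologyClass.one_to_one
        elif q in with_hits:
            out[q] = HomologyClass.other_homolog
        else:
            out[q] = HomologyClass.unique
    return out
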