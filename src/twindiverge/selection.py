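"""Pairwise synonymous/nonsynonymous divergence and selection classification.

Two estimators are provided for a pair of aligned, gapless coding
sequences:

* NG86 — unweighted site and pathway counting (Nei-Gojobori style): each
  codon contributes 3 sites split by the fraction of its single-nucleotide
  changes that are synonymous; differences between codons are averaged over
  all minimal mutational pathways; proportions are corrected with the
  Jukes-Cantor formula d = -(3/4) ln(1 - 4p/3).

* YN00 — counting weighted by the transition/transversion ratio kappa and
  F3x4 codon frequencies (Yang-Nielsen style): kappa is first estimated
  from four-fold and zero-fold degenerate sites with a two-parameter (K80)
  correction; sites and pathway weights then use mutation rates
  proportional to pi_target * kappa^[transition]; dS and dN are corrected
  with the K80 formula on transition/transversion proportions, iterating
  the pathway weighting's omega until dS and dN stabilise.

Selection classes use the error-interval rule: positive when
dN - dN_err > dS + dS_err, purifying when dS - dS_err > dN + dN_err,
otherwise neutral.  Records whose distances fall outside the correction
domain are flagged and excluded from classification.

Changes to and from stop codons are excluded throughout; site fractions are
renormalised over the admissible changes and pathways running through a
stop codon are discarded (if every pathway is blocked, the stop constraint
is relaxed for that codon pair).
"""

from __future__ import annotations

import itertools
import math
from collections import Counter
from dataclasses import dataclass, field
from enum import Enum

import numpy as np

from ._genetic_code import (
    CODON_TO_AA,
    DEGENERACY,
    SENSE_CODONS,
    STOP_CODONS,
    codon_neighbors,
    is_synonymous,
    is_transition,
)

MIN_GAPLESS_CODONS = 50  # transcript-level gate for divergence analyses


class SelectionClass(str, Enum):
    positive = "positive"
    purifying = "purifying"
    neutral = "neutral"


@dataclass
class PairwiseDivergence:
    """Synonymous/nonsynonymous divergence between one pair of sequences."""

    pair_id: str
    method: str  # "NG86" | "YN00"
    L_codons: int
    S: float
    N: float
    Sd: float
    Nd: float
    pS: float | None
    pN: float | None
    dS: float | None
    dS_err: float | None
    dN: float | None
    dN_err: float | None
    omega: float | None
    kappa: float | None = None
    t: float | None = None
    converged: bool = True
    flags: list[str] = field(default_factory=list)

    @property
    def defined(self) -> bool:
        return self.dS is not None and self.dN is not None


# ---------------------------------------------------------------------------
# shared codon machinery

#: per sense codon: list of (neighbor_codon, position, transition?, synonymous?)
#: restricted to sense (non-stop) neighbors
_SENSE_NEIGHBORS: dict[str, list[tuple[str, int, bool, bool]]] = {}
for _c in SENSE_CODONS:
    _SENSE_NEIGHBORS[_c] = [
        (nb, pos, is_transition(_c[pos], nb[pos]), is_synonymous(_c, nb))
        for pos, nb in codon_neighbors(_c)
        if nb not in STOP_CODONS
    ]


def ng86_codon_sites(codon: str) -> tuple[float, float]:
    """Synonymous and nonsynonymous site counts of one sense codon.

    Per position, the fraction of admissible (non-stop) single-nucleotide
    changes that are synonymous; summed over the three positions.  Always
    returns s + n = 3.
    """
    codon = codon.upper()
    if codon in STOP_CODONS:
        raise ValueError(f"stop codon {codon}")
    if codon not in CODON_TO_AA:
        raise ValueError(f"not an unambiguous sense codon: {codon!r}")
    s = 0.0
    for pos in range(3):
        changes = [nb for p, nb in codon_neighbors(codon) if p == pos]
        admissible = [nb for nb in changes if nb not in STOP_CODONS]
        if not admissible:
            continue
        syn = sum(1 for nb in admissible if is_synonymous(codon, nb))
        s += syn / len(admissible)
    return s, 3.0 - s


_NG86_SITES: dict[str, tuple[float, float]] = {
    c: ng86_codon_sites(c) for c in SENSE_CODONS
}


def _pathways(codon_i: str, codon_j: str):
    """Minimal mutational pathways codon_i -> codon_j as step lists.

    Each step is (from_codon, to_codon).  Pathways crossing a stop codon
    are omitted; if all are blocked the constraint is relaxed.
    """
    diff = [p for p in range(3) if codon_i[p] != codon_j[p]]
    paths = []
    blocked = []
    for order in itertools.permutations(diff):
        cur = codon_i
        steps = []
        ok = True
        for pos in order:
            nxt = cur[:pos] + codon_j[pos] + cur[pos + 1 :]
            steps.append((cur, nxt))
            if nxt in STOP_CODONS and nxt != codon_j:
                ok = False
            cur = nxt
        (paths if ok else blocked).append(steps)
    return paths if paths else blocked


def ng86_codon_differences(codon_i: str, codon_j: str
                           ) -> tuple[float, float]:
    """Pathway-averaged synonymous/nonsynonymous differences between two
    sense codons.  sd + nd equals the number of differing positions."""
    codon_i, codon_j = codon_i.upper(), codon_j.upper()
    for c in (codon_i, codon_j):
        if c in STOP_CODONS:
            raise ValueError(f"stop codon {c}")
        if c not in CODON_TO_AA:
            raise ValueError(f"not an unambiguous sense codon: {c!r}")
    if codon_i == codon_j:
        return 0.0, 0.0
    paths = _pathways(codon_i, codon_j)
    sd = nd = 0.0
    for steps in paths:
        for a, b in steps:
            if b not in STOP_CODONS and a not in STOP_CODONS \
                    and is_synonymous(a, b):
                sd += 1.0
            else:
                nd += 1.0
    return sd / len(paths), nd / len(paths)


_NG86_DIFFS: dict[tuple[str, str], tuple[float, float]] = {}


def _ng86_diffs_cached(ci: str, cj: str) -> tuple[float, float]:
    key = (ci, cj)
    if key not in _NG86_DIFFS:
        _NG86_DIFFS[key] = ng86_codon_differences(ci, cj)
    return _NG86_DIFFS[key]


def codon_pair_counts(cds_a: str, cds_b: str
                      ) -> tuple[Counter, int, list[str]]:
    """Compress two aligned gapless CDS into sense codon-pair counts.

    Returns (counter over (codon_a, codon_b), usable codon columns, flags).
    Columns containing a stop or ambiguous codon are skipped with a flag.
    """
    if len(cds_a) != len(cds_b):
        raise ValueError("aligned sequences differ in length")
    if len(cds_a) % 3 != 0:
        raise ValueError("aligned length not divisible by 3")
    counts: Counter = Counter()
    skipped = 0
    for k in range(0, len(cds_a), 3):
        ca, cb = cds_a[k : k + 3].upper(), cds_b[k : k + 3].upper()
        if ca not in CODON_TO_AA or cb not in CODON_TO_AA:
            skipped += 1
            continue
        counts[(ca, cb)] += 1
    flags = [f"skipped_{skipped}_non_sense_codons"] if skipped else []
    return counts, sum(counts.values()), flags


# ---------------------------------------------------------------------------
# distance corrections

def _jukes_cantor(p: float) -> float | None:
    if p >= 0.75:
        return None
    return -0.75 * math.log1p(-4.0 * p / 3.0)


def _jc_error(p: float, sites: float) -> float | None:
    if sites <= 0 or p >= 0.75:
        return None
    return math.sqrt(p * (1.0 - p) / sites) / (1.0 - 4.0 * p / 3.0)


def _k80(P: float, Q: float) -> float | None:
    a = 1.0 - 2.0 * P - Q
    b = 1.0 - 2.0 * Q
    if a <= 0 or b <= 0:
        return None
    return -0.5 * math.log(a) - 0.25 * math.log(b)


# ---------------------------------------------------------------------------
# NG86

def ng86_estimate(cds_a: str, cds_b: str, pair_id: str = "pair"
                  ) -> PairwiseDivergence:
    """NG86 divergence for a pair of aligned, gapless coding sequences."""
    counts, L, flags = codon_pair_counts(cds_a, cds_b)
    if L < 1:
        raise ValueError("no usable codon columns")
    S = N = 0.0
    Sd = Nd = 0.0
    for (ca, cb), k in counts.items():
        sa, _ = _NG86_SITES[ca]
        sb, _ = _NG86_SITES[cb]
        S += k * (sa + sb) / 2.0
        if ca != cb:
            sd, nd = _ng86_diffs_cached(ca, cb)
            Sd += k * sd
            Nd += k * nd
    N = 3.0 * L - S
    return _finalize_proportional(pair_id, "NG86", L, S, N, Sd, Nd, flags)


def _finalize_proportional(pair_id, method, L, S, N, Sd, Nd, flags,
                           kappa=None, t=None, converged=True,
                           dS=None, dN=None):
    """Fill a PairwiseDivergence from counts; JC-based errors on (pS, pN).

    When dS/dN are not supplied (NG86), they are computed by the
    Jukes-Cantor correction of pS/pN.
    """
    flags = list(flags)
    pS = Sd / S if S > 0 else None
    pN = Nd / N if N > 0 else None
    if dS is None:
        dS = _jukes_cantor(pS) if pS is not None else None
    if dN is None:
        dN = _jukes_cantor(pN) if pN is not None else None
    dS_err = _jc_error(pS, S) if (pS is not None and dS is not None) else None
    dN_err = _jc_error(pN, N) if (pN is not None and dN is not None) else None
    if pS is None or dS is None:
        flags.append("ds_undefined")
        dS = dS_err = None
    if pN is None or dN is None:
        flags.append("dn_undefined")
        dN = dN_err = None
    omega = None
    if dS is not None and dN is not None and dS > 0:
        omega = dN / dS
    return PairwiseDivergence(
        pair_id=pair_id, method=method, L_codons=L, S=S, N=N, Sd=Sd, Nd=Nd,
        pS=pS, pN=pN, dS=dS, dS_err=dS_err, dN=dN, dN_err=dN_err,
        omega=omega, kappa=kappa, t=t, converged=converged, flags=flags)


# ---------------------------------------------------------------------------
# YN00

def f3x4_frequencies(counts: Counter) -> dict[str, float]:
    """F3x4 codon frequencies from the nucleotide composition at each codon
    position, pooled over both sequences, renormalised over sense codons."""
    pos_freq = [Counter() for _ in range(3)]
    for (ca, cb), k in counts.items():
        for codon in (ca, cb):
            for p in range(3):
                pos_freq[p][codon[p]] += k
    for p in range(3):
        tot = sum(pos_freq[p].values())
        for b in "ACGT":
            pos_freq[p][b] = (pos_freq[p][b]) / tot if tot else 0.25
    pi = {}
    for codon in SENSE_CODONS:
        pi[codon] = (pos_freq[0][codon[0]] * pos_freq[1][codon[1]]
                     * pos_freq[2][codon[2]])
    total = sum(pi.values())
    if total <= 0:
        raise ValueError("degenerate codon frequencies")
    return {c: v / total for c, v in pi.items()}


def kappa_from_degenerate_sites(counts: Counter,
                                fallback: float = 2.0) -> float:
    """Transition/transversion rate ratio from four-fold and zero-fold
    degenerate sites via the two-parameter (K80) correction.

    A position is used only when its degeneracy class agrees between the
    two codons.  The two classes' corrected transition/transversion
    distances are combined weighted by site counts; the ratio of rates is
    kappa = 2 * d_ts / d_tv.  Degenerate cases fall back to ``fallback``.
    """
    L = {4: 0.0, 1: 0.0}
    ts = {4: 0.0, 1: 0.0}
    tv = {4: 0.0, 1: 0.0}
    for (ca, cb), k in counts.items():
        dega, degb = DEGENERACY[ca], DEGENERACY[cb]
        for p in range(3):
            if dega[p] == degb[p] and dega[p] in L:
                cls = dega[p]
                L[cls] += k
                if ca[p] != cb[p]:
                    if is_transition(ca[p], cb[p]):
                        ts[cls] += k
                    else:
                        tv[cls] += k
    d_ts = d_tv = 0.0
    weight = 0.0
    for cls in (4, 1):
        if L[cls] <= 0:
            continue
        P, Q = ts[cls] / L[cls], tv[cls] / L[cls]
        a, b = 1.0 - 2.0 * P - Q, 1.0 - 2.0 * Q
        if a <= 0 or b <= 0:
            continue
        dts_cls = -0.5 * math.log(a) + 0.25 * math.log(b)
        dtv_cls = -0.5 * math.log(b)
        d_ts += L[cls] * dts_cls
        d_tv += L[cls] * dtv_cls
        weight += L[cls]
    if weight <= 0 or d_tv <= 0 or d_ts <= 0:
        return fallback
    return 2.0 * d_ts / d_tv


def _yn00_sites(counts: Counter, pi: dict[str, float], kappa: float
                ) -> tuple[float, float]:
    """Mutation-rate-weighted synonymous/nonsynonymous site totals,
    averaged over the two sequences."""
    per_codon: dict[str, float] = {}
    for codon in SENSE_CODONS:
        u_syn = u_tot = 0.0
        for nb, _pos, ts, syn in _SENSE_NEIGHBORS[codon]:
            u = pi[nb] * (kappa if ts else 1.0)
            u_tot += u
            if syn:
                u_syn += u
        per_codon[codon] = 3.0 * u_syn / u_tot if u_tot > 0 else 0.0
    S = 0.0
    L = 0
    for (ca, cb), k in counts.items():
        S += k * (per_codon[ca] + per_codon[cb]) / 2.0
        L += k
    return S, 3.0 * L - S


def _step_category(a: str, b: str) -> tuple[bool, bool]:
    """(synonymous?, transition?) of a single-nucleotide codon change."""
    pos = next(p for p in range(3) if a[p] != b[p])
    syn = (a not in STOP_CODONS and b not in STOP_CODONS
           and is_synonymous(a, b))
    return syn, is_transition(a[pos], b[pos])


def _yn00_differences(counts: Counter, pi: dict[str, float], kappa: float,
                      omega: float) -> tuple[float, float, float, float]:
    """Expected (syn_ts, syn_tv, nonsyn_ts, nonsyn_tv) difference counts,
    weighting each minimal pathway by its rate product under the current
    (kappa, omega)."""
    sd_ts = sd_tv = nd_ts = nd_tv = 0.0
    cache: dict[tuple[str, str], tuple[float, float, float, float]] = {}
    for (ca, cb), k in counts.items():
        if ca == cb:
            continue
        key = (ca, cb)
        if key not in cache:
            paths = _pathways(ca, cb)
            weights = []
            contribs = []
            for steps in paths:
                w = 1.0
                c = [0.0, 0.0, 0.0, 0.0]
                for a, b in steps:
                    syn, ts = _step_category(a, b)
                    rate = (pi.get(b, min(pi.values())) *
                            (kappa if ts else 1.0) *
                            (1.0 if syn else omega))
                    w *= max(rate, 1e-100)
                    idx = (0 if syn else 2) + (0 if ts else 1)
                    c[idx] += 1.0
                weights.append(w)
                contribs.append(c)
            tot = sum(weights)
            if tot <= 0:
                weights = [1.0] * len(paths)
                tot = float(len(paths))
            vals = [0.0, 0.0, 0.0, 0.0]
            for w, c in zip(weights, contribs):
                for i in range(4):
                    vals[i] += (w / tot) * c[i]
            cache[key] = tuple(vals)
        v = cache[key]
        sd_ts += k * v[0]
        sd_tv += k * v[1]
        nd_ts += k * v[2]
        nd_tv += k * v[3]
    return sd_ts, sd_tv, nd_ts, nd_tv


def yn00_estimate(cds_a: str, cds_b: str, pair_id: str = "pair",
                  tol: float = 1e-8, max_iter: int = 100
                  ) -> PairwiseDivergence:
    """YN00 divergence for a pair of aligned, gapless coding sequences.

    kappa comes from the degenerate-site estimate and is held fixed; omega
    (used to weight mutational pathways) and the divergence t are iterated
    until successive dS and dN change by less than ``tol``.
    """
    counts, L, flags = codon_pair_counts(cds_a, cds_b)
    if L < 1:
        raise ValueError("no usable codon columns")
    pi = f3x4_frequencies(counts)
    kappa = kappa_from_degenerate_sites(counts)
    S, N = _yn00_sites(counts, pi, kappa)
    omega = 1.0
    prev: tuple[float, float] | None = None
    dS = dN = None
    Sd = Nd = 0.0
    t = None
    converged = False
    for _ in range(max_iter):
        sd_ts, sd_tv, nd_ts, nd_tv = _yn00_differences(counts, pi, kappa,
                                                       omega)
        Sd, Nd = sd_ts + sd_tv, nd_ts + nd_tv
        dS = _k80(sd_ts / S, sd_tv / S) if S > 0 else None
        dN = _k80(nd_ts / N, nd_tv / N) if N > 0 else None
        if dS is None or dN is None:
            break
        t = 3.0 * (S * dS + N * dN) / (S + N)
        cur = (dS, dN)
        if prev is not None and abs(cur[0] - prev[0]) < tol \
                and abs(cur[1] - prev[1]) < tol:
            converged = True
            break
        prev = cur
        if dS > 0:
            omega = min(dN / dS, 99.0)
        elif dN > 0:
            omega = 99.0
        else:
            converged = True
            break
    else:
        flags.append("not_converged")
    if dS is None or dN is None:
        converged = True  # domain failure, not an iteration failure
    return _finalize_proportional(
        pair_id, "YN00", L, S, N, Sd, Nd, flags,
        kappa=kappa, t=t, converged=converged, dS=dS, dN=dN)


# ---------------------------------------------------------------------------
# classification & summaries

def classify_selection(dN: float, dN_err: float, dS: float, dS_err: float
                       ) -> SelectionClass:
    """Error-interval selection rule on (dN +/- dN_err, dS +/- dS_err)."""
    for v in (dN, dN_err, dS, dS_err):
        if v is None or v < 0:
            raise ValueError("classification needs defined, nonnegative "
                             "dN, dN_err, dS, dS_err")
    if dN - dN_err > dS + dS_err:
        return SelectionClass.positive
    if dS - dS_err > dN + dN_err:
        return SelectionClass.purifying
    return SelectionClass.neutral


def classify_record(record: PairwiseDivergence) -> SelectionClass | None:
    """Classify one divergence record; None when dS or dN is undefined."""
    if not record.defined:
        return None
    return classify_selection(record.dN, record.dN_err,
                              record.dS, record.dS_err)


def divergence_summary(records: list[PairwiseDivergence]) -> dict:
    """Medians, between-method correlations and selection-class tallies.

    Records may mix methods; medians are per method, and when both methods
    cover shared pair ids the Pearson correlation of their dS (and dN)
    vectors is reported.
    """
    defined = [r for r in records if r.defined]
    if not defined:
        raise ValueError("no defined divergence records")
    out: dict = {"methods": {}}
    by_method: dict[str, list[PairwiseDivergence]] = {}
    for r in defined:
        by_method.setdefault(r.method, []).append(r)
    for method, recs in by_method.items():
        classes = Counter(classify_record(r).value for r in recs)
        n = len(recs)
        out["methods"][method] = {
            "n": n,
            "median_dS": float(np.median([r.dS for r in recs])),
            "median_dN": float(np.median([r.dN for r in recs])),
            "class_counts": dict(classes),
            "class_fractions": {k: v / n for k, v in classes.items()},
        }
    methods = sorted(by_method)
    if len(methods) == 2:
        a = {r.pair_id: r for r in by_method[methods[0]]}
        b = {r.pair_id: r for r in by_method[methods[1]]}
        shared = sorted(set(a) & set(b))
        if len(shared) >= 3:
            ds_a = np.array([a[p].dS for p in shared])
            ds_b = np.array([b[p].dS for p in shared])
            dn_a = np.array([a[p].dN for p in shared])
            dn_b = np.array([b[p].dN for p in shared])
            out["method_correlation"] = {
                "n": len(shared),
                "dS_pearson_r": float(np.corrcoef(ds_a, ds_b)[0, 1]),
                "dN_pearson_r": float(np.corrcoef(dn_a, dn_b)[0, 1]),
            }
    return out
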