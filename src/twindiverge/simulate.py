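"""Synthetic data generators mirroring the statistical structure of a
two-species comparative transcriptome study.

Four generators provide ground truth for every analysis stage:

* codon pairs evolved under a codon substitution process with
  transition/transversion ratio kappa and selection intensity omega
  (single-nucleotide changes only, stop codons unreachable), at the low
  divergence regime of recently diverged species (dS around 0.02-0.03);
* ortholog catalogs of coding sequences with planted duplications and
  losses that break one-to-one correspondence;
* negative-binomial count matrices for a 2 species x 2 tissues x 3
  replicates design with a controllable fraction of differentially
  expressed genes and a controllable direction bias;
* gene -> term annotations with one planted enriched term.

All generators are deterministic given their seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._genetic_code import (
    SENSE_CODONS,
    codon_neighbors,
    is_synonymous,
    is_transition,
)
from .io_formats import (
    CountMatrix,
    DifferentialResult,
    HitRecord,
    SequenceRecord,
    TermAnnotation,
)

_N_SENSE = len(SENSE_CODONS)


def uniform_codon_frequencies() -> np.ndarray:
    return np.full(_N_SENSE, 1.0 / _N_SENSE)


@dataclass
class SimulationParams:
    """Parameters of the codon substitution process.

    ``t`` is the total expected number of substitutions per codon between
    the two sequences (each lineage evolves for t/2).  Use
    :meth:`with_target_ds` to pick t so the expected synonymous divergence
    matches a target dS.
    """

    length: int = 5000
    t: float = 0.1
    kappa: float = 2.0
    omega: float = 0.25
    codon_frequencies: np.ndarray = field(
        default_factory=uniform_codon_frequencies)
    seed: int = 0

    def __post_init__(self) -> None:
        self.codon_frequencies = np.asarray(self.codon_frequencies,
                                            dtype=float)
        if self.length < 1:
            raise ValueError("length must be >= 1")
        if self.t < 0 or self.kappa <= 0 or self.omega < 0:
            raise ValueError("t >= 0, kappa > 0, omega >= 0 required")
        if self.codon_frequencies.shape != (_N_SENSE,):
            raise ValueError(
                f"codon_frequencies must have {_N_SENSE} entries "
                "(sense codons only; stop codons carry no mass)")
        if (self.codon_frequencies < 0).any() or not math.isclose(
                float(self.codon_frequencies.sum()), 1.0, abs_tol=1e-9):
            raise ValueError("codon_frequencies must be a simplex vector")

    @classmethod
    def with_target_ds(cls, target_ds: float, **kwargs) -> "SimulationParams":
        params = cls(t=0.0, **kwargs)
        proc = CodonProcess(params.kappa, params.omega,
                            params.codon_frequencies)
        params.t = target_ds / proc.ds_rate
        return params


class CodonProcess:
    """A continuous-time codon substitution process.

    Rates: q_ij proportional to pi_j * kappa^[transition] *
    omega^[nonsynonymous] for single-nucleotide changes between sense
    codons, zero otherwise; normalised so the stationary expected number of
    substitutions per codon per unit t is 1.  The process is reversible
    with stationary distribution pi.
    """

    def __init__(self, kappa: float, omega: float,
                 pi: np.ndarray) -> None:
        self.pi = np.asarray(pi, dtype=float)
        q = np.zeros((_N_SENSE, _N_SENSE))
        syn = np.zeros((_N_SENSE, _N_SENSE), dtype=bool)
        index = {c: i for i, c in enumerate(SENSE_CODONS)}
        for i, ci in enumerate(SENSE_CODONS):
            for pos, nb in codon_neighbors(ci):
                j = index.get(nb)
                if j is None:  # stop codon: unreachable
                    continue
                s = is_synonymous(ci, nb)
                rate = self.pi[j] * (kappa if is_transition(ci[pos], nb[pos])
                                     else 1.0)
                if not s:
                    rate *= omega
                q[i, j] = rate
                syn[i, j] = s
        exit_rates = q.sum(axis=1)
        scale = float(self.pi @ exit_rates)
        if scale <= 0:
            raise ValueError("degenerate rate matrix")
        q /= scale
        self.q = q
        self.syn = syn
        self.exit = q.sum(axis=1)
        # jump chain: cumulative transition probabilities per state
        with np.errstate(invalid="ignore", divide="ignore"):
            probs = np.where(self.exit[:, None] > 0,
                             q / self.exit[:, None], 0.0)
        self._cum = np.cumsum(probs, axis=1)
        # mutation-rate-weighted synonymous sites per codon (omega-free)
        mut = np.zeros_like(q)
        for i, ci in enumerate(SENSE_CODONS):
            for pos, nb in codon_neighbors(ci):
                j = index.get(nb)
                if j is None:
                    continue
                mut[i, j] = self.pi[j] * (
                    kappa if is_transition(ci[pos], nb[pos]) else 1.0)
        tot = mut.sum(axis=1)
        syn_rate = (mut * syn).sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            sites = np.where(tot > 0, 3.0 * syn_rate / tot, 0.0)
        self.mean_syn_sites = float(self.pi @ sites)
        self.syn_sub_rate = float(self.pi @ (q * syn).sum(axis=1))

    @property
    def ds_rate(self) -> float:
        """Expected dS per unit t at stationarity (syn substitutions per
        codon divided by syn sites per codon)."""
        return self.syn_sub_rate / self.mean_syn_sites

    def sample_ancestor(self, length: int, rng: np.random.Generator
                        ) -> np.ndarray:
        return rng.choice(_N_SENSE, size=length, p=self.pi)

    def evolve(self, states: np.ndarray, tau: float,
               rng: np.random.Generator) -> tuple[np.ndarray, int, int]:
        """Evolve codon states for time tau; returns (new states,
        synonymous events, nonsynonymous events)."""
        states = states.copy()
        n_syn = n_non = 0
        if tau <= 0:
            return states, 0, 0
        with np.errstate(divide="ignore"):
            first = rng.exponential(size=states.size) / self.exit[states]
        for i in np.nonzero(first < tau)[0]:
            t_now = first[i]
            s = states[i]
            while t_now < tau:
                u = rng.random()
                s_new = int(np.searchsorted(self._cum[s], u))
                if self.syn[s, s_new]:
                    n_syn += 1
                else:
                    n_non += 1
                s = s_new
                t_now += rng.exponential() / self.exit[s]
            states[i] = s
        return states, n_syn, n_non


def simulate_codon_pair(params: SimulationParams,
                        rng: np.random.Generator | None = None
                        ) -> tuple[str, str, dict]:
    """Evolve two coding sequences from a common ancestor.

    Returns (cds_a, cds_b, truth) where truth records the realised
    synonymous/nonsynonymous event counts and the generating parameters.
    """
    if rng is None:
        rng = np.random.default_rng(params.seed)
    proc = CodonProcess(params.kappa, params.omega, params.codon_frequencies)
    ancestor = proc.sample_ancestor(params.length, rng)
    half = params.t / 2.0
    states_a, syn_a, non_a = proc.evolve(ancestor, half, rng)
    states_b, syn_b, non_b = proc.evolve(ancestor, half, rng)
    cds_a = "".join(SENSE_CODONS[s] for s in states_a)
    cds_b = "".join(SENSE_CODONS[s] for s in states_b)
    truth = {
        "t": params.t, "kappa": params.kappa, "omega": params.omega,
        "length": params.length,
        "syn_events": syn_a + syn_b, "nonsyn_events": non_a + non_b,
        "expected_ds": params.t * proc.ds_rate,
    }
    return cds_a, cds_b, truth


# ---------------------------------------------------------------------------
# ortholog catalogs

def _random_cds(length: int, pi: np.ndarray,
                rng: np.random.Generator) -> str:
    states = rng.choice(_N_SENSE, size=length, p=pi)
    return "".join(SENSE_CODONS[s] for s in states)


def _identity(a: str, b: str) -> float:
    n = min(len(a), len(b))
    if n == 0:
        return 0.0
    same = sum(1 for x, y in zip(a[:n], b[:n]) if x == y)
    return 100.0 * same / n


def _hit(query: str, subject: str, seq_q: str, seq_s: str,
         bit: float) -> HitRecord:
    n = min(len(seq_q), len(seq_s))
    ident = _identity(seq_q, seq_s)
    mismatches = round(n * (1.0 - ident / 100.0))
    return HitRecord(query, subject, round(ident, 2), n, mismatches, 0,
                     1, n, 1, n, 1e-50, bit)


def simulate_ortholog_catalog(
    n_pairs: int,
    duplication_fraction: float = 0.0,
    loss_fraction: float = 0.0,
    divergence: SimulationParams | None = None,
    codon_length: int = 200,
    seed: int = 0,
) -> dict:
    """Two species' coding-sequence catalogs plus directed hit tables.

    ``n_pairs`` true ortholog pairs are evolved at the configured
    divergence.  A ``duplication_fraction`` of them receive an extra
    species-A paralog whose bit scores break reciprocity (the paralog's
    best hit points to the wrong partner, while the partner's best hit
    points to the paralog), so those pairs are not recoverable as
    one-to-one.  ``loss_fraction`` adds species-unique genes with no hits.

    Returns a dict with keys ``fasta_a``, ``fasta_b`` (SequenceRecord
    lists), ``hits_ab``, ``hits_ba`` (HitRecord lists) and ``truth``
    (DataFrame: gene_id, species, true_class, partner).
    """
    if n_pairs < 1:
        raise ValueError("n_pairs must be >= 1")
    if not (0 <= duplication_fraction <= 1 and 0 <= loss_fraction <= 1):
        raise ValueError("fractions must be in [0, 1]")
    rng = np.random.default_rng(seed)
    if divergence is None:
        divergence = SimulationParams.with_target_ds(
            0.025, length=codon_length, kappa=2.0, omega=0.25)
    proc_params = SimulationParams(
        length=codon_length, t=divergence.t, kappa=divergence.kappa,
        omega=divergence.omega,
        codon_frequencies=divergence.codon_frequencies)

    n_dup = round(duplication_fraction * n_pairs)
    dup_idx = set(rng.choice(n_pairs, size=n_dup, replace=False).tolist()) \
        if n_dup else set()

    fasta_a: list[SequenceRecord] = []
    fasta_b: list[SequenceRecord] = []
    hits_ab: list[HitRecord] = []
    hits_ba: list[HitRecord] = []
    truth_rows = []
    seqs: dict[str, str] = {}

    base_bits = 500.0 + rng.permutation(n_pairs) * 10.0
    paralog_proc = CodonProcess(proc_params.kappa, proc_params.omega,
                                proc_params.codon_frequencies)

    for i in range(n_pairs):
        a_id, b_id = f"A{i:05d}", f"B{i:05d}"
        cds_a, cds_b, _ = simulate_codon_pair(proc_params, rng)
        seqs[a_id], seqs[b_id] = cds_a, cds_b
        fasta_a.append(SequenceRecord(a_id, cds_a))
        fasta_b.append(SequenceRecord(b_id, cds_b))
        bit = float(base_bits[i])
        hits_ab.append(_hit(a_id, b_id, cds_a, cds_b, bit))
        hits_ba.append(_hit(b_id, a_id, cds_b, cds_a, bit))
        cls = "many_to_one" if i in dup_idx else "one_to_one"
        truth_rows.append((a_id, "A", cls, b_id))
        truth_rows.append((b_id, "B", cls, a_id))

    for i in sorted(dup_idx):
        a_id, b_id = f"A{i:05d}", f"B{i:05d}"
        dup_id = f"A{i:05d}d"
        states = np.array([SENSE_CODONS.index(seqs[a_id][k : k + 3])
                           for k in range(0, len(seqs[a_id]), 3)])
        states, _, _ = paralog_proc.evolve(states, proc_params.t / 4.0, rng)
        cds_dup = "".join(SENSE_CODONS[s] for s in states)
        seqs[dup_id] = cds_dup
        fasta_a.append(SequenceRecord(dup_id, cds_dup))
        bit = float(base_bits[i])
        # wrong partner for the paralog's own best hit
        j = int(rng.integers(n_pairs - 1))
        if j >= i:
            j += 1
        wrong_b = f"B{j:05d}"
        hits_ab.append(_hit(dup_id, b_id, cds_dup, seqs[b_id], bit - 2.0))
        hits_ab.append(_hit(dup_id, wrong_b, cds_dup, seqs[wrong_b],
                            bit - 1.0))
        # the partner's best hit becomes the paralog -> reciprocity broken
        hits_ba.append(_hit(b_id, dup_id, seqs[b_id], cds_dup, bit + 2.0))
        hits_ba.append(_hit(wrong_b, dup_id, seqs[wrong_b], cds_dup,
                            float(base_bits[j]) - 5.0))
        truth_rows.append((dup_id, "A", "many_to_one", b_id))

    pi = proc_params.codon_frequencies
    n_loss_a = int(rng.binomial(n_pairs, loss_fraction))
    n_loss_b = int(rng.binomial(n_pairs, loss_fraction))
    for sp, count, records in (("A", n_loss_a, fasta_a),
                               ("B", n_loss_b, fasta_b)):
        for k in range(count):
            uid = f"{sp}u{k:05d}"
            cds = _random_cds(codon_length, pi, rng)
            records.append(SequenceRecord(uid, cds))
            truth_rows.append((uid, sp, "unique", ""))

    truth = pd.DataFrame(truth_rows,
                         columns=["gene_id", "species", "true_class",
                                  "partner"])
    return {"fasta_a": fasta_a, "fasta_b": fasta_b,
            "hits_ab": hits_ab, "hits_ba": hits_ba, "truth": truth}


# ---------------------------------------------------------------------------
# count matrices

@dataclass
class CountSimParams:
    """Parameters of the 2 species x 2 tissues x 3 replicates count
    generator.

    Baseline log2 means are Normal(baseline_log2_mean, baseline_log2_sd);
    counts are negative binomial with variance m + dispersion * m^2.
    ``de_fraction``/``up_in_a_bias`` are per-tissue: the fraction of genes
    with a planted species effect in that tissue's contrast and the
    probability the effect is up in species A.  ``species_correlation``
    sets the cross-species correlation of latent log2 expression.
    ``noisy_replicate_sd`` adds extra log-normal noise to the third
    replicate of every group so replicate selection has signal.
    """

    n_genes: int = 2000
    baseline_log2_mean: float = 6.0
    baseline_log2_sd: float = 2.0
    tissue_effect_sd: float = 1.0
    species_correlation: float = 0.95
    dispersion: float = 0.05
    de_fraction: dict[str, float] = field(
        default_factory=lambda: {"head": 0.05, "leg": 0.05})
    up_in_a_bias: dict[str, float] = field(
        default_factory=lambda: {"head": 0.5, "leg": 0.75})
    effect_log2_low: float = 1.0
    effect_log2_high: float = 3.0
    n_replicates: int = 3
    noisy_replicate_sd: float = 0.4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.dispersion <= 0:
            raise ValueError("dispersion must be > 0")
        for tissue, f in self.de_fraction.items():
            if not 0 <= f <= 1:
                raise ValueError(f"de_fraction[{tissue}] outside [0, 1]")
        if not -1 <= self.species_correlation <= 1:
            raise ValueError("species_correlation outside [-1, 1]")


def simulate_counts(params: CountSimParams
                    ) -> tuple[CountMatrix, dict[str, list[DifferentialResult]]]:
    """Negative-binomial count matrix plus per-tissue truth DE tables.

    Gene-wise baselines are shared across species; the species-B latent
    log2 expression is correlated with species A at
    ``params.species_correlation``; planted log2 effects (positive = up in
    species A) are added per tissue for the configured fraction and
    direction bias.  The truth tables are DifferentialResult lists usable
    directly as externally fitted DE tables.
    """
    rng = np.random.default_rng(params.seed)
    G = params.n_genes
    tissues = ["head", "leg"]
    genes = [f"g{i:05d}" for i in range(G)]

    base = rng.normal(params.baseline_log2_mean, params.baseline_log2_sd, G)
    rho = params.species_correlation
    latent: dict[tuple[str, str], np.ndarray] = {}
    # combined biological deviation (baseline + tissue effect) is shared
    # between species at exactly the requested correlation
    dev_sd = math.hypot(params.baseline_log2_sd, params.tissue_effect_sd)
    for tissue in tissues:
        tiss = rng.normal(0.0, params.tissue_effect_sd, G)
        dev_a = (base - params.baseline_log2_mean) + tiss
        eps = rng.normal(0.0, dev_sd, G)
        dev_b = rho * dev_a + math.sqrt(max(0.0, 1 - rho * rho)) * eps
        latent[("A", tissue)] = params.baseline_log2_mean + dev_a
        latent[("B", tissue)] = params.baseline_log2_mean + dev_b

    de_truth: dict[str, list[DifferentialResult]] = {}
    for tissue in tissues:
        frac = params.de_fraction.get(tissue, 0.0)
        n_de = round(frac * G)
        idx = rng.choice(G, size=n_de, replace=False) if n_de else []
        effects = np.zeros(G)
        if n_de:
            mag = rng.uniform(params.effect_log2_low,
                              params.effect_log2_high, n_de)
            up_a = rng.random(n_de) < params.up_in_a_bias.get(tissue, 0.5)
            effects[idx] = np.where(up_a, mag, -mag)
        latent[("A", tissue)] = latent[("A", tissue)] + effects / 2.0
        latent[("B", tissue)] = latent[("B", tissue)] - effects / 2.0
        table = []
        for g in range(G):
            if effects[g] != 0.0:
                table.append(DifferentialResult(genes[g], float(effects[g]),
                                                1e-6, True))
            else:
                table.append(DifferentialResult(genes[g], 0.0, 1.0, False))
        de_truth[tissue] = table

    columns = {}
    meta_rows = []
    r_inv_disp = 1.0 / params.dispersion
    for species in ("A", "B"):
        for tissue in tissues:
            for rep in range(1, params.n_replicates + 1):
                sample = f"{species}_{tissue}_{rep}"
                z = latent[(species, tissue)].copy()
                if rep == params.n_replicates and params.noisy_replicate_sd:
                    z = z + rng.normal(0.0, params.noisy_replicate_sd, G)
                mean = np.power(2.0, z)
                p = r_inv_disp / (r_inv_disp + mean)
                columns[sample] = rng.negative_binomial(r_inv_disp, p)
                meta_rows.append((sample, species, tissue, str(rep)))
    values = pd.DataFrame(columns, index=genes).astype(float)
    meta = pd.DataFrame(meta_rows,
                        columns=["sample_id", "species", "tissue",
                                 "replicate"]).set_index("sample_id")
    return CountMatrix(values, meta), de_truth


# ---------------------------------------------------------------------------
# annotations

def simulate_annotation(
    n_genes: int = 5000,
    n_terms: int = 50,
    genes_per_term_low: int = 20,
    genes_per_term_high: int = 200,
    planted_term_size: int = 100,
    enrichment_factor: float = 5.0,
    study_size: int = 200,
    seed: int = 0,
) -> tuple[TermAnnotation, set[str], dict]:
    """Random gene -> term annotation with one planted enriched term.

    The planted term's members enter the study set with sampling weight
    ``enrichment_factor`` relative to other annotated genes (factor 1 makes
    it a null term).  Returns (annotation, study set, truth).
    """
    if planted_term_size > n_genes:
        raise ValueError("planted term larger than the population")
    rng = np.random.default_rng(seed)
    genes = np.array([f"g{i:05d}" for i in range(n_genes)])
    terms: dict[str, set[str]] = {}
    planted = "T0000"
    members = rng.choice(n_genes, size=planted_term_size, replace=False)
    terms[planted] = set(genes[members])
    for t in range(1, n_terms):
        size = int(rng.integers(genes_per_term_low,
                                genes_per_term_high + 1))
        idx = rng.choice(n_genes, size=size, replace=False)
        terms[f"T{t:04d}"] = set(genes[idx])
    annotation = TermAnnotation(terms)
    annotated = np.array(sorted(annotation.annotated_genes()))
    weights = np.ones(annotated.size)
    planted_mask = np.isin(annotated, list(terms[planted]))
    weights[planted_mask] = enrichment_factor
    weights /= weights.sum()
    study_idx = rng.choice(annotated.size, size=min(study_size,
                                                    annotated.size),
                           replace=False, p=weights)
    study = set(annotated[study_idx])
    truth = {"planted_term": planted,
             "enrichment_factor": enrichment_factor,
             "planted_in_study": len(study & terms[planted])}
    return annotation, study, truth
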