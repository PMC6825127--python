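"""Synthetic cohorts with the statistical structure the pipeline assumes.

The generator emulates a tumor/normal exome cohort end to end so that
every downstream stage is testable without any download: a scale-free
gene network grown by preferential attachment (real interaction networks
are hub-dominated, which is what propagation concentrates on), a set of
planted recurrence-driver genes, per-sample variant tables whose normal-
sample VAFs follow binomial read-sampling around 0.5 (het), 1.0 (hom) or
0.25 (somatic contaminant), group-shifted expression, exponential
disease-free survival with uniform censoring, and leukocyte metagene
profiles.

The planted signal acts on the planted genes *and their first network
neighbors*: recurred samples draw functional germline variants from that
neighborhood at ``seed_enrichment`` times the base rate.  Because the
informative gene set is a network neighborhood rather than a fixed list,
propagation — not raw mutation counting — is the mechanism that recovers
it.  With ``seed_enrichment=1`` and ``expr_shift=0`` the generator is
label-permutation-invariant: nothing downstream can beat chance.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .propagation import GeneNetwork, normalize_network
from .variants import VariantRecord

logger = logging.getLogger(__name__)

#: Leukocyte metagene profiles tracked in the group comparisons, with the
#: sign of their planted enrichment (+1 = higher in recurred/high-risk).
METAGENE_PROFILES = {
    "MDSC": -1, "E-Memory CD8": -1, "DC+": -1, "CD8+": -1,
    "Tfh": -1, "Monos": -1, "memory B": 1, "B cell+": -1,
    "NK-": -1, "MC-": 1, "gd T": -1, "Neutrophils": 0,
}

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class SyntheticConfig:
    """Knobs of the cohort generator.

    Sample counts mirror a training/testing/validation exome-cohort design
    (200/60/200); ``p_recur`` matches a ~15% relapse rate.
    ``seed_rate_base`` is the expected number of functional germline genes
    per non-recurred sample; recurred samples multiply the per-gene rate
    by ``seed_enrichment`` on the planted neighborhood.  Hazards are
    exponential event rates per month.
    """

    n_genes: int = 600
    n_edges_per_node: int = 3
    n_hallmarks: int = 10
    hallmark_size: int = 150
    n_planted: int = 8
    n_train: int = 200
    n_test: int = 60
    n_valid: int = 200
    p_recur: float = 0.15
    seed_rate_base: float = 60.0
    seed_enrichment: float = 3.0
    coverage_mean: float = 80.0
    expr_shift: float = 0.8
    hazard_low: float = 0.005
    hazard_high: float = 0.02
    censor_max: float = 120.0
    rng_seed: int = 0

    def __post_init__(self):
        counts = (self.n_genes, self.n_edges_per_node, self.n_hallmarks,
                  self.hallmark_size, self.n_planted, self.n_train,
                  self.n_test, self.n_valid)
        if any(c < 1 for c in counts):
            raise ValueError("all counts must be positive")
        if self.n_genes < 2 * self.n_edges_per_node:
            raise ValueError("n_genes must be >= 2 * n_edges_per_node")
        if not 0.0 < self.p_recur < 1.0:
            raise ValueError("p_recur must lie in (0, 1)")
        if self.seed_enrichment < 1.0:
            raise ValueError("seed_enrichment must be >= 1")
        if self.hazard_high <= self.hazard_low:
            raise ValueError("hazard_high must exceed hazard_low")


@dataclass
class SyntheticCohort:
    network: GeneNetwork
    hallmark_sets: dict[str, list[str]]
    planted_genes: set[str]
    informative_genes: set[str]          # planted genes + first neighbors
    leukocyte_genes: set[str]
    variant_tables: dict[str, list[VariantRecord]]
    expression: pd.DataFrame             # genes x samples
    clinical: pd.DataFrame               # indexed by sample_id
    metagenes: pd.DataFrame              # metagene x samples
    config: SyntheticConfig | None = None

    @property
    def labels(self) -> pd.Series:
        return self.clinical["label"]

    def split(self, name: str) -> pd.Index:
        return self.clinical.index[self.clinical["split"] == name]


def generate_network(config: SyntheticConfig) -> GeneNetwork:
    """Scale-free gene network grown by preferential attachment.

    ``n_genes`` nodes, each newcomer attaching ``n_edges_per_node`` edges,
    giving m*(n-m) unit-weight edges; connected and deterministic under
    ``rng_seed``.
    """
    g = nx.barabasi_albert_graph(config.n_genes, config.n_edges_per_node,
                                 seed=config.rng_seed)
    names = {i: f"G{i:05d}" for i in g.nodes}
    edges = [(names[a], names[b]) for a, b in sorted(g.edges)]
    return normalize_network(edges, genes=list(names.values()))


def _draw_vaf(rng, coverage: int, p: float) -> float:
    return rng.binomial(coverage, p) / coverage


def _variant_for(rng, gene: str, gene_idx: int, sample_id: str,
                 kind: str, coverage_mean: float) -> VariantRecord:
    """One simulated variant record of a given kind.

    kinds: germline_functional, germline_benign, somatic.  Normal VAF is
    binomial read sampling around 0.5 (het) / 1.0 (hom) for germline and
    0.25 for a somatic contaminant leaking into the normal sample.
    """
    cov = max(10, int(rng.poisson(coverage_mean)))
    if kind == "somatic":
        normal_p, tumor_p = 0.25, 0.4
        cadd = float(rng.uniform(0.0, 40.0))
    else:
        normal_p = 1.0 if rng.random() < 0.2 else 0.5
        tumor_p = normal_p
        cadd = float(rng.uniform(15.0, 40.0)) if kind == "germline_functional" \
            else float(rng.uniform(0.0, 15.0))
    ref, alt = rng.choice(4, size=2, replace=False)
    return VariantRecord(
        chrom=f"chr{gene_idx % 22 + 1}",
        pos=1_000_000 + gene_idx * 10_000 + int(rng.integers(0, 5_000)),
        ref=str(_BASES[ref]), alt=str(_BASES[alt]),
        gene=gene, sample_id=sample_id,
        tumor_vaf=_draw_vaf(rng, cov, tumor_p),
        normal_vaf=_draw_vaf(rng, cov, normal_p),
        func_scores={"cadd_phred": round(cadd, 2)},
    )


def generate_cohort(config: SyntheticConfig | None = None) -> SyntheticCohort:
    """Generate a full synthetic cohort; byte-identical under one config."""
    config = config or SyntheticConfig()
    rng = np.random.default_rng(config.rng_seed)
    cov_mean = config.coverage_mean

    network = generate_network(config)
    genes = list(network.genes)
    gene_idx = {g: i for i, g in enumerate(genes)}
    n_genes = len(genes)

    planted = set(rng.choice(genes, size=config.n_planted, replace=False))
    informative = set(planted)
    for g in planted:
        informative |= network.neighbors(g)

    hallmarks = _make_hallmarks(rng, genes, informative, config)
    leukocyte = _make_leukocyte_set(rng, genes, informative)

    # --- samples, splits, labels -------------------------------------------
    n_total = config.n_train + config.n_test + config.n_valid
    sample_ids = [f"S{i:04d}" for i in range(n_total)]
    splits = (["train"] * config.n_train + ["test"] * config.n_test
              + ["valid"] * config.n_valid)
    labels = _draw_labels(rng, splits, config.p_recur)

    # --- per-gene seed probabilities ---------------------------------------
    p0 = min(0.9, config.seed_rate_base / n_genes)
    base_p = np.full(n_genes, p0)
    enr_p = base_p.copy()
    inf_mask = np.array([g in informative for g in genes])
    enr_p[inf_mask] = np.minimum(0.9, p0 * config.seed_enrichment)

    variant_tables: dict[str, list[VariantRecord]] = {}
    for sid, lab in zip(sample_ids, labels):
        p = enr_p if lab == 1 else base_p
        hit = np.flatnonzero(rng.random(n_genes) < p)
        if hit.size == 0:
            hit = np.array([rng.integers(0, n_genes)])
        records = []
        for gi in hit:
            for _ in range(1 + rng.poisson(0.3)):
                records.append(_variant_for(rng, genes[gi], gi, sid,
                                            "germline_functional", cov_mean))
        # benign germline background + ~20% somatic contaminants
        for _ in range(rng.poisson(config.seed_rate_base)):
            gi = int(rng.integers(0, n_genes))
            records.append(_variant_for(rng, genes[gi], gi, sid,
                                        "germline_benign", cov_mean))
        n_somatic = int(round(0.25 * len(records)))
        for _ in range(n_somatic):
            gi = int(rng.integers(0, n_genes))
            records.append(_variant_for(rng, genes[gi], gi, sid, "somatic",
                                        cov_mean))
        variant_tables[sid] = records

    # --- expression (genes x samples), informative genes shifted -----------
    expr = rng.standard_normal((n_genes, n_total))
    rec_mask = labels == 1
    expr[np.ix_(inf_mask, rec_mask)] += config.expr_shift
    expression = pd.DataFrame(expr, index=genes, columns=sample_ids)

    # --- clinical -----------------------------------------------------------
    clinical = _make_clinical(rng, sample_ids, splits, labels, config)

    # --- leukocyte metagenes -------------------------------------------------
    mg = rng.standard_normal((len(METAGENE_PROFILES), n_total))
    for i, (_, sign) in enumerate(METAGENE_PROFILES.items()):
        mg[i, rec_mask] += sign * 0.6 * config.expr_shift
    metagenes = pd.DataFrame(mg, index=list(METAGENE_PROFILES),
                             columns=sample_ids)

    return SyntheticCohort(
        network=network, hallmark_sets=hallmarks, planted_genes=planted,
        informative_genes=informative, leukocyte_genes=leukocyte,
        variant_tables=variant_tables, expression=expression,
        clinical=clinical, metagenes=metagenes, config=config,
    )


def _draw_labels(rng, splits, p_recur, max_tries: int = 100) -> np.ndarray:
    """Bernoulli labels, redrawn until every split holds both classes."""
    splits = np.asarray(splits)
    for _ in range(max_tries):
        labels = (rng.random(len(splits)) < p_recur).astype(int)
        if all(0 < labels[splits == s].sum() < (splits == s).sum()
               for s in np.unique(splits)):
            return labels
    raise RuntimeError("could not draw labels with both classes in every split")


def _make_hallmarks(rng, genes, informative, config) -> dict[str, list[str]]:
    """Hallmark gene sets: the first two carry the planted signal, holding a
    ~25% minority of informative genes diluted in background; the rest are
    pure background.  Keeping informative genes a minority of the pool is
    what makes randomized screening non-trivial: only informative-rich gene
    draws separate the classes, so hit frequencies discriminate."""
    background = sorted(set(genes) - informative)
    informative = sorted(informative)
    hallmarks = {}
    n_info_hm = min(2, config.n_hallmarks)
    for h in range(config.n_hallmarks):
        name = f"HALLMARK_{h + 1:02d}"
        if h < n_info_hm:
            k_info = min(len(informative), config.hallmark_size // 4)
            members = list(rng.choice(informative, size=k_info, replace=False))
            k_bg = min(len(background), config.hallmark_size - k_info)
            members += list(rng.choice(background, size=k_bg, replace=False))
        else:
            k = min(len(background), config.hallmark_size)
            members = list(rng.choice(background, size=k, replace=False))
        hallmarks[name] = sorted(members)
    return hallmarks


def _make_leukocyte_set(rng, genes, informative) -> set[str]:
    """Leukocyte-expressed genes: ~10% of the genome, enriched 30% in the
    informative neighborhood so burden contrasts have a leukocyte component."""
    n = max(1, len(genes) // 10)
    n_info = min(len(informative), int(0.3 * n))
    picked = set(rng.choice(sorted(informative), size=n_info, replace=False))
    background = sorted(set(genes) - informative)
    picked |= set(rng.choice(background, size=min(len(background), n - n_info),
                             replace=False))
    return picked


def _make_clinical(rng, sample_ids, splits, labels, config) -> pd.DataFrame:
    hazards = np.where(labels == 1, config.hazard_high, config.hazard_low)
    t_event = rng.exponential(1.0 / hazards)
    t_censor = rng.uniform(0.0, config.censor_max, size=len(sample_ids))
    dfs = np.minimum(t_event, t_censor)
    event = t_event <= t_censor
    # covariates independent of the planted signal by design
    age = np.clip(rng.normal(59, 10, size=len(sample_ids)), 25, 90).round(1)
    stage = rng.choice(["I", "II", "III", "IV"], size=len(sample_ids),
                       p=[0.20, 0.55, 0.20, 0.05])
    nodal = rng.choice([0, 1, 2, 3], size=len(sample_ids),
                       p=[0.45, 0.35, 0.12, 0.08])
    return pd.DataFrame(
        {
            "label": np.where(labels == 1, "recurred", "non-recurred"),
            "dfs_months": dfs.round(3),
            "event": event.astype(int),
            "age": age,
            "stage": stage,
            "nodal": nodal,
            "split": splits,
        },
        index=pd.Index(sample_ids, name="sample_id"),
    )
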