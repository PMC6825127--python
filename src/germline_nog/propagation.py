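"""Network propagation of per-sample seed genes to continuous heating scores.

Each sample's functionally mutated germline genes act as heat sources on a
gene-gene interaction network; diffusing that heat yields a steady-state
"heating score" for every network gene, turning a binary mutation profile
into a continuous one that reflects network context.

The update is the random-walk-with-restart form with symmetric degree
normalization:

    F_{t+1} = alpha * W F_t + (1 - alpha) * F_0,
    W = D^{-1/2} A D^{-1/2}

where ``F_0`` puts weight 1/|seeds| on each seed gene, so samples carrying
different numbers of variants remain comparable.  The fixed point is
``(1 - alpha) (I - alpha W)^{-1} F_0``; because the symmetric-normalized
walk does not conserve mass exactly, each sample's final score vector is
renormalized to sum to one.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
from sklearn.base import BaseEstimator, TransformerMixin

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage of the pipeline cannot produce output (e.g. no seedable samples)."""


@dataclass(frozen=True)
class PropagationConfig:
    alpha: float = 0.7
    tol: float = 1e-8
    max_iter: int = 1000

    def __post_init__(self):
        if not 0.0 < self.alpha < 1.0:
            raise ValueError(f"alpha must be in (0, 1), got {self.alpha}")
        if self.tol <= 0:
            raise ValueError("tol must be positive")


@dataclass
class GeneNetwork:
    """Undirected weighted gene graph with its symmetric-normalized adjacency.

    ``W = D^{-1/2} A D^{-1/2}``; isolated nodes are retained with zero
    rows so that the gene universe is stable.
    """

    genes: list[str]
    adjacency: sp.csr_matrix
    W: sp.csr_matrix
    index: dict[str, int] = field(default_factory=dict)

    def __post_init__(self):
        if not self.index:
            self.index = {g: i for i, g in enumerate(self.genes)}

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    @property
    def n_edges(self) -> int:
        return int(self.adjacency.nnz // 2)

    def degrees(self) -> np.ndarray:
        return np.asarray(self.adjacency.sum(axis=1)).ravel()

    def neighbors(self, gene: str) -> set[str]:
        i = self.index[gene]
        row = self.adjacency.getrow(i)
        return {self.genes[j] for j in row.indices}


def normalize_network(edges, genes: list[str] | None = None) -> GeneNetwork:
    """Build a :class:`GeneNetwork` from an undirected weighted edge list.

    ``edges`` is an iterable of ``(gene_a, gene_b)`` or
    ``(gene_a, gene_b, weight)``; missing weights default to 1.  Gene
    symbols are upper-cased; self-loops are rejected, duplicate edges keep
    the last weight seen.  ``genes`` optionally fixes the node universe
    (extra names become isolated nodes).
    """
    triples = []
    for e in edges:
        if len(e) == 2:
            a, b, w = e[0], e[1], 1.0
        else:
            a, b, w = e[0], e[1], float(e[2])
        a, b = str(a).upper(), str(b).upper()
        if a == b:
            raise ValueError(f"self-loop on {a} not allowed")
        if w <= 0:
            raise ValueError(f"edge {a}-{b} has non-positive weight {w}")
        triples.append((a, b, w))
    if not triples and genes is None:
        raise ValueError("empty edge list")

    universe = {g for a, b, _ in triples for g in (a, b)}
    if genes is not None:
        universe |= {str(g).upper() for g in genes}
    gene_list = sorted(universe)
    idx = {g: i for i, g in enumerate(gene_list)}
    n = len(gene_list)

    A = sp.lil_matrix((n, n))
    for a, b, w in triples:
        A[idx[a], idx[b]] = w
        A[idx[b], idx[a]] = w
    A = A.tocsr()

    deg = np.asarray(A.sum(axis=1)).ravel()
    with np.errstate(divide="ignore"):
        dinv = 1.0 / np.sqrt(deg)
    dinv[~np.isfinite(dinv)] = 0.0  # isolated nodes keep zero rows
    Dinv = sp.diags(dinv)
    W = (Dinv @ A @ Dinv).tocsr()
    return GeneNetwork(genes=gene_list, adjacency=A, W=W, index=idx)


def _seed_vector(network: GeneNetwork, seeds, warn: bool = True) -> np.ndarray | None:
    """Uniform F_0 over the seeds present in the network; None if unseedable."""
    present = sorted({str(g).upper() for g in seeds} & set(network.index))
    missing = len(set(seeds)) - len(present)
    if missing and warn:
        logger.debug("%d seed genes absent from network, dropped", missing)
    if not present:
        return None
    f0 = np.zeros(network.n_genes)
    for g in present:
        f0[network.index[g]] = 1.0 / len(present)
    return f0


def _iterate(W: sp.csr_matrix, F0: np.ndarray, config: PropagationConfig) -> np.ndarray:
    F = F0.copy()
    for _ in range(config.max_iter):
        F_next = config.alpha * (W @ F) + (1.0 - config.alpha) * F0
        delta = np.abs(F_next - F).sum(axis=0)
        F = F_next
        if np.max(delta) < config.tol:
            return F
    raise RuntimeError(
        f"propagation did not converge within {config.max_iter} iterations"
    )


def propagate(
    network: GeneNetwork,
    seeds,
    config: PropagationConfig | None = None,
    renormalize: bool = True,
) -> pd.Series:
    """Diffuse one sample's seed set; returns the heating-score vector.

    With ``renormalize`` (default) the fixed point is scaled to sum to one
    so columns are comparable across samples; disable it to inspect the raw
    fixed point ``(1-alpha)(I-alpha W)^{-1} F_0``.
    """
    config = config or PropagationConfig()
    f0 = _seed_vector(network, seeds)
    if f0 is None:
        raise PipelineError("no seed genes present in the network (unseedable sample)")
    F = _iterate(network.W, f0[:, None], config).ravel()
    if renormalize:
        F = F / F.sum()
    return pd.Series(F, index=network.genes)


@dataclass
class HeatMatrix:
    """Genes x samples heating scores plus the binary seed indicator."""

    scores: pd.DataFrame
    seed_indicator: pd.DataFrame
    excluded_samples: list[str] = field(default_factory=list)

    @property
    def genes(self) -> pd.Index:
        return self.scores.index

    @property
    def samples(self) -> pd.Index:
        return self.scores.columns


def build_heat_matrix(
    network: GeneNetwork,
    seeds_per_sample: dict[str, set[str]],
    config: PropagationConfig | None = None,
) -> HeatMatrix:
    """Propagate every sample's seeds and aggregate the score columns.

    Samples whose seeds all miss the network are excluded and listed in
    ``excluded_samples``; all columns of the returned matrix sum to one.
    All samples share one iterative solve (the linear operator is the
    same), so cost scales with one sparse matvec per iteration.
    """
    config = config or PropagationConfig()
    sample_ids, f0_cols, excluded = [], [], []
    indicator = {}
    for sid in sorted(seeds_per_sample):
        f0 = _seed_vector(network, seeds_per_sample[sid])
        if f0 is None:
            excluded.append(sid)
            continue
        sample_ids.append(sid)
        f0_cols.append(f0)
        indicator[sid] = (f0 > 0).astype(int)
    if not sample_ids:
        raise PipelineError("no seedable samples: every seed set misses the network")
    if excluded:
        logger.warning("%d samples unseedable, excluded: %s", len(excluded), excluded)

    F0 = np.column_stack(f0_cols)
    F = _iterate(network.W, F0, config)
    F = F / F.sum(axis=0, keepdims=True)
    scores = pd.DataFrame(F, index=network.genes, columns=sample_ids)
    seed_ind = pd.DataFrame(
        {sid: indicator[sid] for sid in sample_ids}, index=network.genes
    )
    return HeatMatrix(scores=scores, seed_indicator=seed_ind, excluded_samples=excluded)


class NetworkPropagator(BaseEstimator, TransformerMixin):
    """Scikit-learn style transformer: seed sets -> heating-score profiles.

    Parameters
    ----------
    network : GeneNetwork or edge list
        The interaction network to diffuse over.
    alpha : float, default 0.7
        Diffusion retention; the fraction of heat that keeps walking at
        each step (1 - alpha restarts at the seeds).
    tol, max_iter :
        L1 convergence tolerance and iteration cap.

    ``transform`` accepts a mapping of sample id to seed-gene set (or a
    list of seed sets) and returns a samples x genes DataFrame of heating
    scores.  Samples with no network seeds are dropped and recorded in
    ``excluded_samples_``.
    """

    def __init__(self, network=None, alpha: float = 0.7, tol: float = 1e-8,
                 max_iter: int = 1000):
        self.network = network
        self.alpha = alpha
        self.tol = tol
        self.max_iter = max_iter

    def fit(self, X=None, y=None):
        if self.network is None:
            raise ValueError("a network is required")
        net = self.network
        if not isinstance(net, GeneNetwork):
            net = normalize_network(net)
        self.network_ = net
        self.config_ = PropagationConfig(alpha=self.alpha, tol=self.tol,
                                         max_iter=self.max_iter)
        return self

    def transform(self, X) -> pd.DataFrame:
        if not hasattr(self, "network_"):
            self.fit()
        if not isinstance(X, dict):
            X = {f"S{i:04d}": s for i, s in enumerate(X)}
        hm = build_heat_matrix(self.network_, X, self.config_)
        self.heat_matrix_ = hm
        self.excluded_samples_ = hm.excluded_samples
        return hm.scores.T
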