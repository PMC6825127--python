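"""Multiple Survival Screening: randomized discovery of 30-gene NOG signatures.

For each cancer-hallmark gene set, many random draws of candidate gene
subsets and training-sample subsets are scored for how well the mean
heating score over the drawn genes separates recurred from non-recurred
samples.  Genes are ranked by how often they appear in separating
("hit") rounds; the top genes form a hallmark-labeled Network Operational
Gene (NOG) signature, to which low/high-risk centroids are attached.

The randomization over both genes and samples is what makes the emitted
signatures robust: a gene must separate the classes across many different
gene contexts and sample subsets to rank highly.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

from ._typing import as_binary_labels
from .propagation import HeatMatrix, PipelineError

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class MSSConfig:
    """Screening knobs.

    ``min_hits`` must sit well above the null expectation
    ``hit_alpha * n_rounds`` (500 at the defaults) or chance alone emits
    signatures from uninformative hallmarks; the default 600 is about
    +4.6 SD above the binomial null.  Scale it together with ``n_rounds``.
    """

    signature_size: int = 30
    n_rounds: int = 10000
    sample_fraction: float = 0.8
    hit_alpha: float = 0.05
    min_hits: int = 600
    statistic: str = "ranksum"  # or "ttest"
    rng_seed: int = 0

    def __post_init__(self):
        if not 0 < self.sample_fraction <= 1:
            raise ValueError("sample_fraction must be in (0, 1]")
        if self.signature_size < 1:
            raise ValueError("signature_size must be >= 1")
        if self.statistic not in ("ranksum", "ttest"):
            raise ValueError(f"unknown statistic {self.statistic!r}")


@dataclass
class NOGSignature:
    """A hallmark-labeled gene signature with per-class centroids.

    ``genes`` is ordered by descending hit frequency (ties lexicographic);
    ``centroid_low``/``centroid_high`` are per-gene mean heating scores of
    the non-recurred / recurred training samples.
    """

    hallmark: str
    genes: list[str]
    gene_frequencies: dict[str, int] = field(default_factory=dict)
    centroid_low: pd.Series | None = None
    centroid_high: pd.Series | None = None
    n_hits: int = 0


def _scores_frame(heat) -> pd.DataFrame:
    return heat.scores if isinstance(heat, HeatMatrix) else heat


def _ranksum_pvalues(m0: np.ndarray, m1: np.ndarray) -> np.ndarray:
    """Two-sided rank-sum p per row (normal approximation, continuity corrected).

    ``m0``/``m1`` are rounds x samples blocks of per-sample means for the
    two classes.  Heating scores are continuous so ties are negligible;
    the asymptotic form matches scipy's two-sided Mann-Whitney at these
    sample sizes.
    """
    n0, n1 = m0.shape[1], m1.shape[1]
    ranks = stats.rankdata(np.concatenate([m0, m1], axis=1), axis=1)
    u1 = ranks[:, n0:].sum(axis=1) - n1 * (n1 + 1) / 2.0
    mu = n0 * n1 / 2.0
    sigma = np.sqrt(n0 * n1 * (n0 + n1 + 1) / 12.0)
    z = (np.abs(u1 - mu) - 0.5) / sigma
    return 2.0 * stats.norm.sf(np.maximum(z, 0.0))


def _welch_pvalues(m0: np.ndarray, m1: np.ndarray) -> np.ndarray:
    """Two-sided Welch t p per row."""
    n0, n1 = m0.shape[1], m1.shape[1]
    v0 = m0.var(axis=1, ddof=1) / n0
    v1 = m1.var(axis=1, ddof=1) / n1
    t = (m0.mean(axis=1) - m1.mean(axis=1)) / np.sqrt(v0 + v1)
    df = (v0 + v1) ** 2 / (v0**2 / (n0 - 1) + v1**2 / (n1 - 1))
    return 2.0 * stats.t.sf(np.abs(t), df)


def screen_hallmark(
    heat,
    labels,
    hallmark_genes,
    config: MSSConfig | None = None,
    hallmark_name: str = "",
    rng: np.random.Generator | None = None,
) -> NOGSignature | None:
    """Screen one hallmark gene pool; returns a signature or ``None``.

    Each round draws ``signature_size`` genes uniformly from the hallmark
    pool (restricted to the heat matrix) and a class-stratified
    ``sample_fraction`` subset of the training samples; the round is a hit
    when the two-sided rank-sum test on per-sample mean heat over the drawn
    genes rejects at ``hit_alpha``.  A signature is emitted only if the
    total hit count reaches ``min_hits``.
    """
    config = config or MSSConfig()
    if rng is None:
        rng = np.random.default_rng(config.rng_seed)
    scores = _scores_frame(heat)
    y = as_binary_labels(labels).reindex(scores.columns).dropna().astype(int)
    if y.nunique() < 2:
        raise ValueError("both label classes must be present for screening")

    pool = sorted(set(str(g).upper() for g in hallmark_genes) & set(scores.index))
    if len(pool) < config.signature_size:
        logger.warning(
            "hallmark %s: pool of %d genes smaller than signature size %d, skipped",
            hallmark_name, len(pool), config.signature_size,
        )
        return None

    X = scores.loc[pool, y.index].to_numpy()  # pool genes x labelled samples
    yv = y.to_numpy()
    idx0 = np.flatnonzero(yv == 0)
    idx1 = np.flatnonzero(yv == 1)
    n0 = max(1, int(round(config.sample_fraction * idx0.size)))
    n1 = max(1, int(round(config.sample_fraction * idx1.size)))
    pvalue_fn = _ranksum_pvalues if config.statistic == "ranksum" else _welch_pvalues

    hit_counts = np.zeros(len(pool), dtype=int)
    n_hits = 0
    # chunk so the b x size x samples gather stays within ~200 MB
    chunk = max(1, min(2000, int(2e8 // (8 * config.signature_size * X.shape[1]))))
    done = 0
    while done < config.n_rounds:
        b = min(chunk, config.n_rounds - done)
        done += b
        # batched draws without replacement: first columns of random orderings
        gsel = np.argsort(rng.random((b, len(pool))), axis=1)[:, :config.signature_size]
        s0 = idx0[np.argsort(rng.random((b, idx0.size)), axis=1)[:, :n0]]
        s1 = idx1[np.argsort(rng.random((b, idx1.size)), axis=1)[:, :n1]]
        means = X[gsel].mean(axis=1)                   # b x samples
        row = np.arange(b)[:, None]
        p = pvalue_fn(means[row, s0], means[row, s1])
        hit = p < config.hit_alpha
        n_hits += int(hit.sum())
        np.add.at(hit_counts, gsel[hit].ravel(), 1)

    if n_hits < config.min_hits:
        logger.info(
            "hallmark %s: %d hit rounds < min_hits=%d, no signature",
            hallmark_name, n_hits, config.min_hits,
        )
        return None

    order = sorted(range(len(pool)), key=lambda i: (-hit_counts[i], pool[i]))
    top = order[: config.signature_size]
    sig = NOGSignature(
        hallmark=hallmark_name,
        genes=[pool[i] for i in top],
        gene_frequencies={pool[i]: int(hit_counts[i]) for i in top},
        n_hits=n_hits,
    )
    return fit_centroids(scores, y, sig)


def fit_centroids(heat, labels, signature: NOGSignature) -> NOGSignature:
    """Attach per-class mean-heating-score centroids to a signature."""
    scores = _scores_frame(heat)
    y = as_binary_labels(labels).reindex(scores.columns).dropna().astype(int)
    missing = set(signature.genes) - set(scores.index)
    if missing:
        raise ValueError(f"signature genes missing from matrix: {sorted(missing)}")
    if (y == 0).sum() == 0 or (y == 1).sum() == 0:
        raise ValueError("both label classes required to fit centroids")
    sub = scores.loc[signature.genes, y.index]
    signature.centroid_low = sub.loc[:, (y == 0).values].mean(axis=1)
    signature.centroid_high = sub.loc[:, (y == 1).values].mean(axis=1)
    if np.allclose(signature.centroid_low, signature.centroid_high):
        logger.warning(
            "hallmark %s: identical class centroids; downstream correlation "
            "classification is degenerate", signature.hallmark,
        )
    return signature


def discover_all(
    heat,
    labels,
    hallmark_collection: dict[str, list[str]],
    config: MSSConfig | None = None,
) -> list[NOGSignature]:
    """Screen every hallmark; returns the emitted signatures.

    Deterministic under ``config.rng_seed``: each hallmark gets an
    independent child stream keyed by its (sorted) position, so adding or
    removing a hallmark does not perturb the others' draws.
    """
    config = config or MSSConfig()
    if not hallmark_collection:
        raise ValueError("empty hallmark collection")
    names = sorted(hallmark_collection)
    streams = np.random.SeedSequence(config.rng_seed).spawn(len(names))
    signatures = []
    for name, ss in zip(names, streams):
        sig = screen_hallmark(
            heat, labels, hallmark_collection[name], config,
            hallmark_name=name, rng=np.random.default_rng(ss),
        )
        if sig is not None:
            signatures.append(sig)
    if not signatures:
        raise PipelineError(
            "no hallmark produced a signature; the heat matrix may carry no "
            "label signal or min_hits may be too strict"
        )
    logger.info("MSS emitted %d signatures from %d hallmarks",
                len(signatures), len(names))
    return signatures


def signatures_to_frame(signatures: list[NOGSignature]) -> pd.DataFrame:
    """Tidy TSV-ready table: hallmark, rank, gene, hit_count, centroids."""
    rows = []
    for sig in signatures:
        for rank, g in enumerate(sig.genes, start=1):
            rows.append({
                "hallmark": sig.hallmark,
                "rank": rank,
                "gene": g,
                "hit_count": sig.gene_frequencies.get(g, 0),
                "centroid_low": None if sig.centroid_low is None else sig.centroid_low[g],
                "centroid_high": None if sig.centroid_high is None else sig.centroid_high[g],
            })
    return pd.DataFrame(rows)


class MSSScreener(BaseEstimator):
    """Scikit-learn style estimator wrapping :func:`discover_all`.

    ``fit(X, y)`` takes a samples x genes heating-score frame and binary
    recurrence labels; emitted signatures land in ``signatures_``.
    """

    def __init__(self, hallmark_sets=None, signature_size: int = 30,
                 n_rounds: int = 1000, sample_fraction: float = 0.8,
                 hit_alpha: float = 0.05, min_hits: int = 50,
                 statistic: str = "ranksum", random_state: int = 0):
        self.hallmark_sets = hallmark_sets
        self.signature_size = signature_size
        self.n_rounds = n_rounds
        self.sample_fraction = sample_fraction
        self.hit_alpha = hit_alpha
        self.min_hits = min_hits
        self.statistic = statistic
        self.random_state = random_state

    def _config(self) -> MSSConfig:
        return MSSConfig(
            signature_size=self.signature_size, n_rounds=self.n_rounds,
            sample_fraction=self.sample_fraction, hit_alpha=self.hit_alpha,
            min_hits=self.min_hits, statistic=self.statistic,
            rng_seed=self.random_state,
        )

    def fit(self, X: pd.DataFrame, y):
        if self.hallmark_sets is None:
            raise ValueError("hallmark_sets is required")
        labels = pd.Series(np.asarray(y), index=X.index)
        self.signatures_ = discover_all(X.T, labels, dict(self.hallmark_sets),
                                        self._config())
        return self
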