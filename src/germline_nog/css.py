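"""Combinatory Signature Set (CSS): nearest-centroid voting over NOG signatures.

Each signature casts a vote per sample: the sample's heating-score (or
expression) profile restricted to the signature genes is correlated
(Pearson) with the low-risk and high-risk centroids and the closer group
wins.  Votes from all signatures are combined through two cutoffs fit on
the testing split — at most ``K_low`` high votes calls a sample low risk,
at least ``K_high`` calls it high risk, and the band in between is left
unpredicted.  Signatures that cannot vote (zero variance, too many missing
genes) abstain and the cutoffs are rescaled to the effective vote count so
missingness never forces a low call.
"""
from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin

from ._typing import ABSTAIN, HIGH, LOW, UNPREDICTED, as_binary_labels, round_half_down
from .mss import NOGSignature

logger = logging.getLogger(__name__)


@dataclass
class RiskCall:
    sample_id: str
    votes_high: int
    n_signatures: int          # total signatures in the model (S)
    n_effective: int           # non-abstaining signatures for this sample
    call: str
    per_signature_calls: list[str] = field(default_factory=list)


@dataclass
class CSSModel:
    signatures: list[NOGSignature]
    K_low: int
    K_high: int
    fit_report: pd.DataFrame | None = None

    @property
    def n_signatures(self) -> int:
        return len(self.signatures)


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    a = a - a.mean()
    b = b - b.mean()
    na, nb = np.sqrt((a * a).sum()), np.sqrt((b * b).sum())
    if na == 0.0 or nb == 0.0:
        return np.nan
    return float((a * b).sum() / (na * nb))


def classify_one(profile: pd.Series, signature: NOGSignature,
                 centroids: tuple[pd.Series, pd.Series] | None = None) -> str:
    """Vote one signature on one per-gene profile: ``low``/``high``/``abstain``.

    Abstains when more than half the signature genes are missing from the
    profile, fewer than two are available, or either correlation is
    undefined (zero variance).  An exact correlation tie goes to low.
    """
    c_low, c_high = centroids if centroids is not None else (
        signature.centroid_low, signature.centroid_high)
    if c_low is None or c_high is None:
        raise ValueError(f"signature {signature.hallmark!r} has no centroids")
    genes = [g for g in signature.genes if g in profile.index]
    if len(genes) < max(2, int(np.ceil(len(signature.genes) / 2))):
        return ABSTAIN
    x = profile[genes].to_numpy(dtype=float)
    r_low = _pearson(x, c_low[genes].to_numpy(dtype=float))
    r_high = _pearson(x, c_high[genes].to_numpy(dtype=float))
    if np.isnan(r_low) or np.isnan(r_high):
        return ABSTAIN
    return HIGH if r_high > r_low else LOW


def _votes(signatures, profile: pd.Series,
           centroids_by_sig: list[tuple[pd.Series, pd.Series]] | None = None
           ) -> list[str]:
    out = []
    for i, sig in enumerate(signatures):
        cen = centroids_by_sig[i] if centroids_by_sig is not None else None
        out.append(classify_one(profile, sig, cen))
    return out


def _call_from_votes(k: int, s_eff: int, s_total: int,
                     K_low: int, K_high: int) -> str:
    """Apply the vote band, rescaling cutoffs to the effective vote count."""
    if s_eff == 0:
        return UNPREDICTED
    if s_eff < s_total:
        K_low = round_half_down(K_low * s_eff / s_total)
        K_high = round_half_down(K_high * s_eff / s_total)
        if K_high <= K_low:           # keep the band ordering after rescaling
            K_high = K_low + 1
    if k <= K_low:
        return LOW
    if k >= K_high:
        return HIGH
    return UNPREDICTED


def _risk_call(sample_id: str, votes: list[str], K_low: int, K_high: int,
               s_total: int) -> RiskCall:
    k = sum(v == HIGH for v in votes)
    s_eff = sum(v != ABSTAIN for v in votes)
    return RiskCall(
        sample_id=sample_id, votes_high=k, n_signatures=s_total,
        n_effective=s_eff,
        call=_call_from_votes(k, s_eff, s_total, K_low, K_high),
        per_signature_calls=votes,
    )


def fit_css(
    signatures: list[NOGSignature],
    testing_profiles: pd.DataFrame,
    testing_labels,
    coverage_floor: float = 0.5,
) -> CSSModel:
    """Grid-search the vote cutoffs (K_low, K_high) on the testing split.

    Every pair with ``0 <= K_low < K_high <= S`` is scored by the sum of
    low-risk and high-risk accuracy (the fraction of predicted-low samples
    that are non-recurred plus the fraction of predicted-high samples that
    are recurred), subject to at least ``coverage_floor`` of the testing
    samples receiving a call.  Ties prefer the widest unpredicted band,
    then the smallest K_low.  ``testing_profiles`` is genes x samples.
    """
    if not signatures:
        raise ValueError("no signatures to combine")
    y = as_binary_labels(testing_labels).reindex(testing_profiles.columns)
    if y.isna().any():
        raise ValueError("every testing sample needs a label")
    if y.nunique() < 2:
        raise ValueError("both classes required in the testing split")
    S = len(signatures)

    votes_by_sample = {
        sid: _votes(signatures, testing_profiles[sid])
        for sid in testing_profiles.columns
    }

    rows = []
    best = None
    for K_low, K_high in itertools.combinations(range(S + 1), 2):
        n_low = n_high = n_low_correct = n_high_correct = 0
        for sid, votes in votes_by_sample.items():
            k = sum(v == HIGH for v in votes)
            s_eff = sum(v != ABSTAIN for v in votes)
            call = _call_from_votes(k, s_eff, S, K_low, K_high)
            if call == LOW:
                n_low += 1
                n_low_correct += int(y[sid] == 0)
            elif call == HIGH:
                n_high += 1
                n_high_correct += int(y[sid] == 1)
        coverage = (n_low + n_high) / len(votes_by_sample)
        low_acc = 100.0 * n_low_correct / n_low if n_low else np.nan
        high_acc = 100.0 * n_high_correct / n_high if n_high else np.nan
        objective = (0.0 if np.isnan(low_acc) else low_acc) + \
                    (0.0 if np.isnan(high_acc) else high_acc)
        feasible = coverage >= coverage_floor
        rows.append({
            "K_low": K_low, "K_high": K_high, "coverage": coverage,
            "low_accuracy": low_acc, "high_accuracy": high_acc,
            "objective": objective, "feasible": feasible,
        })
        if feasible:
            key = (objective, K_high - K_low, -K_low)
            if best is None or key > best[0]:
                best = (key, K_low, K_high)

    report = pd.DataFrame(rows)
    if best is None:
        raise RuntimeError(
            f"no cutoff pair reaches coverage {coverage_floor:.0%} on the "
            "testing split; consider a lower coverage floor"
        )
    _, K_low, K_high = best
    logger.info("CSS fit: K_low=%d K_high=%d over %d signatures", K_low, K_high, S)
    return CSSModel(signatures=signatures, K_low=K_low, K_high=K_high,
                    fit_report=report)


def predict(css: CSSModel, profiles: pd.DataFrame) -> list[RiskCall]:
    """Call low/high/unpredicted for each column of a genes x samples frame."""
    return [
        _risk_call(sid, _votes(css.signatures, profiles[sid]),
                   css.K_low, css.K_high, css.n_signatures)
        for sid in profiles.columns
    ]


def calls_to_frame(calls: list[RiskCall]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "sample_id": c.sample_id,
            "votes_high": c.votes_high,
            "n_effective": c.n_effective,
            "call": c.call,
        }
        for c in calls
    ).set_index("sample_id")


def classify_expression(
    css: CSSModel,
    expression: pd.DataFrame,
    train_labels,
    mode: str = "loo",
) -> list[RiskCall]:
    """Classify samples from expression instead of heating scores.

    The signature gene lists and the fitted vote cutoffs are reused
    unchanged; only the centroids are recomputed, from z-scored expression
    of the labelled training samples (z-scoring uses training-split
    mean/SD so validation samples leak nothing).  Under ``mode='loo'`` a
    classified sample that is itself part of the training split is left
    out of its own centroid.
    """
    if mode not in ("loo", "plain"):
        raise ValueError(f"unknown mode {mode!r}")
    y = as_binary_labels(train_labels)
    train_ids = [s for s in y.index if s in expression.columns]
    if not train_ids:
        raise ValueError("no labelled training samples found in the matrix")
    y = y[train_ids]
    if y.nunique() < 2:
        raise ValueError("both classes required among training samples")

    train = expression[train_ids]
    mu = train.mean(axis=1)
    sd = train.std(axis=1, ddof=1).replace(0.0, 1.0)
    z = expression.sub(mu, axis=0).div(sd, axis=0)

    low_ids = [s for s in train_ids if y[s] == 0]
    high_ids = [s for s in train_ids if y[s] == 1]

    def centroids_for(sid: str) -> list[tuple[pd.Series, pd.Series]]:
        lo = [s for s in low_ids if not (mode == "loo" and s == sid)]
        hi = [s for s in high_ids if not (mode == "loo" and s == sid)]
        out = []
        for sig in css.signatures:
            genes = [g for g in sig.genes if g in z.index]
            out.append((z.loc[genes, lo].mean(axis=1),
                        z.loc[genes, hi].mean(axis=1)))
        return out

    calls = []
    for sid in expression.columns:
        votes = _votes(css.signatures, z[sid], centroids_for(sid))
        calls.append(_risk_call(sid, votes, css.K_low, css.K_high,
                                css.n_signatures))
    n_abstain = sum(v == ABSTAIN for c in calls for v in c.per_signature_calls)
    if all(c.n_effective == 0 for c in calls):
        logger.error("all signatures abstained for every sample "
                     "(matrix missing the signature genes?)")
    elif n_abstain:
        logger.info("expression classification: %d signature abstentions", n_abstain)
    return calls


class CSSClassifier(BaseEstimator, ClassifierMixin):
    """Scikit-learn style wrapper: fit cutoffs on a testing split, predict calls.

    ``fit(X, y)`` takes samples x genes profiles of the testing split and
    binary labels; ``predict`` returns an array over
    {'low', 'high', 'unpredicted'}.
    """

    def __init__(self, signatures=None, coverage_floor: float = 0.5):
        self.signatures = signatures
        self.coverage_floor = coverage_floor

    def fit(self, X: pd.DataFrame, y):
        if not self.signatures:
            raise ValueError("signatures are required")
        labels = pd.Series(np.asarray(y), index=X.index)
        model = fit_css(list(self.signatures), X.T, labels, self.coverage_floor)
        self.model_ = model
        self.K_low_ = model.K_low
        self.K_high_ = model.K_high
        self.fit_report_ = model.fit_report
        self.classes_ = np.array([LOW, HIGH, UNPREDICTED])
        return self

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        calls = predict(self.model_, X.T)
        return np.array([c.call for c in calls])

    def predict_calls(self, X: pd.DataFrame) -> list[RiskCall]:
        return predict(self.model_, X.T)
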