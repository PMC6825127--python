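"""Oncotype DX 21-gene recurrence score (RS) from an expression matrix.

Implements the published 21-gene formula (Paik et al. referent): five
reference genes center each sample, four gene groups (HER2/GRB7, ER,
proliferation, invasion) are scored as weighted means with the published
floors on the GRB7 and proliferation groups, and the unscaled RS is their
weighted sum plus three single-gene terms.  The reported RS is the affine
clamp ``20 * (RSu - 6.7)`` into [0, 100], binned low (<18), intermediate
(18-30) or high (>=31).  Every coefficient, floor and threshold lives in
:class:`OncotypeModel` so a variant formula can be dropped in from config.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from ._typing import HIGH, LOW
from .evaluation import MetricReport, accuracy_recall

INTERMEDIATE = "intermediate"

#: Per-gene weights within each group; group score = weighted sum / divisor.
DEFAULT_GROUPS: dict[str, dict] = {
    "her2": {"weights": {"GRB7": 0.9, "ERBB2": 0.1}, "divisor": 1.0, "floor": 8.0},
    "er": {"weights": {"ESR1": 0.8, "PGR": 1.2, "BCL2": 1.0, "SCUBE2": 1.0},
           "divisor": 4.0, "floor": None},
    "proliferation": {"weights": {"MKI67": 1.0, "AURKA": 1.0, "BIRC5": 1.0,
                                  "CCNB1": 1.0, "MYBL2": 1.0},
                      "divisor": 5.0, "floor": 6.5},
    "invasion": {"weights": {"CTSV": 1.0, "MMP11": 1.0},
                 "divisor": 2.0, "floor": None},
}

DEFAULT_GROUP_COEFFICIENTS = {"her2": 0.47, "er": -0.34,
                              "proliferation": 1.04, "invasion": 0.10}
DEFAULT_SINGLE_GENE_COEFFICIENTS = {"CD68": 0.05, "GSTM1": -0.08, "BAG1": -0.07}
DEFAULT_REFERENCE_GENES = ("ACTB", "GAPDH", "GUSB", "RPLP0", "TFRC")


@dataclass
class OncotypeModel:
    reference_genes: tuple[str, ...] = DEFAULT_REFERENCE_GENES
    group_definitions: dict = field(default_factory=lambda: {
        g: dict(d, weights=dict(d["weights"])) for g, d in DEFAULT_GROUPS.items()})
    group_coefficients: dict = field(
        default_factory=lambda: dict(DEFAULT_GROUP_COEFFICIENTS))
    single_gene_coefficients: dict = field(
        default_factory=lambda: dict(DEFAULT_SINGLE_GENE_COEFFICIENTS))
    rs_scale: float = 20.0
    rs_offset: float = 6.7
    bin_thresholds: tuple[float, float] = (18.0, 31.0)  # low < 18 <= int < 31 <= high

    @property
    def cancer_genes(self) -> list[str]:
        genes = []
        for d in self.group_definitions.values():
            genes.extend(d["weights"])
        genes.extend(self.single_gene_coefficients)
        return genes

    @property
    def all_genes(self) -> list[str]:
        return self.cancer_genes + list(self.reference_genes)

    def bin(self, rs: float) -> str:
        low_max, int_max = self.bin_thresholds
        if rs < low_max:
            return LOW
        if rs < int_max:
            return INTERMEDIATE
        return HIGH


@dataclass
class RSResult:
    sample_id: str
    unscaled_rs: float
    rs: float
    bin: str


def reference_normalize(expression: pd.Series | pd.DataFrame,
                        model: OncotypeModel) -> pd.Series | pd.DataFrame:
    """Subtract each sample's mean reference-gene expression."""
    ref = list(model.reference_genes)
    if isinstance(expression, pd.Series):
        return expression - expression[ref].mean()
    return expression.sub(expression.loc[ref].mean(axis=0), axis=1)


def prepare_expression(expression: pd.DataFrame, log_transform: bool = True
                       ) -> pd.DataFrame:
    """Normalize an RNA-seq (FPKM-style) matrix for RS computation:
    log2(x + 1); reference centering happens inside :func:`compute_rs`."""
    return np.log2(expression + 1.0) if log_transform else expression


def compute_rs(expression_column: pd.Series, model: OncotypeModel | None = None,
               sample_id: str = "") -> RSResult:
    """Score one sample's (already log-scale) expression column."""
    model = model or OncotypeModel()
    missing = [g for g in model.all_genes if g not in expression_column.index]
    if missing:
        raise ValueError(f"expression column missing required genes: {missing}")
    x = reference_normalize(expression_column, model)

    group_scores = {}
    for name, d in model.group_definitions.items():
        s = sum(w * x[g] for g, w in d["weights"].items()) / d["divisor"]
        if d["floor"] is not None and s < d["floor"]:
            s = d["floor"]
        group_scores[name] = s

    rsu = sum(model.group_coefficients[g] * s for g, s in group_scores.items())
    rsu += sum(c * x[g] for g, c in model.single_gene_coefficients.items())
    rs = float(np.clip(model.rs_scale * (rsu - model.rs_offset), 0.0, 100.0))
    return RSResult(sample_id=sample_id or str(expression_column.name),
                    unscaled_rs=float(rsu), rs=rs, bin=model.bin(rs))


def compute_rs_matrix(expression: pd.DataFrame,
                      model: OncotypeModel | None = None) -> pd.DataFrame:
    """Score every sample column; returns sample_id, unscaled_rs, rs, bin."""
    model = model or OncotypeModel()
    results = [compute_rs(expression[s], model, sample_id=str(s))
               for s in expression.columns]
    return pd.DataFrame(
        {"sample_id": r.sample_id, "unscaled_rs": r.unscaled_rs,
         "rs": r.rs, "bin": r.bin} for r in results
    ).set_index("sample_id")


def compare_with_css(rs_results: pd.DataFrame, css_calls, labels,
                     intermediate: str = "exclude"
                     ) -> dict[str, MetricReport]:
    """Side-by-side table metrics for RS bins and NOG_CSS calls.

    Restricted to the overlapping samples.  Intermediate-risk RS bins are
    excluded from the paired metrics by default; ``intermediate='merge_high'``
    folds them into the high-risk bin instead.
    """
    if intermediate not in ("exclude", "merge_high"):
        raise ValueError(f"unknown intermediate handling {intermediate!r}")
    from .evaluation import _calls_series

    css = _calls_series(css_calls)
    rs_bin = rs_results["bin"].copy()
    if intermediate == "merge_high":
        rs_bin = rs_bin.replace(INTERMEDIATE, HIGH)
    overlap = rs_bin.index.intersection(css.index)
    if overlap.empty:
        raise ValueError("no overlapping samples between RS results and CSS calls")
    y = pd.Series(labels).reindex(overlap)
    return {
        "oncotype": accuracy_recall(rs_bin[overlap], y),
        "nog_css": accuracy_recall(css[overlap], y),
    }


class OncotypeRS(BaseEstimator, TransformerMixin):
    """Transformer: samples x genes expression -> RS table.

    ``log_transform`` applies log2(x+1) first (for FPKM-style input); pass
    False when the matrix is already on a log scale.
    """

    def __init__(self, model: OncotypeModel | None = None,
                 log_transform: bool = False):
        self.model = model
        self.log_transform = log_transform

    def fit(self, X=None, y=None):
        self.model_ = self.model or OncotypeModel()
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        if not hasattr(self, "model_"):
            self.fit()
        expr = prepare_expression(X.T, self.log_transform)
        return compute_rs_matrix(expr, self.model_)
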