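"""End-to-end convenience runner: cohort -> seeds -> heat -> signatures -> calls.

Glues the stages together with the split hygiene the method requires:
signatures are screened on the training split only, the vote cutoffs are
fit on the testing split only, and the validation split is touched only
at predict time.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

from . import css as css_mod
from .css import CSSModel, RiskCall, fit_css
from .evaluation import MetricReport, accuracy_recall, km_logrank
from .mss import MSSConfig, NOGSignature, discover_all
from .propagation import HeatMatrix, PropagationConfig, build_heat_matrix
from .synthetic import SyntheticCohort
from .variants import FilterConfig, call_variants, seeds_per_sample

logger = logging.getLogger(__name__)


@dataclass
class PipelineResult:
    heat: HeatMatrix
    signatures: list[NOGSignature]
    css: CSSModel
    calls: dict[str, list[RiskCall]] = field(default_factory=dict)
    metrics: dict[str, MetricReport] = field(default_factory=dict)
    validation_logrank: tuple[float, float] | None = None  # (chi2, p)


def run_pipeline(
    cohort: SyntheticCohort,
    filter_config: FilterConfig | None = None,
    propagation_config: PropagationConfig | None = None,
    mss_config: MSSConfig | None = None,
    coverage_floor: float = 0.5,
) -> PipelineResult:
    """Run variant filtering through risk calling on a (synthetic) cohort."""
    all_records = [r for recs in cohort.variant_tables.values() for r in recs]
    calls = call_variants(all_records, filter_config)
    seeds = seeds_per_sample(calls)
    heat = build_heat_matrix(cohort.network, seeds, propagation_config)

    labels = cohort.labels
    train = [s for s in cohort.split("train") if s in heat.samples]
    test = [s for s in cohort.split("test") if s in heat.samples]
    valid = [s for s in cohort.split("valid") if s in heat.samples]

    signatures = discover_all(heat.scores[train], labels[train],
                              cohort.hallmark_sets, mss_config)
    model = fit_css(signatures, heat.scores[test], labels[test],
                    coverage_floor=coverage_floor)

    result = PipelineResult(heat=heat, signatures=signatures, css=model)
    for split, ids in (("train", train), ("test", test), ("valid", valid)):
        split_calls = css_mod.predict(model, heat.scores[ids])
        result.calls[split] = split_calls
        called = [c for c in split_calls if c.call in ("low", "high")]
        if called and labels[[c.sample_id for c in called]].nunique() == 2:
            result.metrics[split] = accuracy_recall(split_calls, labels)

    result.validation_logrank = _split_logrank(cohort, result.calls["valid"])
    return result


def _split_logrank(cohort, calls) -> tuple[float, float] | None:
    frame = css_mod.calls_to_frame(calls)
    rec = cohort.clinical.loc[frame.index].copy()
    rec["group"] = frame["call"]
    rec = rec[rec["group"].isin(["low", "high"])]
    try:
        _, chi2, p = km_logrank(rec)
    except ValueError as exc:
        logger.info("validation log-rank unavailable: %s", exc)
        return None
    return chi2, p
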