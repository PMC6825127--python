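"""Germline variant classification from paired tumor/normal allele frequencies.

A variant called in a tumor/normal pair is classified from its VAF in the
*normal* (healthy-tissue) sample: reads supporting the alternate allele at
roughly half of the depth indicate a heterozygous inherited variant, near
full depth a homozygous one, and anything else (including low-VAF tumor
contamination leaking into the normal) is treated as not germline.  Only
variants additionally predicted damaging by functional annotation tools
(CADD / MutationTaster / CRAVAT-style scores, consumed as columns) are kept;
the genes carrying at least one retained variant per sample form the seed
sets for network propagation.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import pandas as pd

logger = logging.getLogger(__name__)

HOMOZYGOUS = "homozygous"
HETEROZYGOUS = "heterozygous"
NOT_GERMLINE = "not_germline"

#: Recognised functional-rule names for :class:`FilterConfig`.
FUNCTIONAL_RULES = ("any_damaging", "all_damaging")


@dataclass(frozen=True)
class VariantRecord:
    """One called variant in a tumor/normal pair.

    VAFs are fractions in [0, 1]; positions are 1-based.  ``func_scores``
    maps annotation-tool keys (``cadd_phred``, ``mutationtaster``,
    ``cravat_p``) to the score or verdict that tool produced — the scores
    are inputs, never computed here.
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    gene: str
    tumor_vaf: float
    normal_vaf: float
    sample_id: str
    func_scores: Mapping[str, object] = field(default_factory=dict)

    def __post_init__(self):
        if not 0.0 <= self.tumor_vaf <= 1.0:
            raise ValueError(f"tumor VAF {self.tumor_vaf} outside [0, 1]")
        if not 0.0 <= self.normal_vaf <= 1.0:
            raise ValueError(f"normal VAF {self.normal_vaf} outside [0, 1]")
        if self.pos < 1:
            raise ValueError(f"position {self.pos} must be >= 1 (1-based)")


@dataclass(frozen=True)
class GermlineCall:
    variant: VariantRecord
    zygosity: str
    functional: bool = False


@dataclass(frozen=True)
class FilterConfig:
    """Zygosity thresholds (percent of normal-sample VAF) and functional rule.

    Defaults: homozygous at normal VAF >= 90%, heterozygous within the
    closed window [45%, 65%].  ``functional_rule`` combines the annotator
    verdicts: ``any_damaging`` (default) retains a variant if any annotator
    calls it damaging, ``all_damaging`` requires every *present* annotator
    to agree.  Variants with no annotation evidence are always dropped.
    """

    hom_threshold: float = 90.0
    het_low: float = 45.0
    het_high: float = 65.0
    functional_rule: str = "any_damaging"
    cadd_min: float = 15.0
    mutationtaster_damaging: tuple[str, ...] = ("disease_causing",)
    cravat_alpha: float = 0.05

    def __post_init__(self):
        if not 0 < self.het_low < self.het_high < self.hom_threshold <= 100:
            raise ValueError(
                "thresholds must satisfy 0 < het_low < het_high < "
                f"hom_threshold <= 100, got ({self.het_low}, {self.het_high}, "
                f"{self.hom_threshold})"
            )
        if self.functional_rule not in FUNCTIONAL_RULES:
            raise ValueError(
                f"unknown functional rule {self.functional_rule!r}; "
                f"expected one of {FUNCTIONAL_RULES}"
            )


def classify_zygosity(variant: VariantRecord, config: FilterConfig | None = None) -> GermlineCall:
    """Classify a variant's germline zygosity from its normal-sample VAF.

    Thresholds are compared on the percent scale with inclusive endpoints:
    homozygous iff VAF*100 >= ``hom_threshold``, heterozygous iff
    ``het_low`` <= VAF*100 <= ``het_high``, otherwise not germline.
    """
    config = config or FilterConfig()
    pct = variant.normal_vaf * 100.0
    if pct >= config.hom_threshold:
        zyg = HOMOZYGOUS
    elif config.het_low <= pct <= config.het_high:
        zyg = HETEROZYGOUS
    else:
        zyg = NOT_GERMLINE
    return GermlineCall(variant=variant, zygosity=zyg)


def is_damaging(func_scores: Mapping[str, object], config: FilterConfig) -> bool:
    """Evaluate the functional rule on a variant's annotation scores.

    A variant with no scores at all carries no evidence and is never
    damaging.
    """
    verdicts = []
    if "cadd_phred" in func_scores and func_scores["cadd_phred"] is not None:
        verdicts.append(float(func_scores["cadd_phred"]) >= config.cadd_min)
    if "mutationtaster" in func_scores and func_scores["mutationtaster"] is not None:
        verdicts.append(str(func_scores["mutationtaster"]) in config.mutationtaster_damaging)
    if "cravat_p" in func_scores and func_scores["cravat_p"] is not None:
        verdicts.append(float(func_scores["cravat_p"]) < config.cravat_alpha)
    if not verdicts:
        return False
    if config.functional_rule == "any_damaging":
        return any(verdicts)
    return all(verdicts)


def apply_functional_filter(
    calls: Iterable[GermlineCall], config: FilterConfig | None = None
) -> list[GermlineCall]:
    """Retain germline calls that pass the functional-annotation rule.

    The zygosity gate precedes the function gate: non-germline calls are
    dropped regardless of how damaging their annotation looks.
    """
    config = config or FilterConfig()
    kept = []
    n_dropped_zyg = n_dropped_func = 0
    for call in calls:
        if call.zygosity == NOT_GERMLINE:
            n_dropped_zyg += 1
            continue
        if not is_damaging(call.variant.func_scores, config):
            n_dropped_func += 1
            continue
        kept.append(GermlineCall(call.variant, call.zygosity, functional=True))
    logger.debug(
        "functional filter: kept %d, dropped %d non-germline, %d non-functional",
        len(kept), n_dropped_zyg, n_dropped_func,
    )
    return kept


def call_variants(
    variants: Iterable[VariantRecord], config: FilterConfig | None = None
) -> list[GermlineCall]:
    """Classify zygosity then apply the functional filter."""
    config = config or FilterConfig()
    return apply_functional_filter(
        (classify_zygosity(v, config) for v in variants), config
    )


def seeds_per_sample(calls: Iterable[GermlineCall]) -> dict[str, set[str]]:
    """Per-sample set of genes with at least one retained functional variant."""
    seeds: dict[str, set[str]] = {}
    for call in calls:
        if not call.functional:
            continue
        seeds.setdefault(call.variant.sample_id, set()).add(call.variant.gene)
    return seeds


def burden_summary(
    calls: Iterable[GermlineCall], leukocyte_genes: Iterable[str] = ()
) -> pd.DataFrame:
    """Per-sample burden counts of retained functional germline variants.

    Returns a DataFrame indexed by sample with columns ``n_variants`` (all
    functional germline variants), ``n_genes`` (distinct genes hit) and
    ``n_leukocyte_variants`` (variants in leukocyte-expressed genes).
    """
    leuko = set(leukocyte_genes)
    rows: dict[str, dict[str, object]] = {}
    for call in calls:
        if not call.functional:
            continue
        r = rows.setdefault(
            call.variant.sample_id,
            {"n_variants": 0, "genes": set(), "n_leukocyte_variants": 0},
        )
        r["n_variants"] += 1
        r["genes"].add(call.variant.gene)
        if call.variant.gene in leuko:
            r["n_leukocyte_variants"] += 1
    out = pd.DataFrame(
        {
            sid: {
                "n_variants": r["n_variants"],
                "n_genes": len(r["genes"]),
                "n_leukocyte_variants": r["n_leukocyte_variants"],
            }
            for sid, r in rows.items()
        }
    ).T
    out.index.name = "sample_id"
    return out.sort_index()
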