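"""Readers and writers for the pipeline's file formats.

Variant tables travel either as minimal VCF 4.2 (per-sample files with
INFO keys ``GENE``, ``TVAF``, ``NVAF``, ``FUNC_SCORE``) or as a
Varscan2-like flat TSV; both round-trip to the same
:class:`~germline_nog.variants.VariantRecord` lists.  Networks are
two/three-column edge lists, hallmark collections are GMT, expression /
metagene matrices are TSV with genes in rows and samples in columns.
VCF reading goes through cyvcf2; multi-allelic records are split into
per-alt records, and records with a missing normal VAF are dropped with a
warning count (they cannot be zygosity-classified).
"""
from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable

import pandas as pd

from .variants import VariantRecord

logger = logging.getLogger(__name__)

_VCF_HEADER = """\
##fileformat=VCFv4.2
##INFO=<ID=GENE,Number=1,Type=String,Description="Gene symbol">
##INFO=<ID=TVAF,Number=A,Type=Float,Description="Tumor variant allele frequency">
##INFO=<ID=NVAF,Number=A,Type=Float,Description="Normal variant allele frequency">
##INFO=<ID=FUNC_SCORE,Number=A,Type=Float,Description="Functional annotation score (CADD phred)">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO
"""

VARSCAN_COLUMNS = ["sample_id", "chrom", "pos", "ref", "alt", "gene",
                   "tumor_vaf", "normal_vaf", "cadd_phred"]


def write_vcf(records: Iterable[VariantRecord], path) -> None:
    """Write one sample's records as a minimal VCF 4.2 text file."""
    lines = [_VCF_HEADER]
    for r in sorted(records, key=lambda r: (r.chrom, r.pos, r.alt)):
        info = f"GENE={r.gene};TVAF={r.tumor_vaf:.6g};NVAF={r.normal_vaf:.6g}"
        score = r.func_scores.get("cadd_phred")
        if score is not None:
            info += f";FUNC_SCORE={float(score):.6g}"
        lines.append(f"{r.chrom}\t{r.pos}\t.\t{r.ref}\t{r.alt}\t.\tPASS\t{info}\n")
    Path(path).write_text("".join(lines))


def read_vcf(path, sample_id: str | None = None) -> list[VariantRecord]:
    """Read a per-sample VCF via cyvcf2, splitting multi-allelic records.

    ``sample_id`` defaults to the file stem.  Records without an NVAF are
    skipped (cannot be zygosity-classified); a summary warning counts them.
    """
    from cyvcf2 import VCF

    sid = sample_id or Path(path).stem
    records, n_missing = [], 0
    vcf = VCF(str(path))
    try:
        for v in vcf:
            gene = v.INFO.get("GENE") or "."
            tvaf = _per_alt(v.INFO.get("TVAF"), len(v.ALT))
            nvaf = _per_alt(v.INFO.get("NVAF"), len(v.ALT))
            score = _per_alt(v.INFO.get("FUNC_SCORE"), len(v.ALT))
            for i, alt in enumerate(v.ALT):
                if nvaf[i] is None:
                    n_missing += 1
                    continue
                func = {} if score[i] is None else {"cadd_phred": float(score[i])}
                records.append(VariantRecord(
                    chrom=v.CHROM, pos=v.POS, ref=v.REF, alt=alt, gene=str(gene),
                    tumor_vaf=float(tvaf[i]) if tvaf[i] is not None else 0.0,
                    normal_vaf=float(nvaf[i]), sample_id=sid, func_scores=func,
                ))
    finally:
        vcf.close()
    if n_missing:
        logger.warning("%s: dropped %d alt alleles with missing normal VAF",
                       path, n_missing)
    return records


def _per_alt(value, n_alt: int) -> list:
    """Normalize an INFO value to one entry per alt allele."""
    if value is None:
        return [None] * n_alt
    if isinstance(value, (tuple, list)):
        vals = list(value)
        return vals + [None] * (n_alt - len(vals))
    return [value] * n_alt


def write_varscan_tsv(records: Iterable[VariantRecord], path) -> None:
    rows = [
        {
            "sample_id": r.sample_id, "chrom": r.chrom, "pos": r.pos,
            "ref": r.ref, "alt": r.alt, "gene": r.gene,
            "tumor_vaf": r.tumor_vaf, "normal_vaf": r.normal_vaf,
            "cadd_phred": r.func_scores.get("cadd_phred"),
        }
        for r in records
    ]
    pd.DataFrame(rows, columns=VARSCAN_COLUMNS).to_csv(path, sep="\t", index=False)


def read_varscan_tsv(path) -> list[VariantRecord]:
    df = pd.read_csv(path, sep="\t")
    records, n_missing = [], 0
    for row in df.itertuples(index=False):
        if pd.isna(row.normal_vaf):
            n_missing += 1
            continue
        func = {} if pd.isna(row.cadd_phred) else {"cadd_phred": float(row.cadd_phred)}
        records.append(VariantRecord(
            chrom=str(row.chrom), pos=int(row.pos), ref=str(row.ref),
            alt=str(row.alt), gene=str(row.gene),
            tumor_vaf=float(row.tumor_vaf), normal_vaf=float(row.normal_vaf),
            sample_id=str(row.sample_id), func_scores=func,
        ))
    if n_missing:
        logger.warning("%s: dropped %d records with missing normal VAF",
                       path, n_missing)
    return records


def attach_annotation_scores(records, path) -> list[VariantRecord]:
    """Merge a side table of annotation scores into variant records.

    The TSV is keyed by ``chrom:pos:ref:alt`` (either as one ``variant``
    column or four separate columns) and may carry any of ``cadd_phred``,
    ``mutationtaster``, ``cravat_p``.  Existing inline scores win over the
    side table.
    """
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    if "variant" in df.columns:
        parts = df["variant"].str.split(":", expand=True)
        df[["chrom", "pos", "ref", "alt"]] = parts
    df["pos"] = df["pos"].astype(int)
    score_cols = [c for c in ("cadd_phred", "mutationtaster", "cravat_p")
                  if c in df.columns]
    table = {
        (str(r.chrom), int(r.pos), str(r.ref), str(r.alt)):
            {c: getattr(r, c) for c in score_cols if pd.notna(getattr(r, c))}
        for r in df.itertuples(index=False)
    }
    out = []
    for rec in records:
        side = table.get((rec.chrom, rec.pos, rec.ref, rec.alt), {})
        merged = {**side, **dict(rec.func_scores)}
        out.append(VariantRecord(
            chrom=rec.chrom, pos=rec.pos, ref=rec.ref, alt=rec.alt,
            gene=rec.gene, tumor_vaf=rec.tumor_vaf, normal_vaf=rec.normal_vaf,
            sample_id=rec.sample_id, func_scores=merged,
        ))
    return out


def write_gmt(gene_sets: dict[str, list[str]], path) -> None:
    with open(path, "w") as fh:
        for name in sorted(gene_sets):
            genes = "\t".join(gene_sets[name])
            fh.write(f"{name}\tna\t{genes}\n")


def read_gmt(path) -> dict[str, list[str]]:
    sets = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        parts = line.split("\t")
        if len(parts) < 3:
            raise ValueError(f"malformed GMT line: {line[:80]!r}")
        sets[parts[0]] = parts[2:]
    return sets


def write_edge_list(network, path) -> None:
    """Two-column edge list (unit weights omitted)."""
    with open(path, "w") as fh:
        A = network.adjacency.tocoo()
        for i, j in zip(A.row, A.col):
            if i < j:
                fh.write(f"{network.genes[i]}\t{network.genes[j]}\n")


def read_edge_list(path) -> list[tuple]:
    edges = []
    for line in Path(path).read_text().splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.split("\t")
        edges.append(tuple(parts[:3]) if len(parts) >= 3 else (parts[0], parts[1]))
    return edges


def read_gene_list(path) -> set[str]:
    return {ln.strip().upper() for ln in Path(path).read_text().splitlines()
            if ln.strip()}


def write_matrix(df: pd.DataFrame, path, index_label: str = "gene") -> None:
    df.to_csv(path, sep="\t", index_label=index_label)


def read_matrix(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def write_cohort(cohort, out_dir) -> None:
    """Materialize a synthetic cohort as the pipeline's on-disk formats."""
    out = Path(out_dir)
    (out / "vcf").mkdir(parents=True, exist_ok=True)
    all_records = []
    for sid, records in sorted(cohort.variant_tables.items()):
        write_vcf(records, out / "vcf" / f"{sid}.vcf")
        all_records.extend(records)
    write_varscan_tsv(all_records, out / "variants.tsv")
    write_edge_list(cohort.network, out / "network.tsv")
    write_gmt(cohort.hallmark_sets, out / "hallmarks.gmt")
    write_matrix(cohort.expression, out / "expression.tsv")
    write_matrix(cohort.metagenes, out / "metagenes.tsv", index_label="metagene")
    cohort.clinical.to_csv(out / "clinical.tsv", sep="\t")
    (out / "leukocyte_genes.txt").write_text(
        "\n".join(sorted(cohort.leukocyte_genes)) + "\n")
    (out / "planted_genes.txt").write_text(
        "\n".join(sorted(cohort.planted_genes)) + "\n")
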