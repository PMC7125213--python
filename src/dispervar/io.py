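"""Readers and writers for the package's text formats.

Formats: expression matrices and genotype dosage matrices as TSV (first
column = feature ID, header row = sample IDs), sample group labels as a
two-column TSV, gene sets as MSigDB GMT, genotypes alternatively as
minimal VCF (GT field). Readers validate strictly and reject rather than
coerce malformed input; errors cite line numbers where possible.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import ExpressionMatrix, GeneSetCollection, GenotypeMatrix, ValidationError

__all__ = [
    "read_expression", "write_expression",
    "read_labels", "write_labels",
    "read_gmt", "write_gmt",
    "read_genotypes_tsv", "write_genotypes_tsv",
    "read_vcf", "write_vcf",
    "write_dv_table", "write_dispersion_results",
]

log = logging.getLogger(__name__)

_MISSING_GENO = {".", "NA", "nan", ""}


def _read_matrix_tsv(path, kind: str) -> pd.DataFrame:
    """Strictly parsed feature x sample TSV with line-numbered errors."""
    lines = Path(path).read_text().splitlines()
    if not lines:
        raise ValidationError(f"{path}: empty {kind} file")
    header = lines[0].rstrip("\r").split("\t")
    sample_ids = header[1:]
    if len(sample_ids) != len(set(sample_ids)):
        dups = sorted({s for s in sample_ids if sample_ids.count(s) > 1})
        raise ValidationError(f"{path}: duplicate sample IDs {dups}")
    n_cols = len(header)
    ids, rows = [], []
    for lineno, line in enumerate(lines[1:], start=2):
        fields = line.rstrip("\r").split("\t")
        if len(fields) != n_cols:
            raise ValidationError(
                f"{path}: line {lineno}: expected {n_cols} fields, found {len(fields)}"
            )
        ids.append(fields[0])
        rows.append(fields[1:])
    dup = {g for g in ids if ids.count(g) > 1} if len(ids) != len(set(ids)) else set()
    if dup:
        raise ValidationError(f"{path}: duplicate feature IDs {sorted(dup)}")
    return pd.DataFrame(rows, index=ids, columns=sample_ids)


def read_expression(path, labels: pd.Series | None = None,
                    labels_path=None) -> ExpressionMatrix | pd.DataFrame:
    """Read a gene x sample expression TSV.

    With ``labels`` (or ``labels_path``) returns an
    :class:`ExpressionMatrix`; otherwise the bare values DataFrame.
    Non-numeric or missing cells are rejected with their line number.
    """
    raw = _read_matrix_tsv(path, "expression")
    values = raw.apply(pd.to_numeric, errors="coerce")
    bad = values.isna() | ~np.isfinite(values.to_numpy())
    if bad.to_numpy().any():
        gene = values.index[bad.any(axis=1)][0]
        lineno = list(values.index).index(gene) + 2
        raise ValidationError(f"{path}: line {lineno}: non-numeric or missing value in gene {gene!r}")
    values.index.name = "gene_id"
    if labels_path is not None:
        labels = read_labels(labels_path)
    if labels is None:
        return values
    return ExpressionMatrix(values=values, labels=labels)


def write_expression(matrix: ExpressionMatrix | pd.DataFrame, path) -> None:
    values = matrix.values if isinstance(matrix, ExpressionMatrix) else matrix
    values.to_csv(path, sep="\t", index_label="gene_id")


def read_labels(path) -> pd.Series:
    """Two-column TSV (sample_id, group); a header line is auto-detected."""
    lines = Path(path).read_text().splitlines()
    pairs = []
    for lineno, line in enumerate(lines, start=1):
        if not line.strip():
            continue
        fields = line.rstrip("\r").split("\t")
        if len(fields) != 2:
            raise ValidationError(f"{path}: line {lineno}: expected 2 fields, found {len(fields)}")
        if lineno == 1 and fields[0].lower() in ("sample_id", "sample"):
            continue
        pairs.append(fields)
    if not pairs:
        raise ValidationError(f"{path}: no label rows found")
    ids = [p[0] for p in pairs]
    if len(ids) != len(set(ids)):
        dups = sorted({s for s in ids if ids.count(s) > 1})
        raise ValidationError(f"{path}: duplicate sample IDs {dups}")
    return pd.Series([p[1] for p in pairs], index=ids, name="group")


def write_labels(labels: pd.Series, path) -> None:
    with open(path, "w") as fh:
        fh.write("sample_id\tgroup\n")
        for sample, group in labels.items():
            fh.write(f"{sample}\t{group}\n")


def read_gmt(path) -> GeneSetCollection:
    """MSigDB GMT: one set per line — name, description, member genes.

    Trailing tabs and CRLF line endings are tolerated; duplicate genes
    within a line are de-duplicated (first occurrence kept, logged).
    """
    sets: dict[str, list[str]] = {}
    descriptions: dict[str, str] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.rstrip("\r")
        if not line.strip():
            continue
        fields = [f for f in line.split("\t")]
        while fields and fields[-1] == "":
            fields.pop()
        if len(fields) < 3:
            raise ValidationError(f"{path}: line {lineno}: GMT line needs >= 3 fields")
        name, desc, genes = fields[0], fields[1], fields[2:]
        if name in sets:
            raise ValidationError(f"{path}: line {lineno}: duplicate set name {name!r}")
        deduped = list(dict.fromkeys(genes))
        if len(deduped) != len(genes):
            log.warning("%s: line %d: duplicate genes in set %r de-duplicated", path, lineno, name)
        sets[name] = deduped
        descriptions[name] = desc
    return GeneSetCollection(sets=sets, descriptions=descriptions)


def write_gmt(collection: GeneSetCollection, path) -> None:
    with open(path, "w") as fh:
        for name, genes in collection:
            desc = collection.descriptions.get(name, "")
            fh.write("\t".join([name, desc, *genes]) + "\n")


def read_genotypes_tsv(path) -> GenotypeMatrix:
    """SNP x sample dosage TSV with codes 0/1/2; '.', 'NA' or '' = missing."""
    raw = _read_matrix_tsv(path, "genotype")
    arr = np.full(raw.shape, -1, dtype=np.int8)
    for j in range(raw.shape[1]):
        col = raw.iloc[:, j]
        for i, cell in enumerate(col):
            cell = cell.strip()
            if cell in _MISSING_GENO:
                continue
            if cell not in ("0", "1", "2"):
                raise ValidationError(
                    f"{path}: line {i + 2}: invalid genotype code {cell!r} (expected 0/1/2 or missing)"
                )
            arr[i, j] = int(cell)
    return GenotypeMatrix(values=pd.DataFrame(arr, index=raw.index, columns=raw.columns))


def write_genotypes_tsv(geno: GenotypeMatrix, path) -> None:
    out = geno.values.astype(object).where(geno.values >= 0, ".")
    out.to_csv(path, sep="\t", index_label="snp_id")


def read_vcf(path) -> GenotypeMatrix:
    """Minimal VCF reader (diploid GT field) built on cyvcf2.

    './.' is treated as missing; multi-allelic sites are skipped with a
    warning. Dosages count ALT alleles.
    """
    from cyvcf2 import VCF  # optional dependency, imported lazily

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    snp_ids, rows, chroms, poss = [], [], [], []
    # cyvcf2 gt_types: 0=hom-ref, 1=het, 2=unknown, 3=hom-alt
    code = {0: 0, 1: 1, 3: 2, 2: -1}
    for var in vcf:
        if len(var.ALT) != 1:
            log.warning("%s: skipping multi-allelic site %s:%d", path, var.CHROM, var.POS)
            continue
        snp_ids.append(var.ID or f"{var.CHROM}:{var.POS}")
        rows.append([code[int(t)] for t in var.gt_types])
        chroms.append(var.CHROM)
        poss.append(var.POS)
    values = pd.DataFrame(np.asarray(rows, dtype=np.int8).reshape(len(snp_ids), len(samples)),
                          index=pd.Index(snp_ids, name="snp_id"), columns=samples)
    positions = pd.DataFrame({"chrom": chroms, "pos": poss}, index=values.index)
    return GenotypeMatrix(values=values, positions=positions)


_VCF_GT = {0: "0/0", 1: "0/1", 2: "1/1", -1: "./."}


def write_vcf(geno: GenotypeMatrix, path) -> None:
    """Write dosages as a minimal diploid VCF (GT field only)."""
    samples = list(geno.samples)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        chroms = (geno.positions["chrom"] if geno.positions is not None
                  else pd.Series("1", index=geno.snps))
        for chrom in dict.fromkeys(chroms):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples) + "\n")
        for i, snp in enumerate(geno.snps):
            if geno.positions is not None:
                chrom, pos = geno.positions.loc[snp, "chrom"], int(geno.positions.loc[snp, "pos"])
            else:
                chrom, pos = "1", i + 1
            gts = "\t".join(_VCF_GT[int(g)] for g in geno.values.loc[snp])
            fh.write(f"{chrom}\t{pos}\t{snp}\tA\tG\t.\t.\t.\tGT\t{gts}\n")


def write_dv_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index_label="gene_id")


def write_dispersion_results(results, path) -> None:
    """Dispersion-scan results as TSV, one row per gene set."""
    rows = []
    for r in results:
        top = ",".join(f"{g}:{share:.4f}" for g, share in r.contributions[:5])
        rows.append({
            "set_name": r.set_name,
            "n_genes_used": r.n_genes_used,
            "n_genes_total": r.n_genes_total,
            "f_statistic": r.f_statistic,
            "p_value": r.p_value,
            "direction": r.direction,
            "top_genes": top,
        })
    cols = ["set_name", "n_genes_used", "n_genes_total", "f_statistic", "p_value", "direction", "top_genes"]
    pd.DataFrame(rows, columns=cols).to_csv(path, sep="\t", index=False)
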