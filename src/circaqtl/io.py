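"""Readers and writers for the pipeline's on-disk formats.

Genotypes travel as VCF v4.2 (single-ALT records with GT, an INFO_SCORE
info field) or as a TSV dosage matrix (samples x variants); traces,
phenotypes, hairpin screens and timecourses are long-format TSV.
VCF reading goes through cyvcf2; writing emits plain-text VCF directly
(records are simple biallelic GT lines).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .synthetic import BioluminescenceTrace, GenotypeMatrix

_GT_CODE = {0: "0/0", 1: "0/1", 2: "1/1"}


def write_vcf(genotypes: GenotypeMatrix, path) -> None:
    path = Path(path)
    lines = [
        "##fileformat=VCFv4.2",
        '##INFO=<ID=INFO_SCORE,Number=1,Type=Float,Description="Imputation info score">',
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(genotypes.samples),
    ]
    for j, var in genotypes.variants.iterrows():
        gts = []
        for d in genotypes.dosages[:, j]:
            gts.append("./." if np.isnan(d) else _GT_CODE[int(round(d))])
        lines.append(
            f"{var['chrom']}\t{int(var['pos'])}\t{var['snp_id']}\t{var['ref']}\t"
            f"{var['alt']}\t.\tPASS\tINFO_SCORE={var.get('info_score', 1.0):.4f}\tGT\t"
            + "\t".join(gts)
        )
    path.write_text("\n".join(lines) + "\n")


def read_vcf(path) -> GenotypeMatrix:
    """Read a VCF (v4.2, GT field, one ALT per record) via cyvcf2."""
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    rows, dosages = [], []
    for rec in vcf:
        if len(rec.ALT) != 1:
            raise ValueError(f"record {rec.ID}: expected exactly one ALT allele")
        info = rec.INFO.get("INFO_SCORE", 1.0)
        rows.append((rec.CHROM, rec.POS, rec.ID or f"{rec.CHROM}:{rec.POS}",
                     rec.REF, rec.ALT[0], float(info)))
        gt = np.asarray(rec.genotypes, dtype=float)[:, :2]
        gt[gt < 0] = np.nan
        dosages.append(gt.sum(axis=1))
    variants = pd.DataFrame(
        rows, columns=["chrom", "pos", "snp_id", "ref", "alt", "info_score"]
    )
    dos = np.array(dosages).T if dosages else np.empty((len(samples), 0))
    return GenotypeMatrix(samples, variants, dos)


def write_dosage_tsv(genotypes: GenotypeMatrix, path) -> None:
    frame = genotypes.dosage_frame()
    frame.index.name = "sample_id"
    frame.to_csv(path, sep="\t", na_rep="NA")


def read_dosage_tsv(path, variants: pd.DataFrame | None = None) -> GenotypeMatrix:
    frame = pd.read_csv(path, sep="\t", index_col="sample_id", na_values="NA")
    samples = list(frame.index.astype(str))
    snp_ids = list(frame.columns)
    if variants is None:
        variants = pd.DataFrame(
            {
                "chrom": ["1"] * len(snp_ids),
                "pos": np.arange(1, len(snp_ids) + 1),
                "snp_id": snp_ids,
                "ref": ["A"] * len(snp_ids),
                "alt": ["G"] * len(snp_ids),
                "info_score": np.ones(len(snp_ids)),
            }
        )
    return GenotypeMatrix(samples, variants, frame.to_numpy(dtype=float))


def write_traces_tsv(traces: list[BioluminescenceTrace], path) -> None:
    frames = [
        pd.DataFrame(
            {
                "line_id": tr.line_id,
                "replicate_id": tr.replicate_id,
                "time_h": tr.time_h,
                "signal": tr.signal,
            }
        )
        for tr in traces
    ]
    pd.concat(frames, ignore_index=True).to_csv(path, sep="\t", index=False)


def read_traces_tsv(path) -> list[BioluminescenceTrace]:
    table = pd.read_csv(path, sep="\t")
    traces = []
    for (line, rep), sub in table.groupby(["line_id", "replicate_id"], sort=False):
        sub = sub.sort_values("time_h")
        traces.append(
            BioluminescenceTrace(str(line), str(rep),
                                 sub["time_h"].to_numpy(), sub["signal"].to_numpy())
        )
    return traces


def write_tsv(frame: pd.DataFrame, path, index: bool = False) -> None:
    frame.to_csv(path, sep="\t", index=index)


def read_tsv(path, **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", **kwargs)


def write_bed6(genes: pd.DataFrame, path) -> None:
    """Write gene annotations (chrom, start, end, gene_id, score, strand)
    as BED6 (0-based half-open)."""
    cols = ["chrom", "start", "end", "gene_id", "score", "strand"]
    genes[cols].to_csv(path, sep="\t", index=False, header=False)
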