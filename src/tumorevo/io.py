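"""Readers and writers for the tabular interchange formats.

Dialects: MAF-style variant TSV (1-based inclusive coordinates), minimal
per-caller VCF (via cyvcf2; 1-based on ingest), SEG-style copy-number TSV,
tidy clonotype / neoantigen / RNA-support TSVs, gene-by-sample expression
TSV, GMT gene-set definitions, and Newick trees.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from skbio import TreeNode

from .filtering import CohortVariantTable
from .immuno import GeneSignature
from .phylogeny import ClonePrevalenceMatrix, DistanceMatrix, PhyloTree, newick_string

log = logging.getLogger("tumorevo")

__all__ = [
    "SchemaError",
    "MAF_REQUIRED_COLUMNS",
    "read_maf_table",
    "write_maf_table",
    "read_samples_table",
    "write_samples_table",
    "read_seg",
    "write_seg",
    "read_vcf_calls",
    "read_repertoire",
    "read_neoantigens",
    "read_rna_support",
    "read_expression",
    "write_matrix",
    "read_gmt",
    "write_gmt",
    "write_newick",
    "read_newick",
    "write_cp_matrix",
    "read_cp_matrix",
    "write_distance_matrix",
]


class SchemaError(ValueError):
    """An input file is missing a required column."""


MAF_REQUIRED_COLUMNS = (
    "Hugo_Symbol",
    "Chromosome",
    "Start_Position",
    "Reference_Allele",
    "Tumor_Seq_Allele2",
    "Tumor_Sample_Barcode",
    "t_alt_count",
    "t_ref_count",
    "IMPACT",
)

_MAF_TO_INTERNAL = {
    "Hugo_Symbol": "gene",
    "Chromosome": "chrom",
    "Start_Position": "pos",
    "Reference_Allele": "ref",
    "Tumor_Seq_Allele2": "alt",
    "Tumor_Sample_Barcode": "sample_id",
    "t_alt_count": "alt_count",
    "t_ref_count": "ref_count",
    "IMPACT": "impact",
}


def _require(df: pd.DataFrame, columns: Sequence[str], path) -> None:
    for c in columns:
        if c not in df.columns:
            raise SchemaError(f"{path}: missing required column {c!r}")


def read_maf_table(
    path, samples: pd.DataFrame | None = None, callers: Sequence[str] | None = None
) -> CohortVariantTable:
    """Read a MAF-style TSV into a cohort variant table.

    Coordinates are 1-based inclusive and preserved as-is. Per-caller PASS
    flags are read from boolean ``PASS_<caller>`` columns (all detected
    columns unless ``callers`` is given). Rows with missing read counts
    are skipped with a warning; extra columns are ignored. ``samples``
    carries phase and purity per sample; without it every sample defaults
    to phase 'post' and purity 1.0.
    """
    df = pd.read_csv(path, sep="\t", comment="#")
    _require(df, MAF_REQUIRED_COLUMNS, path)
    if callers is None:
        callers = tuple(
            c[len("PASS_"):] for c in df.columns if c.startswith("PASS_")
        )
    if not callers:
        raise SchemaError(f"{path}: no PASS_<caller> columns found")
    bad = df["t_alt_count"].isna() | df["t_ref_count"].isna()
    if bad.any():
        log.warning("%s: skipping %d rows with missing read counts", path, bad.sum())
        df = df.loc[~bad]
    if df.empty:
        log.warning("%s: no usable variant rows (header-only file?)", path)
    obs = df.rename(columns=_MAF_TO_INTERNAL).copy()
    obs["variant_id"] = (
        obs["chrom"].astype(str)
        + ":"
        + obs["pos"].astype(str)
        + ":"
        + obs["ref"].astype(str)
        + ":"
        + obs["alt"].astype(str)
    )
    obs["alt_count"] = obs["alt_count"].astype(int)
    obs["ref_count"] = obs["ref_count"].astype(int)
    for c in callers:
        obs[f"pass_{c}"] = obs[f"PASS_{c}"].astype(bool)
    keep = ["sample_id", "variant_id", "chrom", "pos", "ref", "alt", "gene", "impact",
            "alt_count", "ref_count"] + [f"pass_{c}" for c in callers]
    if "rescued" in obs.columns:
        keep.append("rescued")
    obs = obs[keep]
    if samples is None:
        ids = sorted(obs["sample_id"].unique())
        log.warning("no samples table given: defaulting phase='post', purity=1.0")
        samples = pd.DataFrame(
            {"phase": "post", "purity": 1.0}, index=pd.Index(ids, name="sample_id")
        )
    return CohortVariantTable(
        observations=obs, samples=samples, callers=tuple(callers)
    )


def write_maf_table(table: CohortVariantTable, path) -> None:
    """Write a cohort variant table as MAF-style TSV (1-based inclusive)."""
    inv = {v: k for k, v in _MAF_TO_INTERNAL.items()}
    obs = table.observations.copy()
    out = obs.rename(columns=inv)
    for c in table.callers:
        out[f"PASS_{c}"] = obs[f"pass_{c}"]
    cols = list(MAF_REQUIRED_COLUMNS) + [f"PASS_{c}" for c in table.callers] + ["rescued"]
    out[cols].to_csv(path, sep="\t", index=False)


def read_samples_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    _require(df, ("sample_id", "phase", "purity"), path)
    return df.set_index("sample_id")


def write_samples_table(samples: pd.DataFrame, path) -> None:
    samples.rename_axis("sample_id").reset_index().to_csv(path, sep="\t", index=False)


def read_seg(path) -> pd.DataFrame:
    """SEG-style allele-specific copy-number segments, 1-based inclusive."""
    df = pd.read_csv(path, sep="\t")
    _require(df, ("sample_id", "chrom", "start", "end", "cn_total"), path)
    return df


def write_seg(cn: pd.DataFrame, path) -> None:
    cn.to_csv(path, sep="\t", index=False)


def read_vcf_calls(path, sample_id: str | None = None) -> pd.DataFrame:
    """Minimal single-sample VCF reader for one caller's output.

    Returns a per-caller call table (sample_id, variant_id, chrom, pos,
    ref, alt, alt_count, ref_count, pass) suitable for
    :func:`tumorevo.filtering.merge_caller_calls`. Read counts come from
    the AD FORMAT field of the tumor sample; FILTER PASS (or '.') maps to
    ``pass=True``. VCF positions are 1-based and kept as-is (matching the
    MAF convention for SNVs).
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    vcf_samples = list(vcf.samples)
    if sample_id is None:
        if len(vcf_samples) != 1:
            raise ValueError(f"{path}: specify sample_id among {vcf_samples}")
        sample_id = vcf_samples[0]
    idx = vcf_samples.index(sample_id)
    rows = []
    for rec in vcf:
        for alt in rec.ALT:
            ad = rec.format("AD")
            if ad is None:
                raise SchemaError(f"{path}: AD FORMAT field required for read counts")
            ref_count, alt_count = int(ad[idx][0]), int(ad[idx][1])
            rows.append(
                {
                    "sample_id": sample_id,
                    "variant_id": f"{rec.CHROM}:{rec.POS}:{rec.REF}:{alt}",
                    "chrom": rec.CHROM,
                    "pos": rec.POS,
                    "ref": rec.REF,
                    "alt": alt,
                    "alt_count": alt_count,
                    "ref_count": ref_count,
                    "pass": rec.FILTER is None,
                }
            )
    return pd.DataFrame(rows)


def read_repertoire(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    _require(df, ("sample_id", "chain", "clonotype", "count"), path)
    return df


def read_neoantigens(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    _require(df, ("sample_id", "peptide", "gene", "binding_rank"), path)
    return df


def read_rna_support(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    _require(df, ("sample_id", "variant_id", "supporting_read_count"), path)
    return df


def read_expression(path) -> pd.DataFrame:
    """Gene-by-sample expression TSV, genes in the first column."""
    return pd.read_csv(path, sep="\t", index_col=0)


def write_matrix(df: pd.DataFrame, path, index_label: str | None = None) -> None:
    df.to_csv(path, sep="\t", index_label=index_label)


def read_gmt(path) -> dict[str, GeneSignature]:
    """GMT gene-set file: name <tab> description <tab> gene1 <tab> ..."""
    out: dict[str, GeneSignature] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise SchemaError(f"{path}: GMT lines need name, description, >=1 gene")
        name, _, *genes = parts
        out[name] = GeneSignature(name=name, genes=frozenset(g for g in genes if g))
    return out


def write_gmt(signatures: Mapping[str, Sequence[str]], path) -> None:
    lines = [
        "\t".join([name, "synthetic"] + sorted(genes))
        for name, genes in signatures.items()
    ]
    Path(path).write_text("\n".join(lines) + "\n")


def write_newick(tree: PhyloTree, path, sig_digits: int = 6) -> None:
    """Write standard Newick with branch lengths at ``sig_digits``
    significant digits; re-reading reproduces topology and lengths to the
    printed precision."""
    Path(path).write_text(newick_string(tree, sig_digits))


def read_newick(path) -> PhyloTree:
    root = TreeNode.read(str(path))
    return PhyloTree(root=root)


def write_cp_matrix(cpm: ClonePrevalenceMatrix, path) -> None:
    out = cpm.cp.copy()
    out.insert(0, "n_mutations", cpm.n_mutations)
    out.to_csv(path, sep="\t", index_label="clone_id")


def read_cp_matrix(path) -> ClonePrevalenceMatrix:
    df = pd.read_csv(path, sep="\t", index_col="clone_id")
    _require(df.reset_index(), ("clone_id", "n_mutations"), path)
    n_mut = df.pop("n_mutations")
    return ClonePrevalenceMatrix(cp=df, n_mutations=n_mut)


def write_distance_matrix(d: DistanceMatrix, path) -> None:
    d.to_frame().to_csv(path, sep="\t", index_label="sample_id")
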