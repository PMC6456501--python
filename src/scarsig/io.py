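"""Readers and writers for the pipeline's tabular formats.

Variant positions are 1-based (VCF convention); interval files (segments,
regions) are 0-based half-open (BED convention). Catalog TSVs have the 96
channel labels as first column, in canonical order, and one column per sample.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .catalog import CHANNELS

__all__ = [
    "read_variant_table",
    "read_vcf_variants",
    "write_minimal_vcf",
    "read_catalog",
    "write_catalog",
    "read_signature_matrix",
    "read_cutoffs",
    "read_segments",
    "read_snps",
    "read_regions_bed",
]

_VARIANT_COLUMNS = [
    "sample", "chrom", "pos", "ref", "alt",
    "tumor_ref_reads", "tumor_alt_reads", "control_ref_reads", "control_alt_reads",
]


def read_vcf_variants(path, sample: str | None = None) -> pd.DataFrame:
    """Read SNVs from a (possibly minimal) VCF via pysam.

    Expects an AD FORMAT field; the first VCF sample is the tumor, the second
    (when present) the control. Non-SNV records are skipped.
    """
    import pysam

    rows = []
    with pysam.VariantFile(str(path)) as vcf:
        vcf_samples = list(vcf.header.samples)
        for rec in vcf:
            if rec.alts is None or len(rec.ref) != 1:
                continue
            for alt in rec.alts:
                if len(alt) != 1:
                    continue
                row = {
                    "sample": sample or (vcf_samples[0] if vcf_samples else "sample"),
                    "chrom": rec.chrom,
                    "pos": rec.pos,
                    "ref": rec.ref,
                    "alt": alt,
                }
                for role, vcf_sample in zip(("tumor", "control"), vcf_samples):
                    ad = rec.samples[vcf_sample].get("AD")
                    if ad is not None and len(ad) >= 2:
                        row[f"{role}_ref_reads"], row[f"{role}_alt_reads"] = ad[0], ad[1]
                rows.append(row)
    return pd.DataFrame(rows)


def read_variant_table(path, sample: str | None = None) -> pd.DataFrame:
    """Read a variant table from VCF or TSV, sniffed by extension."""
    path = Path(path)
    if path.suffix.lower() in (".vcf", ".gz", ".bcf"):
        return read_vcf_variants(path, sample=sample)
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    if sample is not None:
        df["sample"] = sample
    return df


def write_minimal_vcf(records: pd.DataFrame, path, contigs=None) -> None:
    """Write variant records as a minimal VCF 4.2 with tumor/control AD fields."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">\n')
        if contigs:
            for name, length in contigs:
                fh.write(f"##contig=<ID={name},length={length}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tTUMOR\tCONTROL\n")
        for r in records.sort_values(["chrom", "pos"]).itertuples():
            t_ad = f"{int(r.tumor_ref_reads)},{int(r.tumor_alt_reads)}"
            c_ad = f"{int(r.control_ref_reads)},{int(r.control_alt_reads)}"
            fh.write(
                f"{r.chrom}\t{r.pos}\t.\t{r.ref}\t{r.alt}\t.\tPASS\t.\tAD\t{t_ad}\t{c_ad}\n"
            )


def read_catalog(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    missing = set(CHANNELS) - set(df.index)
    if missing:
        raise ValueError(f"catalog missing {len(missing)} channels")
    return df.reindex(list(CHANNELS))


def write_catalog(catalog: pd.DataFrame, path) -> None:
    catalog.rename_axis("channel").to_csv(path, sep="\t")


def read_signature_matrix(path) -> pd.DataFrame:
    """Signature TSV: channels x signatures, header row of signature ids."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    df = df.reindex(list(CHANNELS))
    if df.isna().any().any():
        raise ValueError("signature matrix does not cover the 96 canonical channels")
    sums = df.sum(axis=0)
    if ((sums - 1).abs() > 1e-6).any():
        df = df / sums
    return df


def read_cutoffs(path) -> pd.Series:
    df = pd.read_csv(path, sep="\t")
    cut = pd.Series(df.cutoff.to_numpy(dtype=float), index=df.signature, name="cutoff")
    if ((cut < 0) | (cut > 1)).any():
        raise ValueError("cutoffs must lie in [0, 1]")
    return cut


def read_segments(path) -> pd.DataFrame:
    """Segment TSV/BED: chrom, start, end (0-based half-open) plus data columns."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    for col in ("chrom", "start", "end"):
        if col not in df.columns:
            raise ValueError(f"segment table missing column {col!r}")
    return df


def read_snps(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"chrom": str})


def read_regions_bed(path) -> list[tuple[str, int, int]]:
    """Read a headerless BED3 into (chrom, start, end) tuples."""
    df = pd.read_csv(path, sep="\t", header=None, usecols=[0, 1, 2],
                     names=["chrom", "start", "end"], dtype={"chrom": str},
                     comment="#")
    return [(r.chrom, int(r.start), int(r.end)) for r in df.itertuples()]
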