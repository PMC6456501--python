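"""HR-gene inactivation events and the paired-biopsy variant look-up.

The biallelic-event classifier reproduces the zygosity taxonomy used to call
homologous-recombination gene inactivation: a (likely) pathogenic germline
variant (ACMG class 4-5) plus a somatic second hit (deletion of the wild-type
allele, copy-neutral LOH, or a somatic point mutation) is
``biallelic-germline-somatic``; two somatic hits make ``biallelic-somatic``;
a single hit is ``monoallelic``. ACMG classes are consumed as input labels,
never computed here.

The look-up compares the variant sets of two biopsies of the same tumor:
variant keys are merged, rows with coverage below 20x in either sample or
flagged germline are dropped, and the remainder is partitioned into shared
and private sets by alternative-read support.
"""

from __future__ import annotations

import importlib.resources
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from statsmodels.stats.proportion import proportions_ztest

logger = logging.getLogger(__name__)

__all__ = [
    "load_hr_panel",
    "default_hr_panel",
    "classify_biallelic",
    "compare_germline_tumor_af",
    "lookup_paired_variants",
    "count_coding_nonsyn",
    "HRGeneEvent",
    "LookupResult",
]

MIN_LOOKUP_COVERAGE = 20
MIN_SHARED_ALT_READS = 2


# ---------------------------------------------------------------------------
# panel

def load_hr_panel(path) -> pd.DataFrame:
    """Load an HR-gene panel TSV (columns gene, source) with duplicate checking."""
    df = pd.read_csv(path, sep="\t")
    if len(df) == 0:
        raise ValueError("empty HR panel file")
    dupes = df.gene[df.gene.duplicated()].tolist()
    if dupes:
        raise ValueError(f"duplicate genes in panel: {dupes}")
    return df.reset_index(drop=True)


def default_hr_panel() -> pd.DataFrame:
    """The packaged 23-gene candidate panel: a 12-gene PARP-inhibitor
    biomarker set plus 11 additional DNA-repair genes (user-editable)."""
    ref = importlib.resources.files("scarsig.data").joinpath("hr_panel.tsv")
    with importlib.resources.as_file(ref) as path:
        return load_hr_panel(path)


# ---------------------------------------------------------------------------
# biallelic classification

@dataclass(frozen=True)
class HRGeneEvent:
    gene: str
    zygosity: str  # biallelic-germline-somatic | biallelic-somatic | monoallelic | none
    germline_class: int | None = None
    somatic_cn_state: str = "none"  # wt_deletion | cn_loh | none
    somatic_snv: bool = False
    af_direction: str | None = None
    inconsistent: bool = False
    notes: str = ""


def classify_biallelic(
    gene: str,
    germline_class: int | None = None,
    somatic_cn_state: str = "none",
    somatic_snv: bool = False,
    retained_het_snps: bool = False,
) -> HRGeneEvent:
    """Zygosity call for one HR-gene locus.

    ``somatic_cn_state`` is the somatic copy-number state of the locus:
    ``wt_deletion`` (loss of the wild-type allele), ``cn_loh`` (copy-neutral
    LOH) or ``none``. A biallelic deletion combined with retained het SNPs at
    the locus is contradictory and flagged inconsistent.
    """
    if germline_class is not None and not 1 <= germline_class <= 5:
        raise ValueError("ACMG class must lie in 1..5")
    if somatic_cn_state not in ("wt_deletion", "cn_loh", "none"):
        raise ValueError(f"unknown somatic CN state {somatic_cn_state!r}")
    inconsistent = retained_het_snps and somatic_cn_state in ("wt_deletion", "cn_loh")
    germ_path = germline_class is not None and germline_class >= 4
    somatic_hits = int(somatic_cn_state != "none") + int(somatic_snv)
    if germ_path and somatic_hits >= 1:
        zyg = "biallelic-germline-somatic"
    elif somatic_hits >= 2:
        zyg = "biallelic-somatic"
    elif germ_path or somatic_hits == 1:
        zyg = "monoallelic"
    else:
        zyg = "none"
    return HRGeneEvent(
        gene=gene,
        zygosity=zyg,
        germline_class=germline_class,
        somatic_cn_state=somatic_cn_state,
        somatic_snv=somatic_snv,
        inconsistent=inconsistent,
        notes="biallelic CN loss with retained het SNPs" if inconsistent else "",
    )


def classify_cohort(germline: pd.DataFrame, somatic: pd.DataFrame, panel=None) -> pd.DataFrame:
    """Classify every panel gene from generator-style germline/somatic tables."""
    if panel is None:
        panel = somatic.gene.tolist()
    germ_by_gene = {r.gene: r for r in germline.itertuples()} if len(germline) else {}
    rows = []
    for r in somatic.itertuples():
        if r.gene not in panel:
            continue
        if (r.cn_a, r.cn_b) == (0, 1):
            cn_state = "wt_deletion"
        elif r.cn_a == 0 and r.cn_b >= 2:
            cn_state = "cn_loh"
        else:
            cn_state = "none"
        germ = germ_by_gene.get(r.gene)
        event = classify_biallelic(
            r.gene,
            germline_class=int(germ.acmg_class) if germ is not None else None,
            somatic_cn_state=cn_state,
            somatic_snv=bool(r.somatic_snv),
        )
        rows.append(
            {
                "gene": event.gene,
                "zygosity": event.zygosity,
                "germline_class": event.germline_class,
                "somatic_cn_state": event.somatic_cn_state,
                "somatic_snv": event.somatic_snv,
            }
        )
    return pd.DataFrame(rows)


def compare_germline_tumor_af(
    tumor_alt: int,
    tumor_depth: int,
    control_alt: int,
    control_depth: int,
    alpha: float = 0.05,
    min_coverage: int = MIN_LOOKUP_COVERAGE,
) -> str:
    """Compare a germline variant's allele fraction in tumor vs control.

    A two-proportion z-test at the 5% level decides whether the tumor allele
    fraction is ``enriched`` (supporting loss of the wild-type allele),
    ``depleted``, or ``unchanged``. Returns ``indeterminate`` when either
    sample has coverage below 20x.
    """
    if tumor_depth < min_coverage or control_depth < min_coverage:
        return "indeterminate"
    if tumor_alt == control_alt and tumor_depth == control_depth:
        return "unchanged"
    stat, p = proportions_ztest(
        [tumor_alt, control_alt], [tumor_depth, control_depth]
    )
    if p >= alpha or np.isnan(p):
        return "unchanged"
    return "enriched" if tumor_alt / tumor_depth > control_alt / control_depth else "depleted"


# ---------------------------------------------------------------------------
# paired-biopsy look-up

@dataclass
class LookupResult:
    """Merged paired-biopsy variant table with shared/private classification."""

    table: pd.DataFrame  # key cols, counts and VAFs per sample, class
    n_shared: int
    n_private_a: int
    n_private_b: int
    n_dropped_coverage: int
    n_dropped_germline: int
    summary: dict = field(init=False)

    def __post_init__(self) -> None:
        self.summary = {
            "shared": self.n_shared,
            "private-A": self.n_private_a,
            "private-B": self.n_private_b,
            "dropped_coverage": self.n_dropped_coverage,
            "dropped_germline": self.n_dropped_germline,
        }


_KEY = ["chrom", "pos", "ref", "alt"]


def lookup_paired_variants(
    table_a: pd.DataFrame,
    table_b: pd.DataFrame,
    min_coverage: int = MIN_LOOKUP_COVERAGE,
    min_alt_reads: int = MIN_SHARED_ALT_READS,
) -> LookupResult:
    """Merge the variant sets of two biopsies and classify shared/private calls.

    Keys are (chrom, pos, ref, alt). Rows with coverage below ``min_coverage``
    in either sample are dropped, as are germline-flagged rows
    (``origin == 'germline'`` in either table). A retained row is ``shared``
    when both samples have at least ``min_alt_reads`` alternative reads,
    otherwise private to the supporting sample (falling back to the sample
    with more alternative reads). The returned table carries paired VAFs,
    ready for a scatter display.
    """
    for name, tbl in (("A", table_a), ("B", table_b)):
        if tbl.duplicated(_KEY).any():
            raise ValueError(f"duplicate variant keys in table {name}")
    a = table_a.set_index(_KEY)
    b = table_b.set_index(_KEY)
    merged = a.join(b, how="outer", lsuffix="_a", rsuffix="_b")

    def col(side, name):
        c = f"{name}_{side}"
        return merged[c] if c in merged else merged[name]

    depth_a = (col("a", "ref_reads") + col("a", "alt_reads")).fillna(0)
    depth_b = (col("b", "ref_reads") + col("b", "alt_reads")).fillna(0)
    alt_a = col("a", "alt_reads").fillna(0)
    alt_b = col("b", "alt_reads").fillna(0)
    germline = pd.Series(False, index=merged.index)
    for side in ("a", "b"):
        c = f"origin_{side}"
        if c in merged:
            germline |= merged[c].fillna("") == "germline"
        elif "origin" in merged:
            germline |= merged["origin"].fillna("") == "germline"
    low_cov = (depth_a < min_coverage) | (depth_b < min_coverage)
    keep = ~low_cov & ~germline
    n_drop_cov = int(low_cov.sum())
    n_drop_germ = int((germline & ~low_cov).sum())

    sup_a = alt_a >= min_alt_reads
    sup_b = alt_b >= min_alt_reads
    cls = np.where(
        sup_a & sup_b,
        "shared",
        np.where(
            sup_a,
            "private-A",
            np.where(sup_b, "private-B", np.where(alt_a >= alt_b, "private-A", "private-B")),
        ),
    )
    out = merged[keep].reset_index()[_KEY].copy()
    out["alt_reads_a"] = alt_a[keep].to_numpy()
    out["alt_reads_b"] = alt_b[keep].to_numpy()
    out["depth_a"] = depth_a[keep].to_numpy()
    out["depth_b"] = depth_b[keep].to_numpy()
    out["vaf_a"] = out.alt_reads_a / out.depth_a
    out["vaf_b"] = out.alt_reads_b / out.depth_b
    out["class"] = cls[keep.to_numpy()]
    return LookupResult(
        table=out,
        n_shared=int((out["class"] == "shared").sum()),
        n_private_a=int((out["class"] == "private-A").sum()),
        n_private_b=int((out["class"] == "private-B").sum()),
        n_dropped_coverage=n_drop_cov,
        n_dropped_germline=n_drop_germ,
    )


# ---------------------------------------------------------------------------
# coding-mutation counting

NONSYN_SNV_CLASSES = {"nonsynonymous-SNV", "stopgain-SNV", "stoploss-SNV"}
CODING_INDEL_CLASSES = {"frameshift-indel", "nonframeshift-indel", "splice-indel"}


def count_coding_nonsyn(variants: pd.DataFrame) -> tuple[int, int]:
    """Count non-synonymous coding SNVs and coding/splice-site indels.

    Records without an effect class are excluded with a logged count;
    annotation itself is an upstream task.
    """
    if "effect" not in variants.columns:
        raise ValueError("variant table lacks an 'effect' column")
    effect = variants.effect
    unannotated = effect.isna() | (effect == "")
    if unannotated.any():
        logger.warning("count_coding_nonsyn: %d unannotated records excluded",
                       int(unannotated.sum()))
    annotated = variants[~unannotated]
    n_snv = int(annotated.effect.isin(NONSYN_SNV_CLASSES).sum())
    n_indel = int(annotated.effect.isin(CODING_INDEL_CLASSES).sum())
    return n_snv, n_indel
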