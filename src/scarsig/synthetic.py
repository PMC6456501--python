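"""Synthetic cohort generator.

Emulates every input the pipeline consumes: 96-channel catalogs drawn from
known signature mixtures at chordoma-like burdens, segmented tumor genomes
with known tumor-cell-content (TCC) / ploidy / LOH structure and binomial
B-allele-frequency noise, paired tumor biopsies with shared and private
variant sets, and HR-gene germline/somatic event tables. Every generated
object carries its ground-truth parameters so recovery can be tested.

All randomness flows from a single integer seed through
``numpy.random.SeedSequence`` spawns, one stream per sample, so regenerating a
subset reproduces it bit-identically.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .catalog import CHANNELS, channel_to_parts, revcomp
from .genome import GenomeDefinition, toy_genome

__all__ = [
    "CNEvent",
    "SimulationConfig",
    "CNProfile",
    "HRGeneEventSpec",
    "make_signature_matrix",
    "sample_cohort_exposures",
    "simulate_catalog",
    "simulate_mutation_records",
    "simulate_cn_profile",
    "simulate_paired_variant_tables",
    "simulate_hr_gene_cohort",
]


# ---------------------------------------------------------------------------
# configuration

@dataclass(frozen=True)
class CNEvent:
    """A copy-number event: allele-specific state over an interval (0-based half-open)."""

    chrom: str
    start: int
    end: int
    cn_a: int
    cn_b: int

    def __post_init__(self) -> None:
        if self.end <= self.start or self.start < 0:
            raise ValueError(f"bad event interval {self.chrom}:{self.start}-{self.end}")
        if min(self.cn_a, self.cn_b) < 0 or self.cn_a + self.cn_b < 1:
            raise ValueError("event copy numbers must be >= 0 with total >= 1")


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic cohort.

    Burdens default to the modest range seen in chordoma exomes (tens to a few
    hundred SNVs per sample). Mixing weights of the active signatures are
    drawn from the given relative ranges and renormalised to sum to one, so
    per-sample burdens are exact and the recorded truth is the normalised
    weight vector.
    """

    seed: int = 0
    n_samples: int = 11
    burden_range: tuple[int, int] = (40, 500)
    active_signatures: dict = field(default_factory=dict)  # sig id -> (lo, hi) in [0,1]
    tcc: float = 0.6
    ploidy: float = 2.0
    cn_events: tuple = ()
    snp_density_per_mbp: float = 5.0
    depth: int = 100
    ratio_noise_sd: float = 0.02
    baf_noise: bool = True  # False: emit exact expected allele fractions
    hom_snp_fraction: float = 0.1
    n_shared: int = 10
    n_private_a: int = 5
    n_private_b: int = 3
    n_low_coverage: int = 0
    n_germline: int = 0

    def __post_init__(self) -> None:
        if not 0.15 <= self.tcc <= 1.0:
            raise ValueError("tcc must lie in [0.15, 1.0]")
        if not 1.0 <= self.ploidy <= 6.5:
            raise ValueError("ploidy must lie in [1.0, 6.5]")
        hi_sum = sum(hi for _, hi in self.active_signatures.values())
        if hi_sum > 1 + 1e-9:
            raise ValueError("relative exposure upper bounds of active signatures exceed 1")


# ---------------------------------------------------------------------------
# signatures and catalogs

def make_signature_matrix(
    k: int,
    concentration: float = 0.3,
    seed: int = 0,
    n_channels: int = 96,
    ids=None,
) -> pd.DataFrame:
    """Draw a channels x K signature matrix with Dirichlet columns.

    A symmetric Dirichlet with small concentration gives peaked, signature-like
    columns; large concentration gives flat ones. Columns are probability
    vectors over the canonical channel order.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if concentration <= 0:
        raise ValueError("concentration must be > 0")
    rng = np.random.default_rng(seed)
    cols = rng.dirichlet(np.full(n_channels, concentration), size=k).T
    if ids is None:
        ids = [f"S{i + 1}" for i in range(k)]
    index = list(CHANNELS) if n_channels == 96 else list(range(n_channels))
    return pd.DataFrame(cols, index=index, columns=list(ids))


def sample_cohort_exposures(config: SimulationConfig, signature_ids, rng=None) -> pd.DataFrame:
    """Draw per-sample absolute exposures (signatures x samples) from the config.

    Active-signature weights are drawn uniformly from their configured
    relative ranges, renormalised to sum to one, and scaled by a burden drawn
    uniformly from ``burden_range``.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    signature_ids = list(signature_ids)
    unknown = set(config.active_signatures) - set(signature_ids)
    if unknown:
        raise ValueError(f"active signatures not in matrix: {sorted(unknown)}")
    streams = [np.random.default_rng(s) for s in np.random.SeedSequence(
        entropy=int(rng.integers(2**31))).spawn(config.n_samples)]
    samples = [f"sample_{i + 1:02d}" for i in range(config.n_samples)]
    H = np.zeros((len(signature_ids), config.n_samples))
    for j, srng in enumerate(streams):
        n = int(srng.integers(config.burden_range[0], config.burden_range[1] + 1))
        weights = np.zeros(len(signature_ids))
        for sig, (lo, hi) in config.active_signatures.items():
            weights[signature_ids.index(sig)] = srng.uniform(lo, hi)
        total = weights.sum()
        if total <= 0:
            raise ValueError("no active signature weight drawn > 0")
        H[:, j] = weights / total * n
    return pd.DataFrame(H, index=signature_ids, columns=samples)


def simulate_catalog(W: pd.DataFrame, exposures: pd.DataFrame, seed: int = 0) -> pd.DataFrame:
    """Draw a mutational catalog from signature mixtures.

    Each sample's column is a multinomial draw of ``N = round(sum exposures)``
    mutations from the mixture ``W h / |W h|_1``; column sums equal N exactly.
    """
    W_arr = W.to_numpy(dtype=float)
    out = np.zeros((W_arr.shape[0], exposures.shape[1]), dtype=float)
    streams = np.random.SeedSequence(entropy=seed).spawn(exposures.shape[1])
    for j, ss in enumerate(streams):
        h = exposures.iloc[:, j].to_numpy(dtype=float)
        if (h < 0).any():
            raise ValueError("exposures must be non-negative")
        n = int(round(h.sum()))
        if n == 0:
            warnings.warn(f"all-zero exposure vector for sample {exposures.columns[j]}")
            continue
        mix = W_arr @ h
        mix = mix / mix.sum()
        out[:, j] = np.random.default_rng(ss).multinomial(n, mix)
    return pd.DataFrame(out, index=W.index, columns=exposures.columns)


def simulate_mutation_records(
    catalog: pd.DataFrame, genome: GenomeDefinition | None = None, seed: int = 0
) -> pd.DataFrame:
    """Expand a catalog into per-mutation records (chrom, pos, ref, alt, context).

    Each record is emitted on a random strand: half are written in the
    purine frame (reverse-complemented ref/alt/context), so rebuilding the
    catalog exercises strand collapsing. Positions are uniform over
    length-weighted chromosomes; the genome supplies coordinates only, the
    context comes from the channel.
    """
    if genome is None:
        genome = toy_genome()
    if not genome.chromosomes:
        raise ValueError("genome must contain at least one chromosome")
    rng = np.random.default_rng(seed)
    lengths = np.array([c.length for c in genome.chromosomes], dtype=float)
    probs = lengths / lengths.sum()
    rows = []
    for sample in catalog.columns:
        for label, count in catalog[sample].items():
            ref, alt, triplet = channel_to_parts(str(label))
            for _ in range(int(round(count))):
                ci = rng.choice(len(lengths), p=probs)
                chrom = genome.chromosomes[ci]
                pos = int(rng.integers(2, chrom.length))  # keeps both flanks inside
                r, a, ctx = ref, alt, triplet
                if rng.random() < 0.5:  # purine-frame encoding
                    comp = str.maketrans("ACGT", "TGCA")
                    r, a, ctx = r.translate(comp), a.translate(comp), revcomp(ctx)
                rows.append(
                    {
                        "sample": sample,
                        "chrom": chrom.name,
                        "pos": pos,
                        "ref": r,
                        "alt": a,
                        "context": ctx,
                        "tumor_ref_reads": 60,
                        "tumor_alt_reads": 40,
                        "control_ref_reads": 100,
                        "control_alt_reads": 0,
                        "effect": "nonsynonymous-SNV",
                        "origin": "somatic",
                    }
                )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# copy-number profiles

def _expected_baf(cn_allele: float, tcn: float, tcc: float) -> float:
    return (tcc * cn_allele + (1 - tcc)) / (tcc * tcn + 2 * (1 - tcc))


@dataclass
class CNProfile:
    """Simulated allele-specific copy-number profile with ground truth."""

    segments: pd.DataFrame  # chrom,start,end,ratio,true_cn_a,true_cn_b,true_tcn
    snps: pd.DataFrame  # chrom,pos,control_aaf,tumor_alt_reads,tumor_ref_reads,tumor_depth
    truth: dict


def simulate_cn_profile(
    config: SimulationConfig, genome: GenomeDefinition | None = None
) -> CNProfile:
    """Simulate segment coverage ratios and het-SNP B-allele read counts.

    Per segment the tumor/control coverage ratio is
    ``r = [TCC*TCN + 2(1-TCC)] / [TCC*psi + 2(1-TCC)]`` plus additive Gaussian
    noise; psi is the length-weighted mean tumor copy number of the simulated
    genome. Per het SNP, alt-supporting reads are Binomial(depth, expected
    BAF). True allele-specific copy numbers are recorded for recovery tests.
    """
    if genome is None:
        genome = toy_genome()
    rng = np.random.default_rng(config.seed)
    base_a = int(config.ploidy) // 2
    base_b = int(round(config.ploidy)) - base_a
    if base_a + base_b < 1:
        base_b = 1

    # partition each chromosome into baseline + event segments
    seg_rows = []
    for chrom in genome.chromosomes:
        events = sorted(
            (e for e in config.cn_events if e.chrom == chrom.name), key=lambda e: e.start
        )
        cursor = 0
        for ev in events:
            if ev.end > chrom.length:
                raise ValueError(f"CN event {ev} outside chromosome bounds")
            if ev.start < cursor:
                raise ValueError(f"CN events overlap on {chrom.name}")
            if ev.start > cursor:
                seg_rows.append((chrom.name, cursor, ev.start, base_a, base_b))
            seg_rows.append((chrom.name, ev.start, ev.end, ev.cn_a, ev.cn_b))
            cursor = ev.end
        if cursor < chrom.length:
            seg_rows.append((chrom.name, cursor, chrom.length, base_a, base_b))

    segments = pd.DataFrame(
        seg_rows, columns=["chrom", "start", "end", "true_cn_a", "true_cn_b"]
    )
    segments["true_tcn"] = segments.true_cn_a + segments.true_cn_b
    lengths = (segments.end - segments.start).to_numpy(dtype=float)
    psi = float((segments.true_tcn * lengths).sum() / lengths.sum())
    tcc = config.tcc
    denom = tcc * psi + 2 * (1 - tcc)
    ratio = (tcc * segments.true_tcn + 2 * (1 - tcc)) / denom
    if config.ratio_noise_sd > 0:
        ratio = ratio + rng.normal(0, config.ratio_noise_sd, size=len(ratio))
    segments["ratio"] = ratio.clip(lower=1e-6)

    snp_rows = []
    for seg in segments.itertuples():
        n_snp = rng.poisson(config.snp_density_per_mbp * (seg.end - seg.start) / 1e6)
        if n_snp == 0:
            continue
        pos = np.sort(rng.integers(seg.start + 1, seg.end + 1, size=n_snp))
        tcn = seg.true_tcn
        for p in pos:
            is_hom = config.baf_noise and rng.random() < config.hom_snp_fraction
            if is_hom:
                p_ctrl = 0.995 if rng.random() < 0.5 else 0.005
                p_alt = p_ctrl
            else:
                p_ctrl = 0.5
                cn_alt = seg.true_cn_b if rng.random() < 0.5 else seg.true_cn_a
                p_alt = _expected_baf(cn_alt, tcn, tcc)
            if config.baf_noise:
                ctrl_alt = rng.binomial(config.depth, p_ctrl)
                tum_alt = rng.binomial(config.depth, p_alt)
            else:
                ctrl_alt = config.depth * p_ctrl
                tum_alt = config.depth * p_alt
            snp_rows.append(
                (
                    seg.chrom,
                    int(p),
                    ctrl_alt / config.depth,
                    tum_alt,
                    config.depth - tum_alt,
                    config.depth,
                )
            )
    snps = pd.DataFrame(
        snp_rows,
        columns=[
            "chrom",
            "pos",
            "control_aaf",
            "tumor_alt_reads",
            "tumor_ref_reads",
            "tumor_depth",
        ],
    )
    return CNProfile(segments=segments, snps=snps, truth={"tcc": tcc, "psi": psi})


# ---------------------------------------------------------------------------
# paired biopsies

def simulate_paired_variant_tables(
    config: SimulationConfig, genome: GenomeDefinition | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate look-up-style variant tables for two biopsies of one tumor.

    Both tables carry read counts for every merged variant (emulating a joint
    re-genotyping look-up). Carrier samples get Binomial(depth, VAF) alt reads
    (floored at 2 supporting reads); non-carriers get at most one noise read.
    Optional sub-threshold-coverage rows (19x in one sample) and germline rows
    are injected for filter tests.
    """
    if genome is None:
        genome = toy_genome()
    rng = np.random.default_rng(config.seed)
    chrom = genome.chromosomes[0].name
    total = (
        config.n_shared
        + config.n_private_a
        + config.n_private_b
        + config.n_low_coverage
        + config.n_germline
    )
    positions = rng.choice(
        np.arange(1000, genome.chromosomes[0].length - 1000), size=total, replace=False
    )
    labels = (
        ["shared"] * config.n_shared
        + ["private-A"] * config.n_private_a
        + ["private-B"] * config.n_private_b
        + ["subthreshold"] * config.n_low_coverage
        + ["germline"] * config.n_germline
    )
    bases = "ACGT"
    rows_a, rows_b = [], []
    for pos, label in zip(sorted(positions.tolist()), rng.permutation(labels)):
        ref = bases[rng.integers(4)]
        alt = bases[(bases.index(ref) + 1 + rng.integers(3)) % 4]
        depth_a = depth_b = config.depth
        if label == "germline":
            vaf_a = vaf_b = 0.5
        else:
            vaf = rng.uniform(0.15, 0.5)
            in_a = label in ("shared", "private-A", "subthreshold")
            in_b = label in ("shared", "private-B")
            if label == "subthreshold":
                # low-coverage row: carried by A but failing the 20x rule in B
                in_b = False
                depth_b = 19
            vaf_a = vaf if in_a else 0.0
            vaf_b = vaf if in_b else 0.0
        alt_a = rng.binomial(depth_a, vaf_a) if vaf_a else int(rng.random() < 0.1)
        alt_b = rng.binomial(depth_b, vaf_b) if vaf_b else int(rng.random() < 0.1)
        if vaf_a:
            alt_a = max(alt_a, 2)
        if vaf_b:
            alt_b = max(alt_b, 2)
        common = dict(chrom=chrom, pos=int(pos), ref=ref, alt=alt,
                      origin="germline" if label == "germline" else "somatic",
                      truth_class=label)
        rows_a.append({**common, "ref_reads": depth_a - alt_a, "alt_reads": alt_a,
                       "depth": depth_a})
        rows_b.append({**common, "ref_reads": depth_b - alt_b, "alt_reads": alt_b,
                       "depth": depth_b})
    return pd.DataFrame(rows_a), pd.DataFrame(rows_b)


# ---------------------------------------------------------------------------
# HR-gene cohorts

@dataclass(frozen=True)
class HRGeneEventSpec:
    """Germline/somatic event combination at one HR-gene locus."""

    gene: str
    germline_class: int | None = None  # ACMG class 1-5, None = no germline variant
    germline_variant: str = "frameshift"
    somatic_cn: str = "none"  # wt_deletion | cn_loh | none
    somatic_snv: bool = False


_TRUTH_RULES_DOC = """truth labels follow the biallelic-event taxonomy:
pathogenic germline (class >= 4) + somatic second hit -> biallelic-germline-somatic;
two somatic hits -> biallelic-somatic; one hit -> monoallelic; else none."""


def _truth_label(spec: HRGeneEventSpec) -> str:
    germ_path = spec.germline_class is not None and spec.germline_class >= 4
    somatic_hits = int(spec.somatic_cn != "none") + int(spec.somatic_snv)
    if germ_path and somatic_hits >= 1:
        return "biallelic-germline-somatic"
    if somatic_hits >= 2:
        return "biallelic-somatic"
    if germ_path or somatic_hits == 1:
        return "monoallelic"
    return "none"


def simulate_hr_gene_cohort(
    panel, events, seed: int = 0, depth: int = 100, tcc: float = 0.8
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Emit germline and somatic event tables for an HR-gene panel.

    Germline rows carry ACMG class and tumor/control allele fractions; the
    tumor fraction is enriched when the wild-type allele is somatically lost.
    Somatic rows carry the locus copy-number state and any somatic point
    mutation. Truth labels (see module docs) are recorded per gene.
    """
    panel = list(panel)
    rng = np.random.default_rng(seed)
    by_gene = {}
    for spec in events:
        if spec.gene not in panel:
            raise ValueError(f"unknown gene in event spec: {spec.gene}")
        by_gene[spec.gene] = spec
    germ_rows, som_rows = [], []
    for gene in panel:
        spec = by_gene.get(gene, HRGeneEventSpec(gene))
        truth = _truth_label(spec)
        cn_map = {"wt_deletion": (0, 1), "cn_loh": (0, 2), "none": (1, 1)}
        cn_a, cn_b = cn_map[spec.somatic_cn]
        som_rows.append(
            {
                "gene": gene,
                "cn_a": cn_a,
                "cn_b": cn_b,
                "somatic_snv": spec.somatic_snv,
                "somatic_snv_vaf": round(tcc / 2, 3) if spec.somatic_snv else 0.0,
                "truth_label": truth,
            }
        )
        if spec.germline_class is not None:
            wt_lost = spec.somatic_cn in ("wt_deletion", "cn_loh")
            tumor_vaf = _expected_baf(cn_b, cn_a + cn_b, tcc) if wt_lost else 0.5
            t_alt = int(round(depth * tumor_vaf))
            c_alt = rng.binomial(depth, 0.5)
            germ_rows.append(
                {
                    "gene": gene,
                    "variant": spec.germline_variant,
                    "acmg_class": spec.germline_class,
                    "control_alt_reads": c_alt,
                    "control_depth": depth,
                    "tumor_alt_reads": t_alt,
                    "tumor_depth": depth,
                    "truth_label": truth,
                }
            )
    return pd.DataFrame(germ_rows), pd.DataFrame(som_rows)
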