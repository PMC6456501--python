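"""Tumor cell content, ploidy and allele-specific copy numbers from exome data.

The observed tumor/control coverage ratio of a segment with tumor total copy
number TCN, in a sample with tumor cell content TCC (rho) and tumor ploidy psi, is

    r = [rho*TCN + 2(1 - rho)] / [rho*psi + 2(1 - rho)]

and the major-allele B-allele frequency of an imbalanced segment with allele
copy numbers (CN_A <= CN_B) is

    b = [rho*CN_B + (1 - rho)] / [rho*TCN + 2(1 - rho)].

Fitting inverts these relations on a (TCC, ploidy) grid: per candidate, each
usable segment (>= 20 heterozygous SNPs, not ambiguous) gets real-valued
copy numbers, and the segment-length-weighted mean distance to the nearest
allowed integer state (even TCN for balanced segments, any non-negative
integer allele copy number for imbalanced ones) scores the candidate.
Candidates implying a negative copy number or a decrease of heterozygosity
(DH) above one on any segment are excluded; grid-local minima are returned
ranked by distance. An independent TCC estimate from somatic-SNV allele
fractions on copy-neutral segments is reported alongside, and a manual TCC
override can replace the selected solution.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import find_peaks
from scipy.stats import gaussian_kde

logger = logging.getLogger(__name__)

__all__ = [
    "TCC_RANGE",
    "PLOIDY_RANGE",
    "call_het_snps",
    "classify_segment_balance",
    "segment_mean_baf",
    "invert_mixture",
    "summarize_segments",
    "grid_fit_tcc_ploidy",
    "fit_segments_at",
    "tcc_from_snv_vaf",
    "apply_tcc_override",
    "TCCPloidyFit",
]

TCC_RANGE = (0.15, 1.0)
PLOIDY_RANGE = (1.0, 6.5)
MIN_HET_SNPS = 20


def call_het_snps(snps: pd.DataFrame, lo: float = 0.3, hi: float = 0.7) -> pd.Series:
    """Heterozygous if the control alternative-allele fraction lies in
    [0.3, 0.7] (bounds inclusive). SNPs without a control fraction are
    excluded with a logged count."""
    aaf = snps["control_aaf"]
    missing = aaf.isna()
    if missing.any():
        logger.warning("call_het_snps: %d SNPs lack a control fraction", int(missing.sum()))
    return (aaf >= lo) & (aaf <= hi) & ~missing


def classify_segment_balance(
    tumor_bafs,
    min_snps: int = MIN_HET_SNPS,
    bandwidth: float = 0.03,
    balanced_window: tuple[float, float] = (0.45, 0.55),
    prominence_frac: float = 0.1,
) -> str:
    """Classify a segment from the alt-allele-fraction distribution of its
    het SNPs: 'balanced' if the global density maximum lies within
    [0.45, 0.55]; otherwise 'imbalanced' with two (or more) peaks or
    'ambiguous' with a single off-centre peak. Ambiguous segments are
    excluded downstream; segments with < 20 het SNPs return 'excluded'.
    """
    x = np.asarray(tumor_bafs, dtype=float)
    if x.size < min_snps:
        return "excluded"
    grid = np.linspace(0.0, 1.0, 501)
    sd = x.std()
    if sd < 1e-9:
        peaks_at = np.array([x.mean()])
    else:
        kde = gaussian_kde(x, bw_method=bandwidth / sd)
        dens = kde(grid)
        idx, _ = find_peaks(dens, prominence=prominence_frac * dens.max())
        # an interior monotone maximum at the edge of [0,1] is still a peak
        if dens.argmax() not in idx:
            idx = np.sort(np.append(idx, dens.argmax()))
        peaks_at = grid[idx]
        global_max = grid[dens.argmax()]
        if balanced_window[0] <= global_max <= balanced_window[1]:
            return "balanced"
        return "imbalanced" if len(peaks_at) >= 2 else "ambiguous"
    if balanced_window[0] <= peaks_at[0] <= balanced_window[1]:
        return "balanced"
    return "ambiguous"


def segment_mean_baf(alt_reads, ref_reads) -> float:
    """Mean major-allele fraction over het SNPs: per SNP the allele with the
    higher read count is the B allele; ties contribute 0.5."""
    alt = np.asarray(alt_reads, dtype=float)
    ref = np.asarray(ref_reads, dtype=float)
    if alt.size == 0:
        raise ValueError("no het SNPs")
    total = alt + ref
    with np.errstate(invalid="ignore", divide="ignore"):
        b = np.maximum(alt, ref) / total
    b = np.where(total == 0, 0.5, b)
    return float(np.mean(b))


def invert_mixture(
    r: float, b: float, tcc: float, psi: float, balanced: bool = False
) -> tuple[float, float, float, float]:
    """Invert the coverage/BAF mixture model at one (TCC, ploidy) candidate.

    Returns (TCN, CN_A, CN_B, DH) with CN_A <= CN_B. Balanced segments split
    the total copy number evenly; DH = 1 corresponds to complete loss of
    heterozygosity and DH > 1 is infeasible.
    """
    if not 0 < tcc <= 1 or psi <= 0:
        raise ValueError("tcc must lie in (0, 1], psi > 0")
    tumor_cov = r * (tcc * psi + 2 * (1 - tcc))  # rho*TCN + 2(1-rho)
    tcn = (tumor_cov - 2 * (1 - tcc)) / tcc
    if balanced:
        cn_a = cn_b = tcn / 2
        dh = 0.0
    else:
        cn_b = (b * tumor_cov - (1 - tcc)) / tcc
        cn_a = tcn - cn_b
        dh = (2 * b - 1) * tumor_cov / (tcc * tcn) if tcn > 0 else np.inf
    return tcn, min(cn_a, cn_b), max(cn_a, cn_b), dh


def summarize_segments(
    segments: pd.DataFrame, snps: pd.DataFrame, min_snps: int = MIN_HET_SNPS
) -> pd.DataFrame:
    """Attach het-SNP counts, balance class and mean major-allele BAF to segments.

    ``segments`` needs chrom, start, end, ratio; ``snps`` the SnpRecord
    columns. Segments with fewer than ``min_snps`` het SNPs are classed
    'excluded'; ambiguous and excluded segments carry ``usable = False``.
    """
    het = snps[call_het_snps(snps)]
    out = segments.copy()
    n_het, classes, bafs = [], [], []
    for seg in segments.itertuples():
        mask = (het.chrom == seg.chrom) & (het.pos > seg.start) & (het.pos <= seg.end)
        sub = het[mask]
        n_het.append(len(sub))
        if len(sub) < min_snps:
            classes.append("excluded")
            bafs.append(np.nan)
            continue
        frac = sub.tumor_alt_reads / (sub.tumor_alt_reads + sub.tumor_ref_reads)
        cls = classify_segment_balance(frac.to_numpy(), min_snps=min_snps)
        classes.append(cls)
        bafs.append(
            0.5 if cls == "balanced"
            else segment_mean_baf(sub.tumor_alt_reads, sub.tumor_ref_reads)
        )
    out["n_het_snps"] = n_het
    out["balance_class"] = classes
    out["mean_baf"] = bafs
    out["usable"] = out.balance_class.isin(["balanced", "imbalanced"])
    return out


@dataclass
class TCCPloidyFit:
    """Ranked (TCC, ploidy) candidates with the fitted segment profile."""

    candidates: pd.DataFrame  # tcc, psi, distance, rank
    surface: pd.DataFrame  # full grid: tcc, psi, distance, feasible
    segments: pd.DataFrame  # usable segments fitted at the selected solution
    selected: dict | None
    tcc_snv: float | None = None
    manual_override: bool = False
    diagnostics: dict = field(default_factory=dict)


def _grid_distances(seg: pd.DataFrame, tcc: np.ndarray, psi: np.ndarray):
    """Vectorised distance + feasibility over candidate axes.

    ``tcc``/``psi`` are flat arrays of equal length (the candidate list);
    returns (distance, feasible) arrays of that length.
    """
    r = seg.ratio.to_numpy(dtype=float)[None, :]
    b = seg.mean_baf.to_numpy(dtype=float)[None, :]
    balanced = (seg.balance_class == "balanced").to_numpy()[None, :]
    w = (seg.end - seg.start).to_numpy(dtype=float)[None, :]
    t = tcc[:, None]
    p = psi[:, None]
    tumor_cov = r * (t * p + 2 * (1 - t))
    tcn = (tumor_cov - 2 * (1 - t)) / t
    cn_b = (b * tumor_cov - (1 - t)) / t
    cn_a = tcn - cn_b
    with np.errstate(divide="ignore", invalid="ignore"):
        dh = (2 * b - 1) * tumor_cov / (t * tcn)
    even_dist = 2 * np.abs(tcn / 2 - np.round(tcn / 2))
    int_dist = 0.5 * (
        np.abs(cn_a - np.clip(np.round(cn_a), 0, None))
        + np.abs(cn_b - np.clip(np.round(cn_b), 0, None))
    )
    dist = np.where(balanced, even_dist, int_dist)
    neg = np.where(balanced, tcn < -1e-9, np.minimum(cn_a, np.minimum(cn_b, tcn)) < -1e-9)
    bad_dh = ~balanced & ((dh > 1 + 1e-9) | (tcn <= 0))
    feasible = ~(neg | bad_dh).any(axis=1)
    distance = (dist * w).sum(axis=1) / w.sum()
    return distance, feasible


def grid_fit_tcc_ploidy(
    profile: pd.DataFrame,
    tcc_step: float = 0.01,
    psi_step: float = 0.05,
) -> TCCPloidyFit:
    """Grid search over TCC in [0.15, 1.0] and ploidy in [1.0, 6.5].

    ``profile`` is the output of :func:`summarize_segments`. Grid-local minima
    of the weighted mean distance (a point no worse than its <= 8 feasible
    neighbours) are returned ranked by distance; rank 1 is selected.
    """
    seg = profile[profile.usable].reset_index(drop=True)
    if len(seg) == 0:
        raise ValueError("no usable segments (>= 20 het SNPs, unambiguous)")
    tcc_axis = np.round(np.arange(TCC_RANGE[0], TCC_RANGE[1] + 1e-9, tcc_step), 10)
    psi_axis = np.round(np.arange(PLOIDY_RANGE[0], PLOIDY_RANGE[1] + 1e-9, psi_step), 10)
    TT, PP = np.meshgrid(tcc_axis, psi_axis, indexing="ij")
    dist_flat, feas_flat = _grid_distances(seg, TT.ravel(), PP.ravel())
    D = dist_flat.reshape(TT.shape)
    F = feas_flat.reshape(TT.shape)
    surface = pd.DataFrame(
        {"tcc": TT.ravel(), "psi": PP.ravel(), "distance": dist_flat, "feasible": feas_flat}
    )
    Dm = np.where(F, D, np.inf)
    cands = []
    for i in range(Dm.shape[0]):
        for j in range(Dm.shape[1]):
            if not F[i, j]:
                continue
            window = Dm[max(i - 1, 0) : i + 2, max(j - 1, 0) : j + 2]
            if Dm[i, j] <= window.min() + 1e-15:
                cands.append((float(TT[i, j]), float(PP[i, j]), float(D[i, j])))
    candidates = (
        pd.DataFrame(cands, columns=["tcc", "psi", "distance"])
        .sort_values(["distance", "tcc", "psi"])
        .reset_index(drop=True)
    )
    candidates["rank"] = np.arange(1, len(candidates) + 1)
    if len(candidates) == 0:
        logger.warning("grid_fit_tcc_ploidy: no feasible (TCC, ploidy) combination")
        return TCCPloidyFit(candidates, surface, seg.assign(), None,
                            diagnostics={"n_usable_segments": len(seg)})
    sel = candidates.iloc[0]
    selected = {"tcc": float(sel.tcc), "psi": float(sel.psi), "distance": float(sel.distance)}
    fitted = fit_segments_at(seg, selected["tcc"], selected["psi"])
    return TCCPloidyFit(
        candidates, surface, fitted, selected,
        diagnostics={"n_usable_segments": len(seg)},
    )


def fit_segments_at(seg: pd.DataFrame, tcc: float, psi: float) -> pd.DataFrame:
    """Per-segment copy numbers at a fixed (TCC, ploidy); adds rounded integer
    states and the LOH flag (minor allele copy number zero, total >= 1)."""
    rows = []
    for s in seg.itertuples():
        tcn, cn_a, cn_b, dh = invert_mixture(
            s.ratio, 0.5 if s.balance_class == "balanced" else s.mean_baf,
            tcc, psi, balanced=s.balance_class == "balanced",
        )
        rows.append((tcn, cn_a, cn_b, dh))
    out = seg.copy()
    out[["tcn", "cn_a", "cn_b", "dh"]] = pd.DataFrame(rows, index=seg.index)
    out["cn_a_int"] = np.clip(np.round(out.cn_a), 0, None).astype(int)
    out["cn_b_int"] = np.clip(np.round(out.cn_b), 0, None).astype(int)
    out["tcn_int"] = out.cn_a_int + out.cn_b_int
    out["loh"] = (out.cn_a_int == 0) & (out.tcn_int >= 1)
    return out


def tcc_from_snv_vaf(
    vafs, fitted_segments: pd.DataFrame | None = None, positions: pd.DataFrame | None = None,
    min_snvs: int = 10,
) -> float | None:
    """TCC from the somatic-SNV allele-fraction distribution.

    For clonal heterozygous SNVs on copy-neutral (1,1) segments the expected
    VAF is TCC/2, so TCC = 2 x median VAF, capped at 1. When ``positions``
    (chrom, pos per VAF) and ``fitted_segments`` are given, only SNVs on
    segments fitted as (1,1) are used. Returns None below ``min_snvs``.
    """
    vafs = np.asarray(vafs, dtype=float)
    if fitted_segments is not None and positions is not None:
        neutral = fitted_segments[
            (fitted_segments.cn_a_int == 1) & (fitted_segments.cn_b_int == 1)
        ]
        keep = np.zeros(len(vafs), dtype=bool)
        for seg in neutral.itertuples():
            keep |= (
                (positions.chrom == seg.chrom)
                & (positions.pos > seg.start)
                & (positions.pos <= seg.end)
            ).to_numpy()
        vafs = vafs[keep]
    if vafs.size < min_snvs:
        logger.warning("tcc_from_snv_vaf: only %d qualifying SNVs", vafs.size)
        return None
    return float(min(2 * np.median(vafs), 1.0))


def apply_tcc_override(fit: TCCPloidyFit, override: float) -> TCCPloidyFit:
    """Replace the selected solution's TCC with a manual value (e.g. set from
    histology) and recompute segment copy numbers; provenance is recorded."""
    if not 0 < override <= 1:
        raise ValueError("TCC override must lie in (0, 1]")
    if fit.selected is None:
        raise ValueError("no selected solution to override")
    psi = fit.selected["psi"]
    seg_cols = [c for c in fit.segments.columns
                if c not in ("tcn", "cn_a", "cn_b", "dh", "cn_a_int", "cn_b_int",
                             "tcn_int", "loh")]
    fitted = fit_segments_at(fit.segments[seg_cols], override, psi)
    return TCCPloidyFit(
        candidates=fit.candidates,
        surface=fit.surface,
        segments=fitted,
        selected={"tcc": float(override), "psi": psi, "distance": np.nan},
        tcc_snv=fit.tcc_snv,
        manual_override=True,
        diagnostics={**fit.diagnostics, "override_from": fit.selected["tcc"]},
    )
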