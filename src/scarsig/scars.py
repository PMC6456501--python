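"""Genomic-scar statistics: HRD-LOH and large-scale state transitions (LST).

Both scores are computed from a smoothed allele-specific copy-number profile.
Smoothing merges segments smaller than 3 Mbp into the neighbouring segment
with the closer total copy number, which removes oversegmentation noise
before counting. An LST is a switch between copy-number states of two
adjacent segments that are each larger than 10 Mbp, unless the breakpoint
separates two entire chromosome arms; the HRD-LOH score counts subchromosomal
LOH segments (minor allele copy number zero) larger than 15 Mbp. Their sum is
the combined instability score used to flag HR-deficient genomes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genome import GenomeDefinition

__all__ = [
    "InstabilityResult",
    "smooth_segments",
    "count_lst",
    "count_hrd_loh",
    "combined_instability",
    "score_sample",
]

MIN_SMOOTH_BP = 3_000_000
MIN_LST_SEG_BP = 10_000_000
MIN_HRD_SEG_BP = 15_000_000


@dataclass(frozen=True)
class InstabilityResult:
    hrd_loh: int
    lst: int

    @property
    def combined(self) -> int:
        return self.hrd_loh + self.lst


def _check_sorted(df: pd.DataFrame) -> None:
    for chrom, sub in df.groupby("chrom", sort=False):
        s = sub.sort_values("start")
        if (s.start.to_numpy()[1:] < s.end.to_numpy()[:-1]).any():
            raise ValueError(f"overlapping segments on {chrom}")


def smooth_segments(segments: pd.DataFrame, min_size: int = MIN_SMOOTH_BP) -> pd.DataFrame:
    """Merge segments smaller than ``min_size`` into their more similar neighbour.

    Iteratively the smallest sub-threshold segment on each chromosome is
    absorbed by the same-chromosome neighbour with the smaller total-copy-number
    difference (ties go left); the absorbing segment's copy-number state is
    kept and its span extended. Repeats until no segment is below the
    threshold or the chromosome holds a single segment.

    ``segments`` needs chrom, start, end, tcn, cn_a, cn_b (extra columns are
    dropped). Segments must be non-overlapping per chromosome.
    """
    _check_sorted(segments)
    out_rows = []
    for chrom, sub in segments.groupby("chrom", sort=False):
        segs = sub.sort_values("start")[["start", "end", "tcn", "cn_a", "cn_b"]].to_dict(
            "records"
        )
        while len(segs) > 1:
            sizes = [s["end"] - s["start"] for s in segs]
            small = [i for i, sz in enumerate(sizes) if sz < min_size]
            if not small:
                break
            i = min(small, key=lambda i: sizes[i])
            left = segs[i - 1] if i > 0 else None
            right = segs[i + 1] if i + 1 < len(segs) else None
            if left is not None and right is not None:
                d_left = abs(segs[i]["tcn"] - left["tcn"])
                d_right = abs(segs[i]["tcn"] - right["tcn"])
                into = left if d_left <= d_right else right
            else:
                into = left if left is not None else right
            into["start"] = min(into["start"], segs[i]["start"])
            into["end"] = max(into["end"], segs[i]["end"])
            segs.pop(i)
        for s in segs:
            out_rows.append({"chrom": chrom, **s})
    return pd.DataFrame(out_rows, columns=["chrom", "start", "end", "tcn", "cn_a", "cn_b"])


def _state(seg, mode: str) -> tuple:
    if mode == "total":
        return (int(round(seg.tcn)),)
    return (int(round(seg.cn_a)), int(round(seg.cn_b)))


def _is_arm_pair(left, right, chrom, tol: int, arm_frac: float) -> bool:
    """True when the breakpoint between two segments separates entire
    chromosome arms: it lies within ``tol`` of the centromere and each
    flanking segment covers at least ``arm_frac`` of its arm."""
    breakpoint = left.end
    near_centromere = (
        chrom.centromere_start - tol <= breakpoint <= chrom.centromere_end + tol
    )
    if not near_centromere:
        return False
    p_len = chrom.centromere_start
    q_len = chrom.length - chrom.centromere_end
    p_cov = (min(left.end, chrom.centromere_start) - max(left.start, 0)) / p_len
    q_cov = (min(right.end, chrom.length) - max(right.start, chrom.centromere_end)) / q_len
    return p_cov >= arm_frac and q_cov >= arm_frac


def count_lst(
    segments: pd.DataFrame,
    genome: GenomeDefinition,
    min_seg: int = MIN_LST_SEG_BP,
    state: str = "allele",
    centromere_tol: int = 1_000_000,
    arm_frac: float = 0.95,
) -> int:
    """Count large-scale state transitions on a smoothed profile.

    A switch between the copy-number states of two adjacent same-chromosome
    segments, each larger than ``min_seg``, counts as one LST unless the
    breakpoint separates two entire chromosome arms. ``state='allele'``
    compares (CN_A, CN_B) pairs (capturing copy-neutral LOH switches);
    ``state='total'`` compares total copy number only. Segments of 3-10 Mbp
    break adjacency: no switch is counted across them.
    """
    n = 0
    for chrom_name, sub in segments.groupby("chrom", sort=False):
        chrom = genome[chrom_name]
        segs = list(sub.sort_values("start").itertuples())
        for left, right in zip(segs, segs[1:]):
            if (left.end - left.start) <= min_seg or (right.end - right.start) <= min_seg:
                continue
            if _state(left, state) == _state(right, state):
                continue
            if _is_arm_pair(left, right, chrom, centromere_tol, arm_frac):
                continue
            n += 1
    return n


def count_hrd_loh(
    segments: pd.DataFrame,
    genome: GenomeDefinition,
    min_seg: int = MIN_HRD_SEG_BP,
    whole_chrom_frac: float = 0.95,
) -> int:
    """Count subchromosomal LOH segments larger than ``min_seg``.

    LOH means minor allele copy number zero with total copy number >= 1.
    Segments covering at least ``whole_chrom_frac`` of their chromosome are
    whole-chromosome events and do not count.
    """
    n = 0
    for seg in segments.itertuples():
        size = seg.end - seg.start
        if size <= min_seg:
            continue
        loh = int(round(seg.cn_a)) == 0 and int(round(seg.tcn)) >= 1
        if not loh:
            continue
        if size >= whole_chrom_frac * genome[seg.chrom].length:
            continue
        n += 1
    return n


def combined_instability(hrd_loh: int, lst: int) -> int:
    """Sum of the HRD-LOH and LST scores."""
    if hrd_loh < 0 or lst < 0:
        raise ValueError("counts must be non-negative")
    return hrd_loh + lst


def score_sample(
    segments: pd.DataFrame, genome: GenomeDefinition, state: str = "allele"
) -> InstabilityResult:
    """Smooth a fitted segment profile and compute both scar scores."""
    smoothed = smooth_segments(segments)
    return InstabilityResult(
        hrd_loh=count_hrd_loh(smoothed, genome),
        lst=count_lst(smoothed, genome, state=state),
    )
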