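"""96-channel mutational catalogs.

Single-nucleotide variants are binned by substitution class and trinucleotide
context in the pyrimidine frame: 6 classes (C>A, C>G, C>T, T>A, T>C, T>G)
x 16 flanking-base combinations, giving the canonical 96 channels used by the
COSMIC signature compendium. Purine-reference records are reverse-complemented
before lookup, so the two strand encodings of a mutation map to one channel.

Catalogs are pandas DataFrames with the 96 channel labels (e.g. ``A[C>T]A``)
as index, one column per sample, in canonical channel order.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "SUBSTITUTION_CLASSES",
    "CHANNELS",
    "PYRIMIDINE_TRIPLETS",
    "classify_channel",
    "channel_label",
    "channel_to_parts",
    "extract_context",
    "build_catalog",
    "TripletFrequencyTable",
    "motif_frequencies",
    "normalize_catalog_motifs",
]

_BASES = "ACGT"
_COMPLEMENT = str.maketrans("ACGT", "TGCA")

SUBSTITUTION_CLASSES = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")

#: Canonical channel labels: substitution-class major, then 5' and 3' flank
#: lexicographic, e.g. A[C>A]A, A[C>A]C, ..., T[T>G]T.
CHANNELS = tuple(
    f"{five}[{sub}]{three}"
    for sub in SUBSTITUTION_CLASSES
    for five in _BASES
    for three in _BASES
)

#: The 32 pyrimidine-centred triplets, in the order they appear inside CHANNELS.
PYRIMIDINE_TRIPLETS = tuple(
    f"{five}{ref}{three}" for ref in "CT" for five in _BASES for three in _BASES
)

_CHANNEL_INDEX = {label: i for i, label in enumerate(CHANNELS)}


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def classify_channel(ref: str, alt: str, context: str) -> int | None:
    """Map (ref, alt, trinucleotide context) to a channel index in [0, 96).

    ``context`` is the reference-strand 3-mer centred on ``ref``. Purine
    references are reverse-complemented into the pyrimidine frame. Returns
    ``None`` for records containing ambiguous bases (N), which callers should
    count and skip.
    """
    ref, alt, context = ref.upper(), alt.upper(), context.upper()
    if len(context) != 3:
        raise ValueError(f"context must be a 3-mer, got {context!r}")
    if context[1] != ref:
        raise ValueError(f"context middle base {context[1]!r} != ref {ref!r}")
    if ref == alt:
        raise ValueError("ref and alt must differ")
    if any(b not in _BASES for b in (ref, alt, *context)):
        return None
    if ref in "AG":
        ref, alt, context = (
            ref.translate(_COMPLEMENT),
            alt.translate(_COMPLEMENT),
            revcomp(context),
        )
    return _CHANNEL_INDEX[f"{context[0]}[{ref}>{alt}]{context[2]}"]


def channel_label(index: int) -> str:
    return CHANNELS[index]


def channel_to_parts(label: str) -> tuple[str, str, str]:
    """Split ``A[C>T]G`` into (ref, alt, triplet) = ('C', 'T', 'ACG')."""
    five, rest = label[0], label[2:]
    ref, alt, three = rest[0], rest[2], rest[4]
    return ref, alt, f"{five}{ref}{three}"


#: triplet (pyrimidine frame) of each channel, aligned with CHANNELS
CHANNEL_TRIPLETS = tuple(channel_to_parts(c)[2] for c in CHANNELS)


def extract_context(records: pd.DataFrame, fasta) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Fill the ``context`` column from an indexed reference.

    ``fasta`` is a ``pyfaidx.Fasta`` (or any mapping of chrom -> sequence
    supporting slicing). Positions are 1-based. Records whose reference base
    does not match the FASTA, or that lack a flanking base, are rejected.

    Returns ``(accepted, rejected)`` where ``rejected`` carries a ``reason``
    column.
    """
    accepted_rows, rejected = [], []
    for row in records.to_dict("records"):
        chrom, pos = row["chrom"], int(row["pos"])
        if chrom not in fasta:
            raise KeyError(f"chromosome {chrom!r} not present in reference")
        seq = fasta[chrom]
        length = len(seq)
        if pos < 2 or pos > length - 1:
            rejected.append({**row, "reason": "no-flank"})
            continue
        context = str(seq[pos - 2 : pos + 1]).upper()
        if context[1] != row["ref"].upper():
            rejected.append({**row, "reason": "ref-mismatch"})
            continue
        accepted_rows.append({**row, "context": context})
    if rejected:
        logger.warning("extract_context rejected %d records", len(rejected))
    return pd.DataFrame(accepted_rows), pd.DataFrame(rejected)


def build_catalog(records: pd.DataFrame, samples=None) -> pd.DataFrame:
    """Count somatic SNV records into a 96 x samples catalog.

    ``records`` needs columns sample, ref, alt, context. Rows classified to no
    channel (ambiguous base) are dropped with a logged count. ``samples`` may
    declare the column order (including samples with zero records, which get a
    zero column and a warning).
    """
    if samples is None:
        samples = list(pd.unique(records["sample"])) if len(records) else []
    counts = pd.DataFrame(
        np.zeros((96, len(samples)), dtype=float), index=list(CHANNELS), columns=samples
    )
    skipped = 0
    for row in records.itertuples():
        idx = classify_channel(row.ref, row.alt, row.context)
        if idx is None:
            skipped += 1
            continue
        counts.iloc[idx, counts.columns.get_loc(row.sample)] += 1
    if skipped:
        logger.warning("build_catalog skipped %d records with ambiguous bases", skipped)
    empties = [s for s in samples if counts[s].sum() == 0]
    if empties:
        logger.warning("build_catalog: zero records for samples %s", empties)
    return counts


@dataclass(frozen=True)
class TripletFrequencyTable:
    """Relative frequencies of the 32 pyrimidine-centred triplets in a region set."""

    label: str
    frequencies: pd.Series = field(compare=False)

    def __post_init__(self) -> None:
        freq = self.frequencies.reindex(PYRIMIDINE_TRIPLETS)
        if freq.isna().any():
            missing = freq.index[freq.isna()].tolist()
            raise ValueError(f"frequency table {self.label!r} missing triplets: {missing}")
        if (freq <= 0).any():
            raise ValueError(f"frequency table {self.label!r} has non-positive entries")
        freq = freq / freq.sum()
        object.__setattr__(self, "frequencies", freq)

    def __getitem__(self, triplet: str) -> float:
        return float(self.frequencies[triplet])


def motif_frequencies(regions, fasta, label: str = "regions") -> TripletFrequencyTable:
    """Count pyrimidine-collapsed triplet motifs whose centre lies in a region set.

    ``regions`` is an iterable of (chrom, start, end) with 0-based half-open
    coordinates; flanking bases may extend beyond the region but not beyond
    the chromosome. Triplets containing N are skipped.
    """
    regions = list(regions)
    if not regions:
        raise ValueError("empty region set")
    counts = {t: 0 for t in PYRIMIDINE_TRIPLETS}
    total = 0
    for chrom, start, end in regions:
        if chrom not in fasta:
            raise KeyError(f"chromosome {chrom!r} not present in reference")
        seq = fasta[chrom]
        length = len(seq)
        if start < 0 or end > length or end <= start:
            raise ValueError(f"region {chrom}:{start}-{end} outside chromosome bounds")
        lo = max(start, 1)
        hi = min(end, length - 1)
        if hi <= lo:
            continue
        window = str(seq[lo - 1 : hi + 1]).upper()
        for i in range(hi - lo):
            triplet = window[i : i + 3]
            if any(b not in _BASES for b in triplet):
                continue
            if triplet[1] in "AG":
                triplet = revcomp(triplet)
            counts[triplet] += 1
            total += 1
    if total == 0:
        raise ValueError("no valid centre-flank triples in region set")
    freq = pd.Series(counts, dtype=float) / total
    # drop zero-count triplets is disallowed by the table invariant; assign a
    # minimal pseudo-frequency so correction ratios stay defined
    zero = freq == 0
    if zero.any():
        freq[zero] = 0.5 / total
        freq = freq / freq.sum()
    return TripletFrequencyTable(label, freq)


def normalize_catalog_motifs(
    catalog: pd.DataFrame,
    from_freq: TripletFrequencyTable,
    to_freq: TripletFrequencyTable,
) -> pd.DataFrame:
    """Correct a catalog for triplet-motif composition differences.

    Each channel count is multiplied by ``to_freq(t) / from_freq(t)`` for its
    pyrimidine-frame triplet t, e.g. to rescale counts observed on exome
    capture regions to whole-genome motif abundances before decomposition
    against genome-derived signatures.
    """
    ratios = np.array(
        [to_freq[t] / from_freq[t] for t in CHANNEL_TRIPLETS], dtype=float
    )
    out = catalog.copy().astype(float)
    out.iloc[:, :] = out.to_numpy() * ratios[:, None]
    return out
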