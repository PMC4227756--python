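"""Empirical insert-size model and the clustering window W_L.

Discordant-pair clustering needs to know how far apart two read anchors can
be while still plausibly belonging to the same insertion; that window is
W_L = mean insert length + 3 standard deviations, fitted from properly
paired alignments.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

MIN_PAIRS = 100


@dataclass(frozen=True)
class InsertSizeModel:
    """Summary of the outer insert-length distribution of a library."""

    mean_insert: float
    sd_insert: float
    n_pairs_sampled: int

    @property
    def w_l(self) -> float:
        """Clustering window: mean + 3 sd."""
        return self.mean_insert + 3.0 * self.sd_insert

    # alias matching the field name used throughout the literature
    W_L = w_l


def fit_insert_sizes(lengths, trim_frac: float = 0.005) -> InsertSizeModel:
    """Fit mean/sd of observed insert lengths.

    The extreme ``trim_frac`` tail on each side is discarded before taking
    moments so that chimeric pairs do not inflate W_L.
    """
    arr = np.asarray(list(lengths), dtype=float)
    n = arr.size
    if n < MIN_PAIRS:
        raise ValueError("insufficient pairs to model insert size")
    arr.sort()
    k = int(np.floor(n * trim_frac))
    if k > 0:
        arr = arr[k : n - k]
    return InsertSizeModel(
        mean_insert=float(arr.mean()),
        sd_insert=float(arr.std()),
        n_pairs_sampled=n,
    )


def build_insert_size_model(alignments, max_pairs: int = 100_000) -> InsertSizeModel:
    """Fit an :class:`InsertSizeModel` from an alignment stream.

    ``alignments`` is a pysam ``AlignmentFile`` or any iterable of
    ``AlignedSegment``. Only properly paired, primary, non-duplicate records
    with positive template length contribute (each pair counted once).
    """
    lengths = []
    for read in alignments:
        if (
            not read.is_proper_pair
            or read.is_secondary
            or read.is_supplementary
            or read.is_duplicate
            or read.is_unmapped
        ):
            continue
        tlen = read.template_length
        if tlen <= 0:  # count each physical pair from its leftmost end only
            continue
        lengths.append(tlen)
        if len(lengths) >= max_pairs:
            break
    return fit_insert_sizes(lengths)
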