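"""Permutation enrichment of insertion positions against feature tracks.

Observed insertion positions are compared with randomly resampled position
sets matched by chromosome (and excluding assembly gaps); a two-tailed
permutation p-value with add-one correction reports enrichment or
depletion. Flank base composition (%GC and AT/TA dinucleotide density) is
profiled directly from the reference sequence.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)


@dataclass
class FeatureTrack:
    """Named set of genomic intervals, merged and sorted per chromosome."""

    name: str
    starts: dict = field(default_factory=dict)  # chrom -> np.ndarray
    ends: dict = field(default_factory=dict)

    @classmethod
    def from_intervals(cls, name, intervals):
        by_chrom = {}
        for chrom, start, end in intervals:
            by_chrom.setdefault(chrom, []).append((int(start), int(end)))
        track = cls(name=name)
        for chrom, ivs in by_chrom.items():
            ivs.sort()
            merged = []
            for s, e in ivs:
                if merged and s <= merged[-1][1]:
                    merged[-1] = (merged[-1][0], max(merged[-1][1], e))
                else:
                    merged.append((s, e))
            track.starts[chrom] = np.array([s for s, _ in merged])
            track.ends[chrom] = np.array([e for _, e in merged])
        return track

    @classmethod
    def from_bed(cls, path, name=None):
        df = pd.read_csv(
            path, sep="\t", comment="#", header=None, usecols=[0, 1, 2],
            names=["chrom", "start", "end"], dtype={"chrom": str},
        )
        return cls.from_intervals(
            name or str(path), df.itertuples(index=False, name=None)
        )


def overlap_statistic(positions, track: FeatureTrack, window: int = 0) -> int:
    """Number of positions whose +/-window flank intersects the track."""
    count = 0
    missing = set()
    for chrom, pos in positions:
        if chrom not in track.starts:
            missing.add(chrom)
            continue
        lo, hi = pos - window, pos + window + 1
        ends = track.ends[chrom]
        i = int(np.searchsorted(ends, lo, side="right"))
        if i < len(ends) and track.starts[chrom][i] < hi:
            count += 1
    if missing:
        log.info("chromosomes absent from track %s: %s", track.name, sorted(missing))
    return count


class MatchedPositionSampler:
    """Chromosome-matched uniform sampler over non-gap reference bases."""

    def __init__(self, chrom_sizes: dict, gaps: FeatureTrack | None = None):
        self.allowed = {}
        for chrom, size in chrom_sizes.items():
            if gaps is not None and chrom in gaps.starts:
                segs = []
                prev = 0
                for s, e in zip(gaps.starts[chrom], gaps.ends[chrom]):
                    if s > prev:
                        segs.append((prev, min(s, size)))
                    prev = max(prev, e)
                if prev < size:
                    segs.append((prev, size))
            else:
                segs = [(0, size)]
            segs = [(s, e) for s, e in segs if e > s]
            if not segs:
                raise ValueError(f"chromosome {chrom} fully gapped")
            starts = np.array([s for s, _ in segs])
            lens = np.array([e - s for s, e in segs])
            self.allowed[chrom] = (starts, np.concatenate([[0], np.cumsum(lens)]))

    def total_bases(self, chrom) -> int:
        return int(self.allowed[chrom][1][-1])

    def sample(self, positions, rng):
        """One random position per observed position, matched by chromosome."""
        out = []
        for chrom, _pos in positions:
            starts, cum = self.allowed[chrom]
            r = int(rng.integers(0, cum[-1]))
            seg = int(np.searchsorted(cum, r, side="right")) - 1
            out.append((chrom, int(starts[seg] + (r - cum[seg]))))
        return out


def sample_matched_positions(positions, chrom_sizes, gaps=None, seed=0):
    """Convenience wrapper: one matched random set, deterministic under seed."""
    sampler = MatchedPositionSampler(chrom_sizes, gaps)
    return sampler.sample(positions, np.random.default_rng(seed))


@dataclass
class PermutationResult:
    feature: str
    observed: float
    null: np.ndarray
    p_two_tailed: float
    direction: str  # 'enriched' | 'depleted'

    def as_dict(self):
        return {
            "feature": self.feature,
            "observed": self.observed,
            "n_resamples": int(len(self.null)),
            "p_two_tailed": self.p_two_tailed,
            "direction": self.direction,
        }


def two_tailed_p(observed: float, null: np.ndarray) -> float:
    """Add-one two-tailed permutation p-value, capped at 1."""
    null = np.asarray(null, dtype=float)
    n = len(null)
    hi = int((null >= observed).sum()) + 1
    lo = int((null <= observed).sum()) + 1
    return min(1.0, 2.0 * min(hi, lo) / (n + 1))


def permutation_test(
    positions,
    track: FeatureTrack | None = None,
    *,
    statistic=None,
    sampler: MatchedPositionSampler | None = None,
    chrom_sizes: dict | None = None,
    gaps: FeatureTrack | None = None,
    window: int = 0,
    n_resamples: int = 1000,
    seed: int = 0,
    feature_name: str | None = None,
) -> PermutationResult:
    """Two-tailed permutation test of a position-set statistic.

    By default the statistic is the track overlap count; any callable
    mapping a position list to a number may be supplied instead (e.g. mean
    flank %GC). Null sets are chromosome-matched, gap-excluded uniform
    resamples of the observed set.
    """
    if n_resamples < 100:
        log.warning("n_resamples=%d is low; p-values will be coarse", n_resamples)
    if statistic is None:
        if track is None:
            raise ValueError("either track or statistic required")
        statistic = lambda pos: overlap_statistic(pos, track, window=window)
    if sampler is None:
        if chrom_sizes is None:
            raise ValueError("sampler or chrom_sizes required")
        sampler = MatchedPositionSampler(chrom_sizes, gaps)
    rng = np.random.default_rng(seed)
    observed = float(statistic(list(positions)))
    null = np.array(
        [float(statistic(sampler.sample(positions, rng))) for _ in range(n_resamples)]
    )
    return PermutationResult(
        feature=feature_name or (track.name if track else "statistic"),
        observed=observed,
        null=null,
        p_two_tailed=two_tailed_p(observed, null),
        direction="enriched" if observed > float(np.median(null)) else "depleted",
    )


# ---------------------------------------------------------------------------
# Flank composition
# ---------------------------------------------------------------------------


def _composition(seq: str):
    seq = seq.upper()
    non_n = sum(1 for b in seq if b != "N")
    gc = seq.count("G") + seq.count("C")
    dimers = sum(
        1 for i in range(len(seq) - 1) if seq[i : i + 2] in ("AT", "TA")
    )
    pct_gc = 100.0 * gc / non_n if non_n else float("nan")
    at_density = dimers / (len(seq) - 1) if len(seq) > 1 else float("nan")
    return pct_gc, at_density


def flank_composition(positions, fasta, window: int = 500) -> pd.DataFrame:
    """Per-position %GC and AT/TA dimer density of the +/-window flank.

    ``fasta`` is a pyfaidx.Fasta (or any mapping of chrom -> sequence-like).
    Flanks running off a contig end are truncated and flagged.
    """
    rows = []
    for chrom, pos in positions:
        contig = fasta[chrom]
        size = len(contig)
        lo, hi = pos - window, pos + window + 1
        truncated = lo < 0 or hi > size
        seq = str(contig[max(0, lo) : min(size, hi)])
        pct_gc, at_density = _composition(seq)
        rows.append(
            {
                "chrom": chrom,
                "pos": pos,
                "pct_gc": pct_gc,
                "at_dimer_density": at_density,
                "truncated": truncated,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Genic context labeling
# ---------------------------------------------------------------------------

_PRECEDENCE = ["exon", "utr", "intron", "promoter", "terminator", "intergenic"]


def classify_genic_context(positions, genes: pd.DataFrame, flank: int = 5000):
    """Label positions exon/UTR/intron/promoter/terminator/intergenic.

    ``genes`` needs columns chrom, start, end, strand plus optional
    ``exons`` (list of (start, end) coding-exon intervals) and ``utrs``.
    Precedence: exon > UTR > intron > promoter/terminator > intergenic.
    """
    labels = []
    for chrom, pos in positions:
        hits = set()
        sub = genes[genes["chrom"] == chrom]
        for g in sub.itertuples():
            if g.start <= pos < g.end:
                if any(s <= pos < e for s, e in getattr(g, "exons", []) or []):
                    hits.add("exon")
                elif any(s <= pos < e for s, e in getattr(g, "utrs", []) or []):
                    hits.add("utr")
                else:
                    hits.add("intron")
            else:
                up = g.start - flank <= pos < g.start
                down = g.end <= pos < g.end + flank
                if g.strand == "+":
                    if up:
                        hits.add("promoter")
                    if down:
                        hits.add("terminator")
                else:
                    if up:
                        hits.add("terminator")
                    if down:
                        hits.add("promoter")
        label = next((lab for lab in _PRECEDENCE if lab in hits), "intergenic")
        labels.append(label)
    return labels
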