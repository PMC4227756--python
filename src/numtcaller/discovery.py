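"""Per-sample discovery of candidate Numt insertion sites.

The discovery signal is a read pair whose nuclear end maps uniquely
(MAPQ >= 10) while its mate maps to the mitochondrial contig or to a known
reference Numt. Anchors are clustered by strand within the insert-size
window W_L, forward clusters are linked to downstream reverse clusters, and
soft-clipped reads inside the linked region localize the exact breakpoint
when their clipped tails realign to the (circular) mitochondrial sequence.

Coordinates are 0-based half-open internally; ``breakpoint_left`` is the
last reference base before the inserted sequence.
"""

from __future__ import annotations

import logging
from collections import Counter, defaultdict
from dataclasses import dataclass, field

import pandas as pd
import pysam

from .genotype import (
    FilterThresholds,
    LikelihoodInput,
    apply_filters,
    count_reference_spanning,
    genotype_sample,
    mapq_to_error,
)
from .insert_size import InsertSizeModel
from .mito import CircularMatcher, circular_interval_from_points

log = logging.getLogger(__name__)

DEFAULT_MAPQ_MIN = 10
DEFAULT_MIN_CLIP = 20
DEFAULT_MIN_CLIP_READS = 2
DEFAULT_MIN_CLIP_IDENTITY = 0.9


@dataclass(frozen=True)
class MitoAnchoredPair:
    """Nuclear anchor of a read pair whose mate maps to mtDNA or a known Numt."""

    sample_id: str
    chrom: str
    pos: int
    end: int
    strand: str  # '+' (forward) or '-' (reverse)
    mapq: int
    mate_target: str  # mito contig name or known-Numt id
    mate_pos: int
    read_name: str
    mate_is_mito: bool = True


@dataclass
class ReadCluster:
    chrom: str
    start: int
    end: int
    strand: str
    members: list = field(default_factory=list)


@dataclass
class LinkedClusterPair:
    """Forward/reverse cluster pairing around one putative insertion."""

    fwd: ReadCluster | None
    rev: ReadCluster | None

    @property
    def chrom(self) -> str:
        return (self.fwd or self.rev).chrom

    @property
    def two_sided(self) -> bool:
        return self.fwd is not None and self.rev is not None


@dataclass
class CandidateSite:
    chrom: str
    breakpoint_left: int
    breakpoint_right: int
    precise: bool
    fwd_cluster: ReadCluster | None
    rev_cluster: ReadCluster | None
    softclip_support: int
    mito_interval: tuple | None
    clip_read_errors: list = field(default_factory=list)
    clip_read_names: list = field(default_factory=list)


@dataclass
class NumtCall:
    """One putative insertion in one sample, with counts and likelihoods."""

    sample_id: str
    chrom: str
    breakpoint_left: int
    breakpoint_right: int
    precise: bool
    support: int
    ref_support: int
    depth: int
    quality: float
    genotype: str
    gq: float
    log_likelihoods: list
    filters: list
    mito_interval: tuple | None
    ci: tuple

    @property
    def passed(self) -> bool:
        return not self.filters


def load_numt_bed(path):
    """Read a known-Numt BED file into (chrom, start, end, name) tuples."""
    df = pd.read_csv(
        path,
        sep="\t",
        comment="#",
        header=None,
        usecols=[0, 1, 2, 3],
        names=["chrom", "start", "end", "name"],
        dtype={"chrom": str, "name": str},
    )
    return list(df.itertuples(index=False, name=None))


def _mate_numt_target(chrom, pos, intervals):
    for c, s, e, name in intervals:
        if c == chrom and s <= pos < e:
            return name
    return None


def extract_candidate_pairs(
    bam,
    mito_contig: str,
    known_numts=None,
    mapq_min: int = DEFAULT_MAPQ_MIN,
    sample_id: str = "",
    region=None,
):
    """Collect mito-anchored pairs from a coordinate-sorted alignment file.

    Emits one :class:`MitoAnchoredPair` per physical pair: the emitted end is
    the nuclear anchor (primary, non-duplicate, MAPQ >= ``mapq_min``), and the
    mate must map to ``mito_contig`` or inside a known-Numt interval.
    """
    if mito_contig not in bam.references:
        raise ValueError(f"mitochondrial contig '{mito_contig}' absent from header")
    known_numts = known_numts or []
    pairs = []
    it = bam.fetch(*region) if region else bam.fetch()
    for read in it:
        if (
            read.is_unmapped
            or read.is_secondary
            or read.is_supplementary
            or read.is_duplicate
            or read.mate_is_unmapped
        ):
            continue
        if read.mapping_quality < mapq_min:
            continue
        if read.reference_name == mito_contig:
            continue
        # the anchor itself must not sit inside a known-Numt interval
        if _mate_numt_target(read.reference_name, read.reference_start, known_numts):
            continue
        mate_chrom = read.next_reference_name
        mate_pos = read.next_reference_start
        if mate_chrom == mito_contig:
            target, is_mito = mito_contig, True
        else:
            target = _mate_numt_target(mate_chrom, mate_pos, known_numts)
            is_mito = False
            if target is None:
                continue
        pairs.append(
            MitoAnchoredPair(
                sample_id=sample_id,
                chrom=read.reference_name,
                pos=read.reference_start,
                end=read.reference_end,
                strand="-" if read.is_reverse else "+",
                mapq=read.mapping_quality,
                mate_target=target,
                mate_pos=mate_pos,
                read_name=read.query_name,
                mate_is_mito=is_mito,
            )
        )
    pairs.sort(key=lambda p: (p.chrom, p.pos, p.read_name))
    return pairs


def cluster_reads(pairs, model: InsertSizeModel):
    """Single-linkage clustering of anchors within W_L, per chrom and strand."""
    w_l = model.w_l
    by_group = defaultdict(list)
    for p in pairs:
        by_group[(p.chrom, p.strand)].append(p)
    clusters = []
    for (chrom, strand), members in sorted(by_group.items()):
        members.sort(key=lambda p: p.pos)
        current = [members[0]]
        for p in members[1:]:
            if p.pos - current[-1].pos <= w_l:
                current.append(p)
            else:
                clusters.append(_make_cluster(chrom, strand, current))
                current = [p]
        clusters.append(_make_cluster(chrom, strand, current))
    clusters.sort(key=lambda c: (c.chrom, c.start, c.strand))
    return clusters


def _make_cluster(chrom, strand, members):
    return ReadCluster(
        chrom=chrom,
        start=min(p.pos for p in members),
        end=max(p.end for p in members),
        strand=strand,
        members=list(members),
    )


def link_clusters(clusters, model: InsertSizeModel):
    """Pair forward clusters with downstream reverse clusters within 2 W_L.

    Greedy nearest-pair matching (smallest gap first, ties leftmost); each
    cluster joins at most one link. Unlinked clusters are retained as
    one-sided candidates.
    """
    max_gap = 2.0 * model.w_l
    links = []
    by_chrom = defaultdict(list)
    for c in clusters:
        by_chrom[c.chrom].append(c)
    for chrom in sorted(by_chrom):
        fwds = [c for c in by_chrom[chrom] if c.strand == "+"]
        revs = [c for c in by_chrom[chrom] if c.strand == "-"]
        candidates = []
        for f in fwds:
            for r in revs:
                if r.start < f.start:
                    continue  # wrong orientation
                gap = r.start - f.end
                if gap <= max_gap:
                    candidates.append((gap, f.start, r.start, f, r))
        candidates.sort(key=lambda t: (t[0], t[1], t[2]))
        used = set()
        for gap, _, _, f, r in candidates:
            if id(f) in used or id(r) in used:
                continue
            used.add(id(f))
            used.add(id(r))
            links.append(LinkedClusterPair(fwd=f, rev=r))
        for f in fwds:
            if id(f) not in used:
                links.append(LinkedClusterPair(fwd=f, rev=None))
        for r in revs:
            if id(r) not in used:
                links.append(LinkedClusterPair(fwd=None, rev=r))
    links.sort(key=lambda lk: (lk.chrom, (lk.fwd or lk.rev).start))
    return links


def collect_softclips(bam, chrom, start, end, min_clip=DEFAULT_MIN_CLIP):
    """Soft-clip break evidence in a region.

    Returns a list of (break_pos, tail, mapq, read_name) where ``break_pos``
    is the first reference base after the junction for right clips and the
    first aligned base for left clips — identical at a clean insertion
    junction.
    """
    out = []
    for read in bam.fetch(chrom, max(0, start), end):
        if (
            read.is_unmapped
            or read.is_secondary
            or read.is_supplementary
            or read.is_duplicate
        ):
            continue
        cig = read.cigartuples or []
        seq = read.query_sequence or ""
        if len(cig) >= 2 and cig[0][0] == 4 and cig[0][1] >= min_clip:
            out.append(
                (read.reference_start, seq[: cig[0][1]], read.mapping_quality,
                 read.query_name)
            )
        if len(cig) >= 2 and cig[-1][0] == 4 and cig[-1][1] >= min_clip:
            out.append(
                (read.reference_end, seq[len(seq) - cig[-1][1]:],
                 read.mapping_quality, read.query_name)
            )
    return out


def find_softclip_breakpoint(
    bam,
    chrom: str,
    start: int,
    end: int,
    mito_seq,
    min_clip: int = DEFAULT_MIN_CLIP,
    min_clip_reads: int = DEFAULT_MIN_CLIP_READS,
    min_identity: float = DEFAULT_MIN_CLIP_IDENTITY,
):
    """Locate a precise breakpoint from identically broken soft-clipped reads.

    Candidate positions need at least ``min_clip_reads`` reads breaking at the
    same base (modal position wins, ties to the leftmost), and the longest
    clipped tail there must realign ungapped to the circular mitochondrial
    sequence on either strand at >= ``min_identity``. Returns
    (breakpoint_left, precise, clip evidence list, mito_offset) with
    ``breakpoint_left = None`` when no position qualifies.
    """
    matcher = mito_seq if isinstance(mito_seq, CircularMatcher) else CircularMatcher(mito_seq)
    clips = collect_softclips(bam, chrom, start, end, min_clip=min_clip)
    if not clips:
        return None, False, [], None
    counts = Counter(c[0] for c in clips)
    best = max(counts.items(), key=lambda kv: (kv[1], -kv[0]))
    break_pos, n_at = best
    if n_at < min_clip_reads:
        return None, False, [], None
    at_site = [c for c in clips if c[0] == break_pos]
    longest_tail = max(at_site, key=lambda c: len(c[1]))[1]
    ident, offset, _strand = matcher.best_match(longest_tail)
    precise = ident >= min_identity
    if not precise:
        return None, False, [], None
    return break_pos - 1, True, at_site, offset


def call_sites(
    bam,
    linked_pairs,
    model: InsertSizeModel,
    mito_seq: str,
    sample_id: str = "",
    thresholds: FilterThresholds | None = None,
    min_clip: int = DEFAULT_MIN_CLIP,
    min_clip_reads: int = DEFAULT_MIN_CLIP_READS,
):
    """Localize, score and filter each linked-cluster candidate.

    Emits one :class:`NumtCall` per candidate with read support; candidates
    without any insertion-supporting reads after QC are dropped.
    """
    thresholds = thresholds or FilterThresholds()
    matcher = CircularMatcher(mito_seq)
    w_l = int(round(model.w_l))
    calls = []
    for lk in linked_pairs:
        chrom = lk.chrom
        if lk.two_sided:
            region = (lk.fwd.end - w_l, lk.rev.start + w_l)
            interval = (lk.fwd.end, lk.rev.start)
        elif lk.fwd is not None:
            region = (lk.fwd.start - w_l, lk.fwd.end + 2 * w_l)
            interval = (lk.fwd.end, lk.fwd.end + w_l)
        else:
            region = (lk.rev.start - 2 * w_l, lk.rev.end + w_l)
            interval = (max(0, lk.rev.start - w_l), lk.rev.start)

        bp, precise, clip_evidence, _ = find_softclip_breakpoint(
            bam, chrom, region[0], region[1], matcher,
            min_clip=min_clip, min_clip_reads=min_clip_reads,
        )
        if precise:
            breakpoint_left = breakpoint_right = bp
            ci = (0, 0)
        else:
            breakpoint_left = max(0, (interval[0] + interval[1]) // 2)
            breakpoint_right = breakpoint_left
            ci = (interval[0] - breakpoint_left, interval[1] - breakpoint_left)

        members = []
        for cl in (lk.fwd, lk.rev):
            if cl is not None:
                members.extend(cl.members)
        alt_names = {}
        for p in members:
            alt_names.setdefault(p.read_name, mapq_to_error(p.mapq))
        for _, _tail, mapq, name in clip_evidence:
            alt_names.setdefault(name, mapq_to_error(mapq))
        support = len(alt_names)
        if support == 0:
            continue

        ref_count, ref_mapqs = count_reference_spanning(
            bam, chrom, breakpoint_left, min_clip=min_clip
        )
        inp = LikelihoodInput(
            ref_errors=[mapq_to_error(q) for q in ref_mapqs],
            alt_errors=list(alt_names.values()),
        )
        gl = genotype_sample(inp)
        depth = ref_count + support
        mito_points = []
        for p in members:
            if p.mate_is_mito:
                read_len = max(1, (p.end or p.pos + 1) - p.pos)
                mito_points.append(p.mate_pos)
                mito_points.append((p.mate_pos + read_len - 1) % matcher.length)
        mito_interval = circular_interval_from_points(mito_points, matcher.length)
        calls.append(
            NumtCall(
                sample_id=sample_id,
                chrom=chrom,
                breakpoint_left=breakpoint_left,
                breakpoint_right=breakpoint_right,
                precise=precise,
                support=support,
                ref_support=ref_count,
                depth=depth,
                quality=gl.quality,
                genotype=gl.genotype,
                gq=gl.gq,
                log_likelihoods=list(gl.log_l),
                filters=apply_filters(gl.quality, support, depth, thresholds),
                mito_interval=mito_interval,
                ci=ci,
            )
        )
    return calls


def discover_sample(
    bam_path,
    mito_seq: str,
    mito_contig: str,
    known_numts=None,
    mapq_min: int = DEFAULT_MAPQ_MIN,
    thresholds: FilterThresholds | None = None,
    sample_id: str | None = None,
    model: InsertSizeModel | None = None,
):
    """Full per-sample discovery: extract, cluster, link, localize, score.

    Returns (calls, stats dict with per-stage counters, insert-size model).
    """
    from .insert_size import build_insert_size_model

    sample_id = sample_id or str(bam_path)
    with pysam.AlignmentFile(str(bam_path)) as bam:
        pairs = extract_candidate_pairs(
            bam, mito_contig, known_numts=known_numts,
            mapq_min=mapq_min, sample_id=sample_id,
        )
        if model is None and pairs:
            model = build_insert_size_model(bam.fetch())
        clusters = cluster_reads(pairs, model) if pairs else []
        linked = link_clusters(clusters, model) if clusters else []
        calls = (
            call_sites(
                bam, linked, model, mito_seq, sample_id=sample_id,
                thresholds=thresholds,
            )
            if linked
            else []
        )
    stats = {
        "pairs_extracted": len(pairs),
        "clusters": len(clusters),
        "linked_pairs": len(linked),
        "calls": len(calls),
        "pass_calls": sum(1 for c in calls if c.passed),
    }
    log.info("discovery %s: %s", sample_id, stats)
    return calls, stats, model
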