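"""Cohort-level pipeline: site merging, breakpoint refinement, EM genotyping.

Discovery runs per sample; sites found in any sample are then genotyped in
every sample, pooling soft-clip evidence across the cohort to refine the
breakpoint, counting reference-spanning vs insertion-supporting reads at
that position, and iterating Hardy-Weinberg population priors with EM.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pysam

from .discovery import (
    DEFAULT_MIN_CLIP,
    NumtCall,
    collect_softclips,
    discover_sample,
    extract_candidate_pairs,
)
from .genotype import (
    FilterThresholds,
    LikelihoodInput,
    count_reference_spanning,
    em_population_genotyping,
    genotype_sample,
    mapq_to_error,
)
from .insert_size import InsertSizeModel, build_insert_size_model
from .mito import CircularMatcher

log = logging.getLogger(__name__)


@dataclass
class CohortSite:
    chrom: str
    breakpoint_left: int
    precise: bool
    mito_interval: tuple | None = None
    ci: tuple = (0, 0)
    source_calls: list = field(default_factory=list)


def merge_sites(calls, model: InsertSizeModel):
    """Merge per-sample calls into cohort sites.

    Calls on the same chromosome within W_L of each other describe the same
    insertion; the representative breakpoint is the modal precise breakpoint
    when any sample localized one, otherwise the median estimate.
    """
    w_l = model.w_l
    sites = []
    for call in sorted(calls, key=lambda c: (c.chrom, c.breakpoint_left)):
        last = sites[-1] if sites else None
        if (
            last is not None
            and last.chrom == call.chrom
            and call.breakpoint_left - last.source_calls[-1].breakpoint_left <= w_l
        ):
            last.source_calls.append(call)
        else:
            sites.append(
                CohortSite(
                    chrom=call.chrom,
                    breakpoint_left=call.breakpoint_left,
                    precise=call.precise,
                    mito_interval=call.mito_interval,
                    ci=call.ci,
                    source_calls=[call],
                )
            )
    for site in sites:
        precise = [c for c in site.source_calls if c.precise]
        if precise:
            bp = Counter(c.breakpoint_left for c in precise).most_common()
            top = max(bp, key=lambda kv: (kv[1], -kv[0]))
            site.breakpoint_left = top[0]
            site.precise = True
            site.ci = (0, 0)
        else:
            site.breakpoint_left = int(
                np.median([c.breakpoint_left for c in site.source_calls])
            )
        for c in site.source_calls:
            if c.mito_interval is not None:
                site.mito_interval = c.mito_interval
                break
    return sites


def refine_breakpoint_cohort(
    bam_paths,
    site: CohortSite,
    mito_seq,
    model: InsertSizeModel,
    min_clip: int = DEFAULT_MIN_CLIP,
    min_identity: float = 0.9,
) -> CohortSite:
    """Pool soft-clips across samples to pin down the cohort breakpoint.

    The modal identical break position whose longest clipped tail realigns to
    the mitochondrial sequence becomes the refined breakpoint; without such
    evidence the discovery estimate is kept (site stays imprecise).
    """
    matcher = mito_seq if isinstance(mito_seq, CircularMatcher) else CircularMatcher(mito_seq)
    w_l = int(round(model.w_l))
    clips = []
    for path in bam_paths:
        with pysam.AlignmentFile(str(path)) as bam:
            clips.extend(
                collect_softclips(
                    bam,
                    site.chrom,
                    site.breakpoint_left - w_l,
                    site.breakpoint_left + w_l + 1,
                    min_clip=min_clip,
                )
            )
    if not clips:
        return site
    counts = Counter(c[0] for c in clips)
    for break_pos, _n in sorted(
        counts.items(), key=lambda kv: (-kv[1], kv[0])
    ):
        tails = [c[1] for c in clips if c[0] == break_pos]
        longest = max(tails, key=len)
        ident, _off, _strand = matcher.best_match(longest)
        if ident >= min_identity:
            site.breakpoint_left = break_pos - 1
            site.precise = True
            site.ci = (0, 0)
            return site
    return site


def collect_site_evidence(
    bam,
    site: CohortSite,
    model: InsertSizeModel,
    mito_contig: str,
    known_numts=None,
    mapq_min: int = 10,
    min_clip: int = DEFAULT_MIN_CLIP,
    clip_tolerance: int = 5,
) -> LikelihoodInput:
    """Assemble per-sample read evidence at one cohort site.

    Insertion support: mito-anchored pairs whose anchor is correctly oriented
    within W_L of the breakpoint, plus soft-clipped reads breaking at the
    refined position. Reference support: reads spanning the junction
    unbroken. Mapping qualities become per-read error probabilities.
    """
    bp = site.breakpoint_left
    w_l = int(round(model.w_l))
    first_after = bp + 1
    pairs = extract_candidate_pairs(
        bam,
        mito_contig,
        known_numts=known_numts,
        mapq_min=mapq_min,
        region=(site.chrom, max(0, bp - 2 * w_l), bp + 2 * w_l),
    )
    alt = {}
    for p in pairs:
        if p.strand == "+" and bp - w_l <= p.pos <= first_after:
            alt.setdefault(p.read_name, mapq_to_error(p.mapq))
        elif p.strand == "-" and bp <= p.end <= first_after + w_l:
            alt.setdefault(p.read_name, mapq_to_error(p.mapq))
    for break_pos, _tail, mapq, name in collect_softclips(
        bam, site.chrom, max(0, bp - w_l), bp + w_l + 1, min_clip=min_clip
    ):
        if abs(break_pos - first_after) <= clip_tolerance:
            alt.setdefault(name, mapq_to_error(mapq))
    _n_ref, ref_mapqs = count_reference_spanning(
        bam, site.chrom, bp, min_clip=min_clip
    )
    return LikelihoodInput(
        ref_errors=[mapq_to_error(q) for q in ref_mapqs],
        alt_errors=list(alt.values()),
    )


@dataclass
class SiteGenotypes:
    site: CohortSite
    allele_frequency: float
    genotypes: dict  # sample id -> GenotypeLikelihoods
    evidence: dict  # sample id -> LikelihoodInput
    em_iterations: int
    em_converged: bool


@dataclass
class CohortResult:
    sites: list
    samples: list
    model: InsertSizeModel


def genotype_cohort(
    bam_paths: dict,
    sites,
    mito_seq: str,
    mito_contig: str,
    known_numts=None,
    model: InsertSizeModel | None = None,
    max_em_iter: int = 10,
    em_tol: float = 1e-4,
    mapq_min: int = 10,
) -> CohortResult:
    """Genotype every sample at every cohort site with EM population priors."""
    samples = sorted(bam_paths)
    if not samples:
        raise ValueError("empty cohort")
    if model is None:
        with pysam.AlignmentFile(str(bam_paths[samples[0]])) as bam:
            model = build_insert_size_model(bam.fetch())
    matcher = CircularMatcher(mito_seq)
    out_sites = []
    for site in sites:
        site = refine_breakpoint_cohort(
            [bam_paths[s] for s in samples], site, matcher, model
        )
        evidence = {}
        for s in samples:
            with pysam.AlignmentFile(str(bam_paths[s])) as bam:
                evidence[s] = collect_site_evidence(
                    bam, site, model, mito_contig,
                    known_numts=known_numts, mapq_min=mapq_min,
                )
        from .genotype import all_log_likelihoods, PopulationPrior

        ll = np.vstack([all_log_likelihoods(evidence[s]) for s in samples])
        em = em_population_genotyping(ll, max_iter=max_em_iter, tol=em_tol)
        prior = PopulationPrior(em.allele_frequency)
        genotypes = {
            s: genotype_sample(evidence[s], prior=prior) for s in samples
        }
        out_sites.append(
            SiteGenotypes(
                site=site,
                allele_frequency=em.allele_frequency,
                genotypes=genotypes,
                evidence=evidence,
                em_iterations=em.n_iter,
                em_converged=em.converged,
            )
        )
    return CohortResult(sites=out_sites, samples=samples, model=model)


def discover_cohort(
    bam_paths: dict,
    mito_seq: str,
    mito_contig: str,
    known_numts=None,
    thresholds: FilterThresholds | None = None,
    mapq_min: int = 10,
):
    """Run discovery in every sample; returns (all calls, shared model)."""
    all_calls: list[NumtCall] = []
    model = None
    for sample_id in sorted(bam_paths):
        calls, _stats, sample_model = discover_sample(
            bam_paths[sample_id],
            mito_seq,
            mito_contig,
            known_numts=known_numts,
            mapq_min=mapq_min,
            thresholds=thresholds,
            sample_id=sample_id,
            model=None,
        )
        if sample_model is not None:
            model = sample_model
        all_calls.extend(calls)
    return all_calls, model
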