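"""Genotype likelihoods, call quality, filtering and cohort EM genotyping.

The model treats every informative read at a candidate insertion as an
independent draw from one of ``m`` chromosome copies (ploidy), of which
``g`` carry the insertion. With per-read mapping-error probabilities
``e_j`` the likelihood of genotype ``g`` is

    L(g) = m^{-k} * prod_{ref reads} [(m-g)(1-e_j) + g e_j]
                  * prod_{alt reads} [(m-g) e_j + g (1-e_j)]

where ``k`` is the total number of informative reads (reference-supporting
plus insertion-supporting). All arithmetic is done in log space so large
read counts cannot underflow.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

E_MIN = 1e-6
E_MAX = 0.5
QUALITY_CAP = 99.99
GQ_CAP = 99


def mapq_to_error(mapq) -> float:
    """Convert a Phred mapping quality to an error probability in [1e-6, 0.5]."""
    e = 10.0 ** (-float(mapq) / 10.0)
    return min(max(e, E_MIN), E_MAX)


@dataclass
class LikelihoodInput:
    """Per-read mapping-error probabilities split by the allele they support."""

    ref_errors: np.ndarray
    alt_errors: np.ndarray
    ploidy: int = 2

    def __post_init__(self):
        self.ref_errors = np.asarray(self.ref_errors, dtype=float)
        self.alt_errors = np.asarray(self.alt_errors, dtype=float)
        if ((self.ref_errors < 0) | (self.ref_errors > 1)).any() or (
            (self.alt_errors < 0) | (self.alt_errors > 1)
        ).any():
            raise ValueError("error probabilities must lie in [0, 1]")

    @property
    def n_ref(self) -> int:
        return self.ref_errors.size

    @property
    def n_alt(self) -> int:
        return self.alt_errors.size

    @property
    def n_total(self) -> int:
        return self.n_ref + self.n_alt


def genotype_log_likelihood(inp: LikelihoodInput, g: int) -> float:
    """log L(g); -inf when any factor is exactly zero."""
    m = inp.ploidy
    if not 0 <= g <= m:
        raise ValueError(f"genotype {g} outside [0, {m}]")
    k = inp.n_total
    ref_factors = (m - g) * (1.0 - inp.ref_errors) + g * inp.ref_errors
    alt_factors = (m - g) * inp.alt_errors + g * (1.0 - inp.alt_errors)
    factors = np.concatenate([ref_factors, alt_factors])
    if (factors <= 0).any():
        return -math.inf
    return -k * math.log(m) + float(np.log(factors).sum())


def genotype_likelihood(inp: LikelihoodInput, g: int) -> float:
    """L(g) on the linear scale."""
    return math.exp(genotype_log_likelihood(inp, g))


def all_log_likelihoods(inp: LikelihoodInput) -> np.ndarray:
    return np.array(
        [genotype_log_likelihood(inp, g) for g in range(inp.ploidy + 1)]
    )


def _logsumexp(logs: np.ndarray) -> float:
    mx = np.max(logs)
    if mx == -math.inf:
        return -math.inf
    return float(mx + np.log(np.exp(logs - mx).sum()))


def insertion_quality(log_l: np.ndarray) -> float:
    """Phred-scaled confidence that at least one insertion allele is present.

    quality = -10 log10( L(0) / sum_g L(g) ) under a flat prior, capped at
    99.99 when L(0) vanishes numerically.
    """
    log_l = np.asarray(log_l, dtype=float)
    total = _logsumexp(log_l)
    if total == -math.inf:
        raise ValueError("degenerate likelihoods")
    if log_l[0] == -math.inf:
        return QUALITY_CAP
    q = -10.0 * (log_l[0] - total) / math.log(10.0)
    return min(q, QUALITY_CAP)


@dataclass(frozen=True)
class PopulationPrior:
    """Hardy-Weinberg genotype prior from a population allele frequency."""

    allele_frequency: float
    ploidy: int = 2

    def genotype_prior(self) -> np.ndarray:
        p = self.allele_frequency
        if self.ploidy == 2:
            return np.array([(1 - p) ** 2, 2 * p * (1 - p), p**2])
        # binomial(m, p) for general ploidy
        m = self.ploidy
        return np.array(
            [math.comb(m, g) * p**g * (1 - p) ** (m - g) for g in range(m + 1)]
        )


@dataclass
class GenotypeLikelihoods:
    """Per-genotype likelihoods, posterior and the called genotype."""

    log_l: np.ndarray
    posterior: np.ndarray
    genotype_index: int
    gq: float
    quality: float

    @property
    def likelihoods(self) -> np.ndarray:
        return np.exp(self.log_l)

    @property
    def genotype(self) -> str:
        m = len(self.log_l) - 1
        g = self.genotype_index
        if m == 1:
            return str(g)
        return "/".join(["0"] * (m - g) + ["1"] * g)


def genotype_sample(
    inp: LikelihoodInput, prior: PopulationPrior | None = None
) -> GenotypeLikelihoods:
    """Posterior genotype call: posterior(g) proportional to prior(g) L(g)."""
    log_l = all_log_likelihoods(inp)
    if prior is None:
        log_prior = np.zeros_like(log_l)
    else:
        pr = prior.genotype_prior()
        with np.errstate(divide="ignore"):
            log_prior = np.log(pr)
    log_post = log_l + log_prior
    total = _logsumexp(log_post)
    if total == -math.inf:
        raise ValueError("degenerate likelihoods")
    posterior = np.exp(log_post - total)
    posterior /= posterior.sum()
    g = int(np.argmax(posterior))
    err = max(1.0 - posterior[g], 1e-100)
    gq = min(-10.0 * math.log10(err), GQ_CAP)
    return GenotypeLikelihoods(
        log_l=log_l,
        posterior=posterior,
        genotype_index=g,
        gq=gq,
        quality=insertion_quality(log_l),
    )


@dataclass(frozen=True)
class FilterThresholds:
    """Site filters; defaults are the published thresholds."""

    min_quality: float = 50.0
    min_reads: int = 4
    min_depth: int = 5


def apply_filters(
    quality: float,
    support: int,
    depth: int,
    thresholds: FilterThresholds = FilterThresholds(),
) -> list[str]:
    """Return the list of failed filters (empty list means PASS)."""
    failed = []
    if quality < thresholds.min_quality:
        failed.append("min-quality")
    if support < thresholds.min_reads:
        failed.append("min-reads")
    if depth < thresholds.min_depth:
        failed.append("min-depth")
    return failed


# ---------------------------------------------------------------------------
# Read-level evidence at a refined breakpoint
# ---------------------------------------------------------------------------


def count_reference_spanning(
    bam, chrom: str, breakpoint_left: int, anchor: int = 20, min_clip: int = 20
):
    """Reads spanning the insertion junction unbroken, supporting reference.

    A read counts if it is primary and non-duplicate, carries no soft clip of
    ``min_clip`` or more, and aligns continuously with at least ``anchor``
    bases on each side of the junction between ``breakpoint_left`` and the
    next reference base. Returns (count, list of MAPQs).
    """
    first_after = breakpoint_left + 1
    mapqs = []
    for read in bam.fetch(
        chrom, max(0, breakpoint_left - anchor), first_after + anchor
    ):
        if read.is_secondary or read.is_supplementary or read.is_duplicate:
            continue
        if read.is_unmapped:
            continue
        cig = read.cigartuples or []
        if any(op == 4 and ln >= min_clip for op, ln in cig):
            continue
        if (
            read.reference_start <= breakpoint_left - anchor + 1
            and read.reference_end >= first_after + anchor
        ):
            mapqs.append(read.mapping_quality)
    return len(mapqs), mapqs


# ---------------------------------------------------------------------------
# Cohort EM on population allele frequency
# ---------------------------------------------------------------------------


@dataclass
class EMResult:
    allele_frequency: float
    posteriors: np.ndarray  # (N, m+1)
    genotype_indices: np.ndarray  # (N,)
    n_iter: int
    converged: bool


def em_population_genotyping(
    log_likelihoods,
    max_iter: int = 10,
    tol: float = 1e-4,
    ploidy: int = 2,
) -> EMResult:
    """EM estimate of the insertion allele frequency across a cohort.

    ``log_likelihoods`` is an (N, m+1) array of per-sample log L(g). The
    E-step computes genotype posteriors under the current Hardy-Weinberg
    prior; the M-step updates the frequency from posterior-weighted allele
    counts with a single pseudo-allele on each side, so the estimate is
    bounded away from 0 and 1 by 1/(m N + 2).
    """
    ll = np.asarray(log_likelihoods, dtype=float)
    if ll.ndim != 2 or ll.shape[0] == 0:
        raise ValueError("empty cohort")
    n, _ = ll.shape
    g = np.arange(ploidy + 1)

    def posteriors(af):
        pr = PopulationPrior(af, ploidy).genotype_prior()
        with np.errstate(divide="ignore"):
            lp = ll + np.log(pr)
        mx = lp.max(axis=1, keepdims=True)
        w = np.exp(lp - mx)
        return w / w.sum(axis=1, keepdims=True)

    # flat-prior initialization
    post = posteriors(0.5)
    af = ((post @ g).sum() + 1.0) / (ploidy * n + 2.0)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        post = posteriors(af)
        af_new = ((post @ g).sum() + 1.0) / (ploidy * n + 2.0)
        if abs(af_new - af) < tol:
            af = af_new
            converged = True
            break
        af = af_new
    post = posteriors(af)
    return EMResult(
        allele_frequency=float(af),
        posteriors=post,
        genotype_indices=post.argmax(axis=1),
        n_iter=it,
        converged=converged,
    )
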