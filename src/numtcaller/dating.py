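"""Insertion dating by diagnostic substitutions and heteroplasmy screening.

A Numt that integrated t million years ago froze a snapshot of the
mitochondrial lineage of its era. At alignment columns where the modern
human mitochondrial sequence differs from an inferred human-chimp ancestral
sequence ("diagnostic positions"), the fraction of Numt alleles matching
the modern sequence places the insertion along the human lineage:

    age (MYA) = (1 - pct_modern/100) * divergence

with divergence = 6 MY between human and chimpanzee. The matching
percentage is rounded half-to-even to an integer before the
multiplication; a 100% match is reported as "<0.1" MYA and a Numt covering
no diagnostic positions cannot be dated.

Numt-vs-mtDNA substitution profiles are also compared against published
heteroplasmy tables: a reported heteroplasmic position whose minor allele
equals the Numt allele may be a Numt artifact rather than true
heteroplasmy.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction

import edlib
import pandas as pd
from Bio import Align

from .mito import revcomp

DIVERGENCE_MYA = 6.0


# ---------------------------------------------------------------------------
# Alignments
# ---------------------------------------------------------------------------


def align_pair(a: str, b: str):
    """Deterministic affine-gap global alignment; returns gapped strings."""
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 2
    aligner.mismatch_score = -1
    aligner.open_gap_score = -5
    aligner.extend_gap_score = -0.5
    aln = aligner.align(a.upper(), b.upper())[0]
    return str(aln[0]), str(aln[1])


def _align_to_circular(query: str, target: str):
    """Place ``query`` on the circular ``target`` (both strands, gapped).

    Returns (identity, {0-based target pos -> query base}, strand) from the
    best edit-distance placement against the doubled target.
    """
    doubled = (target + target).upper()
    L = len(target)
    best = None
    for strand, q in (("+", query.upper()), ("-", revcomp(query.upper()))):
        res = edlib.align(q, doubled, mode="HW", task="path")
        s0, e0 = res["locations"][0]
        # A run of substitutions flanked by coincidental context matches can
        # be rewritten by the aligner as a cost-equal deletion+insertion
        # pair, erasing the substitutions. Numts are ungapped copies, so
        # when an ungapped placement is at least as parsimonious as the
        # gapped optimum it is preferred.
        ungapped = None
        for off in {s0, e0 + 1 - len(q)}:
            seg = doubled[off : off + len(q)] if off >= 0 else ""
            if len(seg) != len(q):
                continue
            ham = sum(a != b for a, b in zip(q, seg))
            if ungapped is None or ham < ungapped[0]:
                ungapped = (ham, off)
        if ungapped is not None and ungapped[0] <= res["editDistance"]:
            ham, off = ungapped
            ident = 1.0 - ham / len(q) if q else 0.0
            placement = ("ungapped", q, off)
        else:
            nice = edlib.getNiceAlignment(res, q, doubled)
            cols = len(nice["matched_aligned"])
            ident = nice["matched_aligned"].count("|") / cols if cols else 0.0
            placement = ("gapped", nice, s0)
        if best is None or ident > best[0]:
            best = (ident, placement, strand)
    ident, placement, strand = best
    if placement[0] == "ungapped":
        _, q, off = placement
        return ident, {(off + i) % L: b for i, b in enumerate(q)}, strand
    _, nice, tpos = placement
    q_aln, t_aln = nice["query_aligned"], nice["target_aligned"]
    # A terminal query base mismatching the target costs the same whether
    # the aligner writes it as a substitution or as a terminal insertion.
    # On a circular target the insertion reading is a linearization
    # artifact, so terminal target-gap columns are re-anchored onto the
    # adjacent circle bases as substitutions.
    lead = 0
    while lead < len(t_aln) and t_aln[lead] == "-":
        lead += 1
    trail = 0
    while trail < len(t_aln) - lead and t_aln[-1 - trail] == "-":
        trail += 1
    by_pos = {}
    for i in range(lead):
        by_pos[(tpos - lead + i) % L] = q_aln[i]
    for i in range(lead, len(t_aln) - trail):
        qb, tb = q_aln[i], t_aln[i]
        if tb != "-":
            if qb != "-":
                by_pos[tpos % L] = qb
            tpos += 1
    for j in range(trail):
        by_pos[(tpos + j) % L] = q_aln[len(t_aln) - trail + j]
    return ident, by_pos, strand


# ---------------------------------------------------------------------------
# Diagnostic positions and the three-way alignment
# ---------------------------------------------------------------------------


def diagnostic_sites(modern: str, ancestral: str, region=None):
    """1-based modern-mtDNA positions where modern and ancestral differ.

    Only substitution columns count; indel columns are excluded. ``modern``
    and ``ancestral`` may be pre-aligned gapped strings of equal length,
    equal-length raw sequences (compared column-wise), or raw sequences of
    different lengths (aligned here). ``region`` restricts to a 1-based
    inclusive (start, end) interval in modern coordinates.
    """
    modern, ancestral = modern.upper(), ancestral.upper()
    if len(modern) != len(ancestral):
        modern, ancestral = align_pair(modern, ancestral)
    sites = []
    pos = 0
    for mb, ab in zip(modern, ancestral):
        if mb != "-":
            pos += 1
            if ab not in ("-",) and mb != ab:
                sites.append(pos)
    if region is not None:
        lo, hi = region
        sites = [p for p in sites if lo <= p <= hi]
    return sites


@dataclass
class ThreeWayAlignment:
    """Numt placed onto the fixed modern/ancestral mitochondrial alignment."""

    modern: str  # ungapped modern sequence
    numt_base_by_pos: dict  # 1-based modern position -> numt base
    identity: float
    strand: str

    @classmethod
    def build(cls, numt_seq: str, modern: str):
        ident, by_pos0, strand = _align_to_circular(numt_seq, modern)
        return cls(
            modern=modern.upper(),
            numt_base_by_pos={p + 1: b for p, b in by_pos0.items()},
            identity=ident,
            strand=strand,
        )


def match_modern(alignment: ThreeWayAlignment, sites):
    """Count (diagnostic positions covered by the Numt, matches to modern).

    Columns where the Numt has a gap are excluded from both counts.
    """
    n_diag = 0
    n_match = 0
    for pos in sites:
        numt_base = alignment.numt_base_by_pos.get(pos)
        if numt_base is None:
            continue
        n_diag += 1
        if numt_base == alignment.modern[pos - 1]:
            n_match += 1
    return n_diag, n_match


# ---------------------------------------------------------------------------
# Age estimation
# ---------------------------------------------------------------------------


@dataclass
class DatingResult:
    numt_id: str
    n_diagnostic: int
    n_match_modern: int
    pct_modern: int | None  # integer percent, half-to-even
    age_mya: float | None
    age_label: str  # "<0.1", "NA" or the numeric value as printed

    def as_row(self):
        return {
            "numt_id": self.numt_id,
            "n_diagnostic": self.n_diagnostic,
            "n_match_modern": self.n_match_modern,
            "pct_modern": self.pct_modern,
            "age_mya": self.age_label,
        }


def estimate_age(
    n_diagnostic: int,
    n_match_modern: int,
    divergence_mya: float = DIVERGENCE_MYA,
    numt_id: str = "",
) -> DatingResult:
    """Allele-matching-ratio age estimate.

    The matching percentage is rounded half-to-even to an integer (exact
    rational arithmetic, no float half-cases), then
    age = (1 - pct/100) * divergence. 100% matches report "<0.1"; without
    diagnostic positions the age is undefined ("NA").
    """
    if n_diagnostic < 0 or not 0 <= n_match_modern <= max(n_diagnostic, 0):
        raise ValueError("invalid diagnostic counts")
    if n_diagnostic == 0:
        return DatingResult(numt_id, 0, 0, None, None, "NA")
    pct = round(Fraction(100 * n_match_modern, n_diagnostic))
    age = round((100 - pct) * divergence_mya / 100.0, 2)
    label = "<0.1" if pct == 100 else f"{age:g}"
    return DatingResult(numt_id, n_diagnostic, n_match_modern, pct, age, label)


def date_numts(numts: dict, modern: str, ancestral: str,
               divergence_mya: float = DIVERGENCE_MYA) -> pd.DataFrame:
    """Date a set of Numt sequences against modern/ancestral mtDNA.

    ``numts`` maps id -> sequence. Returns a table with one row per Numt:
    diagnostic positions covered, matches to modern, percent and age.
    """
    modern_aln, ancestral_aln = align_pair(modern, ancestral)
    sites = diagnostic_sites(modern_aln, ancestral_aln)
    rows = []
    for numt_id, seq in numts.items():
        tw = ThreeWayAlignment.build(seq, modern)
        n_diag, n_match = match_modern(tw, sites)
        rows.append(
            estimate_age(n_diag, n_match, divergence_mya, numt_id=numt_id).as_row()
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# SNP profiles and heteroplasmy screening
# ---------------------------------------------------------------------------


@dataclass
class NumtSnpProfile:
    numt_id: str
    variants: list  # (1-based mtDNA position, mtDNA allele, numt allele)


def snp_profile(
    numt_seq: str, modern: str, numt_id: str = "", min_identity: float = 0.9
) -> NumtSnpProfile:
    """Single-nucleotide differences of a Numt relative to modern mtDNA.

    The Numt must place on the (circular) mitochondrial sequence at
    >= ``min_identity``; anything lower is rejected as not of recent
    mitochondrial origin.
    """
    ident, by_pos0, _strand = _align_to_circular(numt_seq, modern)
    if ident < min_identity:
        raise ValueError("not of recent mitochondrial origin")
    modern = modern.upper()
    variants = [
        (pos + 1, modern[pos], base)
        for pos, base in sorted(by_pos0.items())
        if base != modern[pos]
    ]
    return NumtSnpProfile(numt_id=numt_id, variants=variants)


def match_heteroplasmy(profile: NumtSnpProfile, reported: pd.DataFrame) -> pd.DataFrame:
    """Rows of ``reported`` whose position AND allele match the Numt profile.

    ``reported`` needs columns 'position' (1-based mtDNA), 'allele' (the
    heteroplasmic allele) and 'study'; extra columns pass through.
    """
    if reported.empty or not profile.variants:
        return reported.iloc[0:0].assign(numt_id=pd.Series(dtype=str),
                                         mtdna_allele=pd.Series(dtype=str))
    prof = pd.DataFrame(
        profile.variants, columns=["position", "mtdna_allele", "numt_allele"]
    )
    prof["numt_allele"] = prof["numt_allele"].str.upper()
    rep = reported.copy()
    rep["allele"] = rep["allele"].str.upper()
    merged = rep.merge(
        prof, left_on=["position", "allele"],
        right_on=["position", "numt_allele"], how="inner",
    )
    merged["numt_id"] = profile.numt_id
    return merged.drop(columns=["numt_allele"])
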