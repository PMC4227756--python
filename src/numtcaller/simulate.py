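"""Synthetic paired-end fixtures with implanted mitochondrial insertions.

The simulator builds a random nuclear contig and a random circular
mitochondrial contig, implants mitochondrial fragments into per-sample
diploid haplotypes, samples paired-end fragments with Normal insert sizes,
and then *projects* each read back onto the un-inserted reference the way an
idealized aligner would: reads wholly in nuclear flank align normally
(MAPQ 60), reads wholly inside the insert align to the mitochondrial contig
(modulo circularity), and junction-spanning reads are soft-clipped at the
breakpoint with their clipped bases preserved. That reproduces the exact
signal pattern the caller consumes without requiring an external aligner.

Limitations (deliberate): no sequencing indels, flat substitution error,
no target-site duplications, no post-insertion rearrangements.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import pysam

from .mito import circular_length, circular_slice, revcomp

BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class NumtSpec:
    """One implanted insertion: where, what mito fragment, and zygosity.

    ``mito_end <= mito_start`` denotes an origin-wrapping fragment. Either a
    fixed ``genotype`` ('0/0', '0/1', '1/1') or a population
    ``allele_frequency`` (haplotypes drawn i.i.d.) must be given.
    """

    nuclear_pos: int
    mito_start: int
    mito_end: int
    strand: str = "+"
    genotype: str | None = None
    allele_frequency: float | None = None
    site_id: str = "numt_1"


@dataclass
class SimConfig:
    nuclear_length: int = 50_000
    mito_length: int = 16_569
    numts: list = field(default_factory=list)
    coverage: float = 10.0
    read_length: int = 100
    insert_mean: float = 350.0
    insert_sd: float = 50.0
    base_error: float = 0.001
    seed: int = 1
    n_samples: int = 1
    nuclear_name: str = "chr20"
    mito_name: str = "chrM"
    repeat_flank: tuple | None = None  # nuclear (start, end) mapped with MAPQ 0
    base_quality: int = 35

    def __post_init__(self):
        if self.coverage <= 0:
            raise ValueError("coverage must be positive")


@dataclass(frozen=True)
class Segment:
    """Contiguous haplotype block mapping to one reference interval.

    For strand '+' the reference coordinate of haplotype position h is
    ``ref_lo + (h - hap_start)``; for '-' it is
    ``ref_lo + (hap_end - 1 - h)`` and the block aligns to the reverse
    strand. Mitochondrial fragments are pre-split at the origin so no
    segment ever wraps.
    """

    hap_start: int
    hap_end: int
    ref_name: str
    ref_lo: int
    strand: str = "+"


def random_sequence(length: int, rng) -> str:
    return rng.choice(BASES, size=length).tobytes().decode("ascii")


def _mito_segments(spec: NumtSpec, hap_pos: int, mito_len: int, mito_name: str):
    """Non-wrapping segments for one (possibly origin-spanning) fragment."""
    ms, me = spec.mito_start % mito_len, spec.mito_end
    frag_len = circular_length(ms, me, mito_len)
    wraps = ms + frag_len > mito_len
    if not wraps:
        parts = [(ms, frag_len)]
    else:
        parts = [(ms, mito_len - ms), (0, frag_len - (mito_len - ms))]
    if spec.strand == "-":
        parts = parts[::-1]
    segs = []
    for lo, ln in parts:
        segs.append(Segment(hap_pos, hap_pos + ln, mito_name, lo, spec.strand))
        hap_pos += ln
    return segs, frag_len


def implant_numt(nuclear_seq: str, mito_seq: str, spec: NumtSpec,
                 nuclear_name: str = "chr20", mito_name: str = "chrM"):
    """Insert one mitochondrial fragment; returns (haplotype, junction map)."""
    return build_haplotype(nuclear_seq, mito_seq, [spec], nuclear_name, mito_name)


def build_haplotype(nuclear_seq: str, mito_seq: str, specs,
                    nuclear_name: str = "chr20", mito_name: str = "chrM"):
    """Haplotype sequence plus its segment (junction) map for a set of numts."""
    specs = sorted(specs, key=lambda s: s.nuclear_pos)
    mito_len = len(mito_seq)
    pieces, segments = [], []
    cur_ref = 0
    hap_pos = 0
    for spec in specs:
        if not 0 <= spec.nuclear_pos <= len(nuclear_seq):
            raise ValueError("nuclear position out of bounds")
        flank = nuclear_seq[cur_ref : spec.nuclear_pos]
        if flank:
            segments.append(Segment(hap_pos, hap_pos + len(flank),
                                    nuclear_name, cur_ref, "+"))
            pieces.append(flank)
            hap_pos += len(flank)
        frag = circular_slice(mito_seq, spec.mito_start, spec.mito_end)
        if spec.strand == "-":
            frag = revcomp(frag)
        frag_segs, _ = _mito_segments(spec, hap_pos, mito_len, mito_name)
        segments.extend(frag_segs)
        pieces.append(frag)
        hap_pos += len(frag)
        cur_ref = spec.nuclear_pos
    tail = nuclear_seq[cur_ref:]
    if tail:
        segments.append(Segment(hap_pos, hap_pos + len(tail),
                                nuclear_name, cur_ref, "+"))
        pieces.append(tail)
    return "".join(pieces), segments


@dataclass
class SimPair:
    name: str
    hap_index: int
    start: int
    insert_length: int
    seq1: str  # forward haplotype substring at [start, start+rl)
    seq2: str  # forward haplotype substring at [end-rl, end)


def _mutate(seq: str, rng, rate: float) -> str:
    if rate <= 0:
        return seq
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8).copy()
    hits = np.nonzero(rng.random(arr.size) < rate)[0]
    for i in hits:
        choices = BASES[BASES != arr[i]]
        arr[i] = rng.choice(choices)
    return arr.tobytes().decode("ascii")


def simulate_pairs(haplotypes, config: SimConfig, rng, sample_id: str = "S0"):
    """Sample read pairs uniformly from a diploid pair of haplotypes.

    Insert lengths are Normal(insert_mean, insert_sd) truncated below at the
    read length; heterozygous samples draw each fragment's haplotype 50/50.
    """
    rl = config.read_length
    if config.insert_mean < rl:
        raise ValueError("insert_mean must be at least read_length")
    mean_len = sum(len(h) for h, _ in haplotypes) / len(haplotypes)
    n_pairs = int(round(config.coverage * mean_len / (2 * rl)))
    pairs = []
    for i in range(n_pairs):
        h = int(rng.integers(len(haplotypes)))
        hap_len = len(haplotypes[h][0])
        ins = int(round(rng.normal(config.insert_mean, config.insert_sd)))
        ins = max(rl, min(ins, hap_len))
        start = int(rng.integers(0, hap_len - ins + 1))
        seq1 = haplotypes[h][0][start : start + rl]
        seq2 = haplotypes[h][0][start + ins - rl : start + ins]
        pairs.append(
            SimPair(
                name=f"{sample_id}.p{i}",
                hap_index=h,
                start=start,
                insert_length=ins,
                seq1=_mutate(seq1, rng, config.base_error),
                seq2=_mutate(seq2, rng, config.base_error),
            )
        )
    return pairs


@dataclass
class Placement:
    ref_name: str
    pos: int
    left_clip: int
    match: int
    right_clip: int
    flip: bool  # True: record goes out reverse-complemented

    @property
    def cigartuples(self):
        out = []
        if self.left_clip:
            out.append((4, self.left_clip))
        out.append((0, self.match))
        if self.right_clip:
            out.append((4, self.right_clip))
        return out

    @property
    def end(self):
        return self.pos + self.match


def project_read(a: int, b: int, segments) -> Placement:
    """Idealized alignment of haplotype interval [a, b) onto the reference.

    The segment with the longest overlap hosts the aligned block; bases
    falling outside it are soft-clipped, exactly as an aligner would place a
    junction-spanning read.
    """
    best, best_ov = None, -1
    for seg in segments:
        ov = min(b, seg.hap_end) - max(a, seg.hap_start)
        if ov > best_ov:
            best, best_ov = seg, ov
    seg = best
    oa, ob = max(a, seg.hap_start), min(b, seg.hap_end)
    if seg.strand == "+":
        return Placement(
            ref_name=seg.ref_name,
            pos=seg.ref_lo + (oa - seg.hap_start),
            left_clip=oa - a,
            match=ob - oa,
            right_clip=b - ob,
            flip=False,
        )
    return Placement(
        ref_name=seg.ref_name,
        pos=seg.ref_lo + (seg.hap_end - ob),
        left_clip=b - ob,
        match=ob - oa,
        right_clip=oa - a,
        flip=True,
    )


def project_alignments(pairs, segments, config: SimConfig, header):
    """Turn simulated pairs into pysam records against the clean reference."""
    rl = config.read_length
    max_proper = config.insert_mean + 10 * config.insert_sd
    records = []
    for pair in pairs:
        a1, b1 = pair.start, pair.start + rl
        a2, b2 = pair.start + pair.insert_length - rl, pair.start + pair.insert_length
        p1 = project_read(a1, b1, segments[pair.hap_index])
        p2 = project_read(a2, b2, segments[pair.hap_index])
        proper = (
            p1.ref_name == p2.ref_name == config.nuclear_name
            and 0 < abs(max(p2.end, p1.end) - min(p1.pos, p2.pos)) <= max_proper
        )
        for idx, (placement, seq, hap_reverse) in enumerate(
            [(p1, pair.seq1, False), (p2, pair.seq2, True)]
        ):
            mate = p2 if idx == 0 else p1
            mate_hap_reverse = not hap_reverse
            rec = pysam.AlignedSegment(header=header)
            rec.query_name = pair.name
            rec.reference_name = placement.ref_name
            rec.reference_start = placement.pos
            rec.cigartuples = placement.cigartuples
            rec.mapping_quality = _mapq(placement, config)
            rec.query_sequence = revcomp(seq) if placement.flip else seq
            rec.query_qualities = pysam.qualitystring_to_array(
                chr(config.base_quality + 33) * rl
            )
            rec.is_paired = True
            rec.is_read1 = idx == 0
            rec.is_read2 = idx == 1
            rec.is_reverse = hap_reverse ^ placement.flip
            rec.mate_is_reverse = mate_hap_reverse ^ mate.flip
            rec.next_reference_name = mate.ref_name
            rec.next_reference_start = mate.pos
            rec.is_proper_pair = proper
            if p1.ref_name == p2.ref_name:
                span = max(p1.end, p2.end) - min(p1.pos, p2.pos)
                if placement.pos < mate.pos or (
                    placement.pos == mate.pos and idx == 0
                ):
                    rec.template_length = span
                else:
                    rec.template_length = -span
            records.append(rec)
    return records


def _mapq(placement: Placement, config: SimConfig) -> int:
    if (
        config.repeat_flank is not None
        and placement.ref_name == config.nuclear_name
        and placement.pos < config.repeat_flank[1]
        and placement.end > config.repeat_flank[0]
    ):
        return 0
    return 60


# ---------------------------------------------------------------------------
# Fixture assembly
# ---------------------------------------------------------------------------


@dataclass
class SimulationResult:
    config: SimConfig
    out_dir: Path
    reference_fasta: Path
    bam_paths: dict  # sample id -> Path
    truth: pd.DataFrame  # one row per (site, sample) with genotype
    nuclear_seq: str
    mito_seq: str


def _draw_genotype(spec: NumtSpec, rng) -> tuple:
    """Allele per haplotype (h0, h1) as 0/1 ints."""
    if spec.genotype is not None:
        alleles = [int(x) for x in spec.genotype.split("/")]
        if len(alleles) != 2:
            raise ValueError(f"bad genotype {spec.genotype!r}")
        return tuple(alleles)
    if spec.allele_frequency is None:
        raise ValueError("spec needs genotype or allele_frequency")
    return tuple(int(rng.random() < spec.allele_frequency) for _ in range(2))


def write_fixture(config: SimConfig, out_dir) -> SimulationResult:
    """Generate the full fixture: reference, per-sample BAMs, truth tables.

    Everything is driven by ``config.seed``; identical configs produce
    identical files.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    nuclear_seq = random_sequence(config.nuclear_length, rng)
    mito_seq = random_sequence(config.mito_length, rng)

    ref_path = out_dir / "reference.fa"
    with open(ref_path, "w") as fh:
        for name, seq in [
            (config.nuclear_name, nuclear_seq),
            (config.mito_name, mito_seq),
        ]:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 60):
                fh.write(seq[i : i + 60] + "\n")
    pysam.faidx(str(ref_path))

    header = pysam.AlignmentHeader.from_dict(
        {
            "HD": {"VN": "1.6", "SO": "coordinate"},
            "SQ": [
                {"SN": config.nuclear_name, "LN": config.nuclear_length},
                {"SN": config.mito_name, "LN": config.mito_length},
            ],
        }
    )

    truth_rows = []
    bam_paths = {}
    for s in range(config.n_samples):
        sample_id = f"S{s:03d}"
        hap_specs = ([], [])
        for spec in config.numts:
            alleles = _draw_genotype(spec, rng)
            for h in range(2):
                if alleles[h]:
                    hap_specs[h].append(spec)
            truth_rows.append(
                {
                    "site_id": spec.site_id,
                    "sample_id": sample_id,
                    "chrom": config.nuclear_name,
                    "breakpoint_left": spec.nuclear_pos - 1,
                    "mito_start": spec.mito_start,
                    "mito_end": spec.mito_end,
                    "strand": spec.strand,
                    "fragment_length": circular_length(
                        spec.mito_start, spec.mito_end, config.mito_length
                    ),
                    "genotype": f"{min(alleles)}/{max(alleles)}",
                    "n_alleles": sum(alleles),
                }
            )
        haplotypes = []
        segments = []
        for h in range(2):
            seq, segs = build_haplotype(
                nuclear_seq, mito_seq, hap_specs[h],
                config.nuclear_name, config.mito_name,
            )
            haplotypes.append((seq, segs))
            segments.append(segs)
        pairs = simulate_pairs(haplotypes, config, rng, sample_id=sample_id)
        records = project_alignments(pairs, segments, config, header)
        records.sort(key=lambda r: (r.reference_id, r.reference_start, r.query_name))
        bam_path = out_dir / f"{sample_id}.bam"
        with pysam.AlignmentFile(str(bam_path), "wb", header=header) as bam:
            for rec in records:
                bam.write(rec)
        pysam.index(str(bam_path))
        bam_paths[sample_id] = bam_path

    truth = pd.DataFrame(truth_rows)
    truth.to_csv(out_dir / "truth.tsv", sep="\t", index=False)
    _write_truth_vcf(out_dir / "truth.vcf", config, truth)
    return SimulationResult(
        config=config,
        out_dir=out_dir,
        reference_fasta=ref_path,
        bam_paths=bam_paths,
        truth=truth,
        nuclear_seq=nuclear_seq,
        mito_seq=mito_seq,
    )


def _write_truth_vcf(path, config: SimConfig, truth: pd.DataFrame):
    samples = sorted(truth["sample_id"].unique()) if len(truth) else []
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##contig=<ID={config.nuclear_name},length={config.nuclear_length}>\n")
        fh.write(f"##contig=<ID={config.mito_name},length={config.mito_length}>\n")
        fh.write('##ALT=<ID=INS:MT,Description="Mitochondrial insertion">\n')
        fh.write('##INFO=<ID=MSTART,Number=1,Type=Integer,Description="Mito start (1-based)">\n')
        fh.write('##INFO=<ID=MEND,Number=1,Type=Integer,Description="Mito end (1-based)">\n')
        fh.write('##INFO=<ID=MLEN,Number=1,Type=Integer,Description="Insertion length">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        cols = ["#CHROM", "POS", "ID", "REF", "ALT", "QUAL", "FILTER", "INFO", "FORMAT"]
        fh.write("\t".join(cols + samples) + "\n")
        if not len(truth):
            return
        for site_id, grp in truth.groupby("site_id", sort=True):
            row = grp.iloc[0]
            gts = dict(zip(grp["sample_id"], grp["genotype"]))
            info = (
                f"MSTART={row.mito_start + 1};MEND={row.mito_end};"
                f"MLEN={row.fragment_length}"
            )
            fields = [
                row.chrom,
                str(int(row.breakpoint_left) + 1),
                site_id,
                "N",
                "<INS:MT>",
                ".",
                "PASS",
                info,
                "GT",
            ] + [gts.get(s, "./.") for s in samples]
            fh.write("\t".join(fields) + "\n")


def export_fastq(pairs, out_prefix, base_quality: int = 35):
    """Optional FASTQ export of simulated pairs (read 2 reverse-complemented)."""
    q = chr(base_quality + 33)
    with open(f"{out_prefix}_1.fastq", "w") as f1, open(
        f"{out_prefix}_2.fastq", "w"
    ) as f2:
        for p in pairs:
            f1.write(f"@{p.name}/1\n{p.seq1}\n+\n{q * len(p.seq1)}\n")
            f2.write(f"@{p.name}/2\n{revcomp(p.seq2)}\n+\n{q * len(p.seq2)}\n")
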