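"""Simulator: implantation, read sampling, idealized projection, fixtures."""

import numpy as np
import pysam
import pytest

from numtcaller import NumtSpec, SimConfig, implant_numt, simulate_pairs, write_fixture
from numtcaller.mito import revcomp
from numtcaller.simulate import (
    build_haplotype,
    project_read,
    random_sequence,
)


def seqs(seed=5, nuc_len=50_000, mito_len=16_569):
    rng = np.random.default_rng(seed)
    return random_sequence(nuc_len, rng), random_sequence(mito_len, rng)


# ---------------------------------------------------------------------------
# Implantation
# ---------------------------------------------------------------------------


def test_simple_implant_length():
    nuc, mito = seqs()
    spec = NumtSpec(nuclear_pos=25_000, mito_start=2_000, mito_end=2_600,
                    genotype="1/1")
    hap, segments = implant_numt(nuc, mito, spec)
    assert len(hap) == 50_600
    assert hap[:25_000] == nuc[:25_000]
    assert hap[25_000:25_600] == mito[2_000:2_600]
    assert hap[25_600:] == nuc[25_000:]


def test_circular_wrap_implant_length():
    nuc, mito = seqs()
    spec = NumtSpec(nuclear_pos=10_000, mito_start=16_000, mito_end=300,
                    genotype="1/1")
    hap, _ = implant_numt(nuc, mito, spec)
    assert len(hap) == 50_000 + 569 + 300
    assert hap[10_000:10_569] == mito[16_000:]
    assert hap[10_569:10_869] == mito[:300]


def test_full_genome_implant():
    nuc, mito = seqs()
    spec = NumtSpec(nuclear_pos=10_000, mito_start=0, mito_end=16_569,
                    genotype="1/1")
    hap, _ = implant_numt(nuc, mito, spec)
    assert len(hap) == 50_000 + 16_569


def test_zero_length_fragment_rejected():
    nuc, mito = seqs()
    spec = NumtSpec(nuclear_pos=10_000, mito_start=500, mito_end=500,
                    genotype="1/1")
    with pytest.raises(ValueError, match="zero-length"):
        implant_numt(nuc, mito, spec)


def test_minus_strand_implant_is_revcomp():
    nuc, mito = seqs()
    spec = NumtSpec(nuclear_pos=10_000, mito_start=100, mito_end=400,
                    strand="-", genotype="1/1")
    hap, _ = implant_numt(nuc, mito, spec)
    assert hap[10_000:10_300] == revcomp(mito[100:400])


# ---------------------------------------------------------------------------
# Pair sampling
# ---------------------------------------------------------------------------


def haplotypes_for(nuc, mito, spec=None):
    specs = [spec] if spec else []
    h1 = build_haplotype(nuc, mito, specs)
    h0 = build_haplotype(nuc, mito, [])
    return [h0, h1]


def test_expected_pair_count():
    nuc, mito = seqs()
    config = SimConfig(nuclear_length=50_000, coverage=10, read_length=100,
                       seed=3)
    rng = np.random.default_rng(3)
    pairs = simulate_pairs([build_haplotype(nuc, mito, [])] * 2, config, rng)
    expected = 10 * 50_000 / (2 * 100)  # coverage * length / (2 * read_len)
    assert abs(len(pairs) - expected) <= 0.1 * expected


def test_error_free_reads_are_substrings():
    nuc, mito = seqs()
    config = SimConfig(nuclear_length=50_000, coverage=2, base_error=0.0, seed=4)
    rng = np.random.default_rng(4)
    hap = build_haplotype(nuc, mito, [])
    pairs = simulate_pairs([hap, hap], config, rng)
    for p in pairs[:50]:
        assert p.seq1 in hap[0]
        assert p.seq2 in hap[0]


def test_same_seed_same_pairs():
    nuc, mito = seqs()
    config = SimConfig(nuclear_length=50_000, coverage=2, seed=9)
    hap = build_haplotype(nuc, mito, [])
    a = simulate_pairs([hap, hap], config, np.random.default_rng(9))
    b = simulate_pairs([hap, hap], config, np.random.default_rng(9))
    assert a == b


def test_insert_mean_below_read_length_rejected():
    nuc, mito = seqs()
    config = SimConfig(insert_mean=80, read_length=100)
    hap = build_haplotype(nuc, mito, [])
    with pytest.raises(ValueError, match="read_length"):
        simulate_pairs([hap, hap], config, np.random.default_rng(0))


# ---------------------------------------------------------------------------
# Projection onto the clean reference
# ---------------------------------------------------------------------------


def test_junction_read_is_softclipped_at_breakpoint():
    nuc, mito = seqs()
    spec = NumtSpec(nuclear_pos=25_000, mito_start=2_000, mito_end=3_000,
                    genotype="1/1")
    _, segments = implant_numt(nuc, mito, spec)
    # read starts 60 bp before the breakpoint: 60 nuclear + 40 insert bases,
    # so the nuclear segment hosts the alignment and the insert bases clip
    p = project_read(24_940, 25_040, segments)
    assert p.ref_name == "chr20"
    assert p.pos == 24_940
    assert p.cigartuples == [(0, 60), (4, 40)]
    # the mirror split is hosted by the insert segment instead
    q = project_read(24_960, 25_060, segments)
    assert q.ref_name == "chrM"
    assert q.pos == 2_000
    assert q.cigartuples == [(4, 40), (0, 60)]


def test_insert_interior_read_maps_to_mito():
    nuc, mito = seqs()
    spec = NumtSpec(nuclear_pos=25_000, mito_start=2_000, mito_end=3_000,
                    genotype="1/1")
    _, segments = implant_numt(nuc, mito, spec)
    p = project_read(25_100, 25_200, segments)
    assert p.ref_name == "chrM"
    assert p.pos == 2_100
    assert p.cigartuples == [(0, 100)]


def test_wrapped_fragment_read_maps_modulo_mito_length():
    nuc, mito = seqs()
    spec = NumtSpec(nuclear_pos=10_000, mito_start=16_000, mito_end=1_000,
                    genotype="1/1")
    _, segments = implant_numt(nuc, mito, spec)
    # read inside the post-origin part of the fragment
    offset = 700  # 569 bases to the origin, then 131 past it
    p = project_read(10_000 + offset, 10_000 + offset + 100, segments)
    assert p.ref_name == "chrM"
    assert p.pos == (16_000 + offset) % 16_569


def test_downstream_flank_read_shifts_back():
    nuc, mito = seqs()
    spec = NumtSpec(nuclear_pos=25_000, mito_start=2_000, mito_end=3_000,
                    genotype="1/1")
    _, segments = implant_numt(nuc, mito, spec)
    p = project_read(30_000, 30_100, segments)
    assert p.ref_name == "chr20"
    assert p.pos == 29_000  # haplotype coordinate minus the 1 kb insert


# ---------------------------------------------------------------------------
# Fixture round trips
# ---------------------------------------------------------------------------


def test_fixture_conserves_every_pair(hom_fixture):
    config = hom_fixture.config
    with pysam.AlignmentFile(str(hom_fixture.bam_paths["S000"])) as bam:
        names = [read.query_name for read in bam.fetch()]
    # every simulated pair appears exactly twice (two reads), nothing lost
    from collections import Counter

    counts = Counter(names)
    assert set(counts.values()) == {2}
    hap_len = config.nuclear_length + 1000
    expected = round(config.coverage * hap_len / (2 * config.read_length))
    assert len(counts) == expected


def test_junction_consistency_errorfree(tmp_path):
    """Clip + matched segment reconstructs the haplotype when base_error=0."""
    config = SimConfig(
        nuclear_length=20_000,
        numts=[NumtSpec(nuclear_pos=10_000, mito_start=500, mito_end=1_500,
                        genotype="1/1", site_id="j")],
        coverage=8,
        base_error=0.0,
        seed=6,
    )
    res = write_fixture(config, tmp_path / "junction")
    checked = 0
    with pysam.AlignmentFile(str(res.bam_paths["S000"])) as bam:
        for read in bam.fetch("chr20"):
            cig = read.cigartuples
            if len(cig) == 2 and cig[0][0] == 0 and cig[1][0] == 4:
                match_len = cig[0][1]
                seq = read.query_sequence
                assert (
                    seq[:match_len]
                    == res.nuclear_seq[read.reference_start : read.reference_start + match_len]
                )
                # clipped tail continues into the implanted fragment
                assert seq[match_len:] == res.mito_seq[500 : 500 + len(seq) - match_len]
                checked += 1
    assert checked >= 2


def test_truth_vcf_is_valid_and_fixture_rereadable(hom_fixture):
    with pysam.VariantFile(str(hom_fixture.out_dir / "truth.vcf")) as vcf:
        recs = list(vcf)
    assert len(recs) == 1
    assert recs[0].pos == 25_000  # 1-based last base before the insertion
    assert recs[0].alts == ("<INS:MT>",)


def test_same_config_identical_fixture(tmp_path):
    config = SimConfig(
        nuclear_length=15_000,
        numts=[NumtSpec(nuclear_pos=7_000, mito_start=100, mito_end=600,
                        genotype="0/1", site_id="d")],
        coverage=5,
        seed=21,
    )
    res_a = write_fixture(config, tmp_path / "a")
    res_b = write_fixture(config, tmp_path / "b")
    with pysam.AlignmentFile(str(res_a.bam_paths["S000"])) as a, pysam.AlignmentFile(
        str(res_b.bam_paths["S000"])
    ) as b:
        ra = [r.to_string() for r in a.fetch()]
        rb = [r.to_string() for r in b.fetch()]
    assert ra == rb
    assert res_a.truth.equals(res_b.truth)
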