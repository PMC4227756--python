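"""Discovery: pair extraction, clustering, linking, breakpoint localization."""

import itertools

import numpy as np
import pysam
import pytest

from numtcaller import (
    cluster_reads,
    discover_sample,
    extract_candidate_pairs,
    find_softclip_breakpoint,
    link_clusters,
)
from numtcaller.discovery import MitoAnchoredPair, ReadCluster, collect_softclips
from numtcaller.genotype import count_reference_spanning
from numtcaller.insert_size import InsertSizeModel
from numtcaller.mito import CircularMatcher

from conftest import make_bam

MODEL = InsertSizeModel(mean_insert=350, sd_insert=50, n_pairs_sampled=1000)


def anchor(pos, strand="+", chrom="chr1", mapq=60, name=None, mate_pos=100):
    return MitoAnchoredPair(
        sample_id="s",
        chrom=chrom,
        pos=pos,
        end=pos + 100,
        strand=strand,
        mapq=mapq,
        mate_target="chrM",
        mate_pos=mate_pos,
        read_name=name or f"r{pos}{strand}",
    )


# ---------------------------------------------------------------------------
# Pair extraction
# ---------------------------------------------------------------------------


def pair_records(name, pos, mapq=60, mate_chrom="chrM", mate_pos=500):
    return {
        "name": name,
        "chrom": "chr1",
        "pos": pos,
        "cigar": "100M",
        "mapq": mapq,
        "mate_chrom": mate_chrom,
        "mate_pos": mate_pos,
    }


def test_extract_mapq_and_target_rules(tmp_path):
    bam_path = make_bam(
        tmp_path / "pairs.bam",
        [
            pair_records("good", 1000, mapq=30),
            pair_records("lowmapq", 2000, mapq=5),
            pair_records("numtmate", 3000, mapq=30, mate_chrom="chr1", mate_pos=50_500),
            pair_records("plainmate", 4000, mapq=30, mate_chrom="chr1", mate_pos=4300),
        ],
    )
    known = [("chr1", 50_000, 51_000, "refnumt_7")]
    with pysam.AlignmentFile(str(bam_path)) as bam:
        pairs = extract_candidate_pairs(bam, "chrM", known_numts=known)
    by_name = {p.read_name: p for p in pairs}
    assert set(by_name) == {"good", "numtmate"}
    assert by_name["good"].mate_target == "chrM"
    assert by_name["numtmate"].mate_target == "refnumt_7"
    assert all(p.mapq >= 10 for p in pairs)


def test_extract_requires_mito_contig(tmp_path):
    bam_path = make_bam(
        tmp_path / "nochrm.bam",
        [pair_records("r", 1000, mate_chrom="MT")],
        references=(("chr1", 100_000), ("MT", 16_569)),
    )
    with pysam.AlignmentFile(str(bam_path)) as bam:
        with pytest.raises(ValueError, match="chrM"):
            extract_candidate_pairs(bam, "chrM")


def test_extract_skips_duplicates_and_secondary(tmp_path):
    recs = [
        dict(pair_records("dup", 1000), duplicate=True),
        dict(pair_records("sec", 2000), secondary=True),
    ]
    bam_path = make_bam(tmp_path / "dups.bam", recs)
    with pysam.AlignmentFile(str(bam_path)) as bam:
        assert extract_candidate_pairs(bam, "chrM") == []


# ---------------------------------------------------------------------------
# Clustering and linking
# ---------------------------------------------------------------------------


def test_single_anchor_singleton_cluster():
    model = InsertSizeModel(200, 0, 100)
    clusters = cluster_reads([anchor(100)], model)
    assert len(clusters) == 1
    assert clusters[0].start == 100


def test_cluster_splits_beyond_window():
    model = InsertSizeModel(200, 0, 100)  # W_L = 200
    clusters = cluster_reads([anchor(100), anchor(150), anchor(600)], model)
    starts = sorted(c.start for c in clusters)
    assert starts == [100, 600]
    assert {len(c.members) for c in clusters} == {1, 2}


def test_strands_never_merge():
    model = InsertSizeModel(200, 0, 100)
    clusters = cluster_reads([anchor(100, "+"), anchor(120, "-")], model)
    assert len(clusters) == 2


def test_clustering_is_order_independent():
    model = InsertSizeModel(200, 0, 100)
    anchors = [anchor(p, s) for p, s in [(100, "+"), (150, "+"), (600, "+"), (140, "-")]]
    reference = cluster_reads(anchors, model)
    key = lambda cs: [(c.chrom, c.start, c.end, c.strand, len(c.members)) for c in cs]
    for perm in itertools.permutations(anchors):
        assert key(cluster_reads(list(perm), model)) == key(reference)


def cluster(start, end, strand):
    return ReadCluster(chrom="chr1", start=start, end=end, strand=strand, members=[])


def test_link_within_twice_window():
    model = InsertSizeModel(200, 0, 100)  # 2 W_L = 400
    links = link_clusters([cluster(100, 500, "+"), cluster(700, 900, "-")], model)
    assert len(links) == 1
    assert links[0].two_sided


def test_no_link_wrong_orientation():
    model = InsertSizeModel(200, 0, 100)
    links = link_clusters([cluster(400, 500, "-"), cluster(700, 900, "+")], model)
    assert all(not lk.two_sided for lk in links)
    assert len(links) == 2  # both retained one-sided


def test_no_link_beyond_twice_window():
    model = InsertSizeModel(200, 0, 100)
    links = link_clusters([cluster(100, 500, "+"), cluster(1000, 1200, "-")], model)
    assert all(not lk.two_sided for lk in links)


def test_greedy_linking_prefers_nearest():
    model = InsertSizeModel(200, 0, 100)
    f1, f2 = cluster(100, 400, "+"), cluster(450, 600, "+")
    r1 = cluster(700, 900, "-")
    links = link_clusters([f1, f2, r1], model)
    two_sided = [lk for lk in links if lk.two_sided]
    assert len(two_sided) == 1
    assert two_sided[0].fwd is f2  # smaller gap wins


# ---------------------------------------------------------------------------
# Soft-clip breakpoints
# ---------------------------------------------------------------------------


def clip_record(name, pos, cigar, seq, mapq=60):
    return {
        "name": name,
        "chrom": "chr1",
        "pos": pos,
        "cigar": cigar,
        "seq": seq,
        "mapq": mapq,
        "mate_chrom": "chr1",
        "mate_pos": pos,
    }


@pytest.fixture()
def mito_seq():
    rng = np.random.default_rng(7)
    return "".join(rng.choice(list("ACGT"), size=2000))


def test_identical_clips_with_mito_tails_are_precise(tmp_path, mito_seq):
    tail = mito_seq[300:360]
    recs = [
        clip_record(f"c{i}", 9_940, "60M60S", "A" * 60 + tail) for i in range(3)
    ]
    bam = make_bam(tmp_path / "clips.bam", recs)
    with pysam.AlignmentFile(str(bam)) as fh:
        bp, precise, evidence, offset = find_softclip_breakpoint(
            fh, "chr1", 9_000, 11_000, mito_seq
        )
    assert precise
    assert bp == 9_999  # last reference base before the insertion
    assert len(evidence) == 3
    assert offset == 300


def test_no_softclips_is_imprecise(tmp_path, mito_seq):
    recs = [clip_record("plain", 9_940, "120M", "A" * 120)]
    bam = make_bam(tmp_path / "noclips.bam", recs)
    with pysam.AlignmentFile(str(bam)) as fh:
        bp, precise, evidence, _ = find_softclip_breakpoint(
            fh, "chr1", 9_000, 11_000, mito_seq
        )
    assert bp is None and not precise and evidence == []


def test_unrelated_tails_fail_the_mito_check(tmp_path, mito_seq):
    rng = np.random.default_rng(99)
    tail = "".join(rng.choice(list("ACGT"), size=60))
    # oracle: exhaustive ungapped scan of the tail over the circular mito
    doubled = mito_seq + mito_seq
    best = max(
        sum(a == b for a, b in zip(tail, doubled[i : i + 60])) / 60
        for i in range(len(mito_seq))
    )
    assert best < 0.9  # the tail really is unrelated
    recs = [clip_record(f"u{i}", 9_940, "60M60S", "A" * 60 + tail) for i in range(3)]
    bam = make_bam(tmp_path / "unrelated.bam", recs)
    with pysam.AlignmentFile(str(bam)) as fh:
        bp, precise, _, _ = find_softclip_breakpoint(
            fh, "chr1", 9_000, 11_000, mito_seq
        )
    assert not precise and bp is None


def test_left_and_right_clips_agree_on_breakpoint(tmp_path, mito_seq):
    tail = mito_seq[500:560]
    recs = [
        clip_record("right", 9_940, "60M60S", "A" * 60 + tail),
        clip_record("left", 10_000, "60S60M", tail + "A" * 60),
    ]
    bam = make_bam(tmp_path / "bothsides.bam", recs)
    with pysam.AlignmentFile(str(bam)) as fh:
        clips = collect_softclips(fh, "chr1", 9_000, 11_000)
    assert {c[0] for c in clips} == {10_000}


# ---------------------------------------------------------------------------
# Reference-spanning counting
# ---------------------------------------------------------------------------


def test_reference_spanning_rules(tmp_path):
    bp = 10_000 - 1  # junction between 9999 and 10000
    recs = [
        clip_record("spans", 9_970, "100M", "A" * 100),  # 30 bp each side
        clip_record("ends_at", 9_900, "100M", "A" * 100),  # ends exactly at bp
        clip_record("clipped", 9_940, "60M60S", "A" * 120),  # supports insertion
    ]
    bam = make_bam(tmp_path / "span.bam", recs)
    with pysam.AlignmentFile(str(bam)) as fh:
        count, mapqs = count_reference_spanning(fh, "chr1", bp)
    assert count == 1
    assert mapqs == [60]


# ---------------------------------------------------------------------------
# End-to-end on simulated data
# ---------------------------------------------------------------------------


def test_discovery_recovers_homozygous_insertion(hom_fixture):
    calls, stats, model = discover_sample(
        hom_fixture.bam_paths["S000"], hom_fixture.mito_seq, "chrM",
        sample_id="S000",
    )
    passing = [c for c in calls if c.passed]
    assert len(passing) == 1
    call = passing[0]
    truth_bp = int(hom_fixture.truth.breakpoint_left.iloc[0])
    assert call.precise
    assert abs(call.breakpoint_left - truth_bp) <= 5
    assert call.support >= 4 and call.depth >= 5 and call.quality >= 50
    assert call.genotype == "1/1"
    # mito source interval approximately matches the implanted fragment
    ms, me = call.mito_interval
    assert abs(ms - 2000) <= model.w_l
    assert abs(me - 3000) <= model.w_l


def test_all_emitted_anchors_pass_mapq_floor(hom_fixture):
    with pysam.AlignmentFile(str(hom_fixture.bam_paths["S000"])) as bam:
        pairs = extract_candidate_pairs(bam, "chrM")
    assert pairs
    assert all(p.mapq >= 10 for p in pairs)


def test_no_implant_no_calls(null_fixture):
    calls, stats, _ = discover_sample(
        null_fixture.bam_paths["S000"], null_fixture.mito_seq, "chrM",
    )
    assert [c for c in calls if c.passed] == []


def test_one_sided_candidates_never_precise_without_clips():
    """A lone cluster with no soft-clip confirmation stays imprecise."""
    model = InsertSizeModel(200, 0, 100)
    links = link_clusters([cluster(100, 400, "+")], model)
    assert len(links) == 1 and not links[0].two_sided


def test_low_mapq_repeat_flank_is_excluded(tmp_path):
    from numtcaller import NumtSpec, SimConfig, write_fixture

    config = SimConfig(
        nuclear_length=30_000,
        numts=[
            NumtSpec(nuclear_pos=15_000, mito_start=100, mito_end=900,
                     genotype="1/1", site_id="rep")
        ],
        coverage=15,
        seed=11,
        repeat_flank=(13_000, 17_000),
    )
    res = write_fixture(config, tmp_path / "repeat")
    with pysam.AlignmentFile(str(res.bam_paths["S000"])) as bam:
        pairs = extract_candidate_pairs(bam, "chrM")
    # every anchor near the insertion has MAPQ 0 and is discarded
    assert pairs == []
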