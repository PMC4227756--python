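"""Shared fixtures: simulated alignment fixtures and a tiny BAM builder."""

from __future__ import annotations

import pysam
import pytest

from numtcaller import NumtSpec, SimConfig, write_fixture

HOM_SEED = 42
NULL_SEED = 43
COHORT_SEED = 77


@pytest.fixture(scope="session")
def hom_fixture(tmp_path_factory):
    """50 kb nucleus, one homozygous 1 kb insertion, 20x coverage."""
    config = SimConfig(
        nuclear_length=50_000,
        numts=[
            NumtSpec(
                nuclear_pos=25_000,
                mito_start=2_000,
                mito_end=3_000,
                genotype="1/1",
                site_id="numt_hom",
            )
        ],
        coverage=20,
        seed=HOM_SEED,
        n_samples=1,
    )
    return write_fixture(config, tmp_path_factory.mktemp("hom_fixture"))


@pytest.fixture(scope="session")
def null_fixture(tmp_path_factory):
    """Same library, zero implants: specificity control."""
    config = SimConfig(
        nuclear_length=50_000, numts=[], coverage=20, seed=NULL_SEED, n_samples=1
    )
    return write_fixture(config, tmp_path_factory.mktemp("null_fixture"))


@pytest.fixture(scope="session")
def cohort_fixture(tmp_path_factory):
    """50 samples segregating one insertion at allele frequency 0.3, 10x."""
    config = SimConfig(
        nuclear_length=50_000,
        numts=[
            NumtSpec(
                nuclear_pos=25_000,
                mito_start=2_000,
                mito_end=3_000,
                allele_frequency=0.3,
                site_id="numt_af30",
            )
        ],
        coverage=10,
        seed=COHORT_SEED,
        n_samples=50,
    )
    return write_fixture(config, tmp_path_factory.mktemp("cohort_fixture"))


def make_bam(path, records, references=(("chr1", 100_000), ("chrM", 16_569))):
    """Write a sorted, indexed BAM from compact record dicts.

    Each record dict: name, chrom, pos, cigar (string), seq (optional),
    mapq (default 60), flags via booleans (reverse, mate_chrom, mate_pos,
    proper, duplicate, secondary), tlen.
    """
    header = pysam.AlignmentHeader.from_dict(
        {
            "HD": {"VN": "1.6", "SO": "coordinate"},
            "SQ": [{"SN": n, "LN": ln} for n, ln in references],
        }
    )
    segs = []
    for r in records:
        a = pysam.AlignedSegment(header=header)
        a.query_name = r["name"]
        a.reference_name = r["chrom"]
        a.reference_start = r["pos"]
        a.cigarstring = r["cigar"]
        qlen = a.infer_query_length()
        a.query_sequence = r.get("seq", "A" * qlen)
        a.query_qualities = pysam.qualitystring_to_array("I" * qlen)
        a.mapping_quality = r.get("mapq", 60)
        a.is_paired = r.get("paired", True)
        a.is_read1 = r.get("read1", True)
        a.is_read2 = not a.is_read1 if a.is_paired else False
        a.is_reverse = r.get("reverse", False)
        a.is_duplicate = r.get("duplicate", False)
        a.is_secondary = r.get("secondary", False)
        a.is_supplementary = r.get("supplementary", False)
        if r.get("mate_chrom"):
            a.next_reference_name = r["mate_chrom"]
            a.next_reference_start = r.get("mate_pos", 0)
            a.mate_is_reverse = r.get("mate_reverse", True)
        else:
            a.mate_is_unmapped = True
        a.is_proper_pair = r.get("proper", False)
        a.template_length = r.get("tlen", 0)
        segs.append(a)
    segs.sort(key=lambda s: (s.reference_id, s.reference_start))
    with pysam.AlignmentFile(str(path), "wb", header=header) as bam:
        for s in segs:
            bam.write(s)
    pysam.index(str(path))
    return path
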