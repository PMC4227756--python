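"""VCF 4.2 output/input for Numt insertion calls.

Insertions are written as symbolic ``<INS:MT>`` records: POS is the 1-based
last reference base before the inserted sequence, the mitochondrial source
interval is carried in MSTART/MEND (1-based inclusive) with its length in
MLEN, and imprecise sites carry IMPRECISE plus a CIPOS confidence interval.
"""

from __future__ import annotations

import pysam

_FILTERS = [
    ("min-quality", "Phred-scaled insertion quality below threshold"),
    ("min-reads", "Fewer insertion-supporting reads than required"),
    ("min-depth", "Total informative depth at breakpoint below threshold"),
]


def _make_header(contigs, samples):
    header = pysam.VariantHeader()
    for name, length in contigs:
        header.contigs.add(name, length=length)
    header.add_meta(
        "ALT", items=[("ID", "INS:MT"), ("Description", "Mitochondrial insertion")]
    )
    for fid, desc in _FILTERS:
        header.filters.add(fid, None, None, desc)
    header.info.add("IMPRECISE", 0, "Flag", "Imprecise structural variant")
    header.info.add("CIPOS", 2, "Integer", "Confidence interval around POS")
    header.info.add("MSTART", 1, "Integer", "Mitochondrial start of insertion (1-based)")
    header.info.add("MEND", 1, "Integer", "Mitochondrial end of insertion (1-based)")
    header.info.add("MLEN", 1, "Integer", "Length of the mitochondrial insertion")
    header.info.add("AF", "A", "Float", "EM-estimated insertion allele frequency")
    header.formats.add("GT", 1, "String", "Genotype")
    header.formats.add("GQ", 1, "Integer", "Genotype quality (Phred)")
    header.formats.add("DP", 1, "Integer", "Informative read depth")
    header.formats.add("AD", "R", "Integer", "Reference, insertion supporting reads")
    for s in samples:
        header.add_sample(s)
    return header


def _gt_tuple(gt_string):
    return tuple(int(a) for a in gt_string.replace("|", "/").split("/"))


def write_discovery_vcf(path, calls, contigs, sample_id, mito_length=None):
    """One single-sample VCF from per-sample discovery calls."""
    header = _make_header(contigs, [sample_id])
    with pysam.VariantFile(str(path), "w", header=header) as vcf:
        for i, call in enumerate(
            sorted(calls, key=lambda c: (c.chrom, c.breakpoint_left))
        ):
            rec = vcf.new_record(
                contig=call.chrom,
                start=call.breakpoint_left,
                stop=call.breakpoint_left + 1,
                alleles=("N", "<INS:MT>"),
                id=f"NUMT_{i + 1}",
                qual=round(call.quality, 2),
            )
            if call.filters:
                for f in call.filters:
                    rec.filter.add(f)
            else:
                rec.filter.add("PASS")
            if not call.precise:
                rec.info["IMPRECISE"] = True
                rec.info["CIPOS"] = (int(call.ci[0]), int(call.ci[1]))
            if call.mito_interval is not None and mito_length is not None:
                ms, me = call.mito_interval
                rec.info["MSTART"] = ms + 1
                rec.info["MEND"] = me if me > 0 else mito_length
                rec.info["MLEN"] = (me - ms) % mito_length or mito_length
            sample = rec.samples[sample_id]
            sample["GT"] = _gt_tuple(call.genotype)
            sample["GQ"] = int(round(call.gq))
            sample["DP"] = call.depth
            sample["AD"] = (call.ref_support, call.support)
            vcf.write(rec)


def write_cohort_vcf(path, cohort_result, contigs, mito_length=None):
    """Multi-sample VCF from a cohort genotyping result."""
    samples = cohort_result.samples
    header = _make_header(contigs, samples)
    with pysam.VariantFile(str(path), "w", header=header) as vcf:
        for i, sg in enumerate(
            sorted(cohort_result.sites, key=lambda s: (s.site.chrom, s.site.breakpoint_left))
        ):
            site = sg.site
            rec = vcf.new_record(
                contig=site.chrom,
                start=site.breakpoint_left,
                stop=site.breakpoint_left + 1,
                alleles=("N", "<INS:MT>"),
                id=f"NUMT_{i + 1}",
            )
            rec.filter.add("PASS")
            rec.info["AF"] = sg.allele_frequency
            if not site.precise:
                rec.info["IMPRECISE"] = True
                rec.info["CIPOS"] = (int(site.ci[0]), int(site.ci[1]))
            if site.mito_interval is not None and mito_length is not None:
                ms, me = site.mito_interval
                rec.info["MSTART"] = ms + 1
                rec.info["MEND"] = me if me > 0 else mito_length
                rec.info["MLEN"] = (me - ms) % mito_length or mito_length
            for s in samples:
                gl = sg.genotypes[s]
                inp = sg.evidence[s]
                fmt = rec.samples[s]
                fmt["GT"] = _gt_tuple(gl.genotype)
                fmt["GQ"] = int(round(gl.gq))
                fmt["DP"] = inp.n_total
                fmt["AD"] = (inp.n_ref, inp.n_alt)
            vcf.write(rec)


def read_vcf(path):
    """Read a Numt VCF back into plain record dicts (round-trip friendly)."""
    out = []
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            entry = {
                "chrom": rec.chrom,
                "breakpoint_left": rec.start,
                "id": rec.id,
                "qual": rec.qual,
                "filters": [f for f in rec.filter.keys() if f != "PASS"],
                "precise": "IMPRECISE" not in rec.info,
                "mito_interval": None,
                "samples": {},
            }
            if "MSTART" in rec.info:
                entry["mito_interval"] = (rec.info["MSTART"] - 1, rec.info["MEND"])
            for s in rec.samples:
                fmt = rec.samples[s]
                entry["samples"][s] = {
                    "GT": "/".join(str(a) for a in fmt["GT"]),
                    "GQ": fmt["GQ"],
                    "DP": fmt["DP"],
                    "AD": tuple(fmt["AD"]),
                }
            out.append(entry)
    return out
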