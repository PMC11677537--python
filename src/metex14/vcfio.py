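"""VCF 4.2 reading and writing for DNA variant calls.

Variants travel as plain-text VCF with per-record INFO fields carrying the
patient, allele frequency, depths and gene annotation (the layout written
by the cohort simulator and accepted back by the classifier).  Reading goes
through :mod:`pysam`; multi-allelic records are split into one
:class:`~metex14.qc_filtering.VariantCall` per alternate allele before any
filtering.  The INFO field names are configurable so externally produced
VCFs (e.g. AO vs AD allele-depth conventions) can be mapped in.
"""

from __future__ import annotations

import os
from typing import Iterable, Mapping, Sequence

import pysam

from .errors import ValidationError
from .qc_filtering import VariantCall

__all__ = ["write_vcf", "read_vcf", "read_vcf_dir", "DEFAULT_FIELD_MAP"]

DEFAULT_FIELD_MAP: Mapping[str, str] = {
    "patient": "PATIENT",
    "af": "AF",
    "dp": "DP",
    "ao": "AO",
    "gene": "GENE",
    "protein_change": "PCHANGE",
}

_HEADER_TEMPLATE = """\
##fileformat=VCFv4.2
##source=metex14
{extra}##INFO=<ID=PATIENT,Number=1,Type=String,Description="Patient identifier">
##INFO=<ID=AF,Number=A,Type=Float,Description="Alternate allele frequency">
##INFO=<ID=DP,Number=1,Type=Integer,Description="Read depth at the site">
##INFO=<ID=AO,Number=A,Type=Integer,Description="Alternate allele observation count">
##INFO=<ID=GENE,Number=1,Type=String,Description="Gene symbol">
##INFO=<ID=PCHANGE,Number=1,Type=String,Description="Protein change (one-letter)">
{contigs}#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO
"""


def write_vcf(variants: Sequence[VariantCall], path,
              extra_header_lines: Sequence[str] = ()) -> None:
    """Write variant calls as an uncompressed single-column VCF 4.2 file.

    Records are sorted by (chromosome, position, patient) so output is
    deterministic regardless of input order.
    """
    recs = sorted(variants, key=lambda v: (str(v.chromosome), v.pos, v.patient_id))
    contigs = "".join(f"##contig=<ID={c}>\n"
                      for c in sorted({str(v.chromosome) for v in recs}))
    extra = "".join(line.rstrip("\n") + "\n" for line in extra_header_lines)
    with open(path, "w") as fh:
        fh.write(_HEADER_TEMPLATE.format(extra=extra, contigs=contigs))
        for v in recs:
            info = (f"PATIENT={v.patient_id};AF={v.allele_frequency:.6g};"
                    f"DP={v.site_depth};AO={v.alt_reads};GENE={v.gene}")
            if v.protein_change:
                info += f";PCHANGE={v.protein_change}"
            fh.write(f"{v.chromosome}\t{v.pos}\t.\t{v.ref}\t{v.alt}\t"
                     f"{v.quality_phred:.6g}\t.\t{info}\n")


def _scalar(value, index: int):
    """Pick the per-alt entry from a possibly tuple-valued INFO field."""
    if isinstance(value, (tuple, list)):
        return value[index] if index < len(value) else value[0]
    return value


def read_vcf(path, field_map: Mapping[str, str] | None = None,
             default_patient: str | None = None) -> list[VariantCall]:
    """Read a VCF into variant calls, splitting multi-allelic records.

    ``field_map`` renames the INFO keys consulted for patient, AF, DP and
    alt-read count; an ``AD``-style (ref,alt...) field is accepted for the
    alt-read entry.  ``default_patient`` is used when the patient INFO field
    is absent (e.g. one-patient-per-file layouts).
    """
    fm = dict(DEFAULT_FIELD_MAP)
    fm.update(field_map or {})
    calls: list[VariantCall] = []
    with pysam.VariantFile(os.fspath(path)) as vf:
        for rec in vf:
            info = rec.info
            patient = info.get(fm["patient"], default_patient)
            if patient is None:
                raise ValidationError(
                    f"record {rec.chrom}:{rec.pos} has no {fm['patient']} INFO field "
                    "and no default patient was given")
            alts = rec.alts or ()
            for i, alt in enumerate(alts):
                ao_field = info.get(fm["ao"])
                if ao_field is None and "AD" in info:
                    ad = info["AD"]
                    ao = int(_scalar(ad, i + 1))  # AD is (ref, alt1, alt2, ...)
                else:
                    ao = int(_scalar(ao_field, i))
                calls.append(VariantCall(
                    patient_id=str(patient),
                    chromosome=str(rec.chrom),
                    pos=int(rec.pos),
                    ref=rec.ref,
                    alt=str(alt),
                    # htslib stores Float INFO as float32; snap back to the
                    # 6-significant-digit text representation we write
                    allele_frequency=float(f"{float(_scalar(info[fm['af']], i)):.6g}"),
                    site_depth=int(info[fm["dp"]]),
                    alt_reads=ao,
                    quality_phred=float(f"{float(rec.qual or 0.0):.6g}"),
                    gene=str(info.get(fm["gene"], "")),
                    protein_change=(str(info[fm["protein_change"]])
                                    if fm["protein_change"] in info else None),
                ))
    return calls


def read_vcf_dir(directory, field_map: Mapping[str, str] | None = None) -> list[VariantCall]:
    """Read every ``*.vcf`` in a directory; filenames double as patient ids."""
    calls: list[VariantCall] = []
    for name in sorted(os.listdir(directory)):
        if name.endswith(".vcf"):
            stem = name[:-4]
            calls.extend(read_vcf(os.path.join(directory, name), field_map,
                                  default_patient=stem))
    return calls
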