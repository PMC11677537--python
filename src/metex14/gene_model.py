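"""Gene model and splice-region windows.

MET exon 14 skipping is caused by DNA variants clustered at the exon 14
splice acceptor (3' end of intron 13) and splice donor (5' end of intron 14)
sites.  This module holds an exon-level gene model on genomic coordinates
(1-based, closed intervals, VCF POS semantics), derives acceptor/donor
windows around a chosen exon, and decides whether a called variant touches
those windows.  The window extents are configurable because clinical
reporting practice, not a single standard, defines how much intronic and
exonic sequence counts as the "splice region".
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from importlib import resources
import yaml

from .errors import ValidationError

__all__ = [
    "Exon",
    "GeneModel",
    "SpliceWindows",
    "WindowConfig",
    "RegionHit",
    "build_splice_windows",
    "variant_affected_interval",
    "variant_in_splice_region",
    "load_gene_model",
    "default_met_model",
]


@dataclass(frozen=True)
class Exon:
    number: int
    start: int  # 1-based inclusive
    end: int    # 1-based inclusive

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValidationError(f"exon {self.number}: start {self.start} > end {self.end}")


@dataclass(frozen=True)
class GeneModel:
    """Exon structure of one transcript on genomic coordinates."""

    gene_symbol: str
    chromosome: str
    strand: str
    transcript_id: str
    exons: tuple[Exon, ...]

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValidationError(f"strand must be '+' or '-', got {self.strand!r}")
        exons = tuple(sorted(self.exons, key=lambda e: e.start))
        object.__setattr__(self, "exons", exons)
        numbers = [e.number for e in exons]
        if len(set(numbers)) != len(numbers):
            raise ValidationError("exon numbers must be unique")
        for a, b in zip(exons, exons[1:]):
            if b.start <= a.end:
                raise ValidationError(f"exons {a.number} and {b.number} overlap")

    def exon(self, number: int) -> Exon:
        for e in self.exons:
            if e.number == number:
                return e
        raise KeyError(f"exon {number} not in model for {self.gene_symbol}/{self.transcript_id}")


@dataclass(frozen=True)
class WindowConfig:
    """Extent (bp) of the splice windows around an exon.

    ``acceptor_intronic_bp`` bases upstream of the exon start plus
    ``acceptor_exonic_bp`` bases into the exon form the acceptor window;
    the donor window mirrors this at the exon end (plus strand).
    """

    acceptor_intronic_bp: int = 25
    acceptor_exonic_bp: int = 2
    donor_exonic_bp: int = 2
    donor_intronic_bp: int = 10

    def __post_init__(self) -> None:
        vals = (self.acceptor_intronic_bp, self.acceptor_exonic_bp,
                self.donor_exonic_bp, self.donor_intronic_bp)
        if any(v < 0 for v in vals):
            raise ValidationError("window extents must be non-negative")
        if all(v == 0 for v in vals):
            raise ValidationError("at least one window extent must be positive")


@dataclass(frozen=True)
class SpliceWindows:
    """Acceptor and donor windows (closed genomic intervals) for one exon.

    A side whose configured extent is zero on both the intronic and exonic
    flank has no window at all and is stored as ``None``.
    """

    chromosome: str
    exon_number: int
    acceptor: tuple[int, int] | None
    donor: tuple[int, int] | None

    def __post_init__(self) -> None:
        for name, iv in (("acceptor", self.acceptor), ("donor", self.donor)):
            if iv is not None and iv[1] < iv[0]:
                raise ValidationError(f"{name} window end {iv[1]} < start {iv[0]}")


class RegionHit(enum.Enum):
    NONE = "none"
    ACCEPTOR = "acceptor"
    DONOR = "donor"
    BOTH = "both"


def build_splice_windows(model: GeneModel, exon_number: int,
                         cfg: WindowConfig | None = None) -> SpliceWindows:
    """Derive the acceptor/donor windows of ``exon_number``.

    Plus strand: acceptor = [start - intronic, start + exonic - 1],
    donor = [end - exonic + 1, end + intronic].  Minus-strand genes are
    handled by mirroring: the acceptor sits at the exon end and the donor
    at the exon start.  Raises if a window would run into an adjacent exon.
    """
    cfg = cfg or WindowConfig()
    exon = model.exon(exon_number)  # KeyError if unknown
    if model.strand == "+":
        acceptor = (exon.start - cfg.acceptor_intronic_bp,
                    exon.start + cfg.acceptor_exonic_bp - 1)
        donor = (exon.end - cfg.donor_exonic_bp + 1,
                 exon.end + cfg.donor_intronic_bp)
    else:
        acceptor = (exon.end - cfg.acceptor_exonic_bp + 1,
                    exon.end + cfg.acceptor_intronic_bp)
        donor = (exon.start - cfg.donor_intronic_bp,
                 exon.start + cfg.donor_exonic_bp - 1)
    acceptor = _none_if_empty(acceptor)
    donor = _none_if_empty(donor)
    for other in model.exons:
        if other.number == exon_number:
            continue
        for iv in (acceptor, donor):
            if iv is not None and iv[0] <= other.end and other.start <= iv[1]:
                raise ValidationError(
                    f"window {list(iv)} for exon {exon_number} overlaps exon {other.number}")
    return SpliceWindows(model.chromosome, exon_number, acceptor, donor)


def _none_if_empty(iv: tuple[int, int]) -> tuple[int, int] | None:
    return None if iv[1] < iv[0] else iv


def variant_affected_interval(ref: str, alt: str, pos: int) -> tuple[int, int]:
    """Genomic interval of reference bases replaced by the variant.

    A SNV collapses to ``[pos, pos]``; a deletion spans the deleted
    reference bases; an insertion is anchored at its reference base.
    """
    if not ref or not alt:
        raise ValidationError("ref and alt alleles must be non-empty")
    return (pos, pos + len(ref) - 1)


def variant_in_splice_region(chromosome: str, pos: int, ref: str, alt: str,
                             w: SpliceWindows) -> RegionHit:
    """Which splice window(s), if any, the variant's affected interval touches.

    Overlap of closed intervals; a deletion partially overlapping a window
    counts, even when the canonical GT/AG dinucleotide itself is untouched.
    """
    if str(chromosome) != str(w.chromosome):
        raise ValidationError(
            f"chromosome mismatch: variant on {chromosome}, windows on {w.chromosome}")
    s, e = variant_affected_interval(ref, alt, pos)
    in_acc = w.acceptor is not None and s <= w.acceptor[1] and w.acceptor[0] <= e
    in_don = w.donor is not None and s <= w.donor[1] and w.donor[0] <= e
    if in_acc and in_don:
        return RegionHit.BOTH
    if in_acc:
        return RegionHit.ACCEPTOR
    if in_don:
        return RegionHit.DONOR
    return RegionHit.NONE


# ---------------------------------------------------------------------------
# Configuration file handling

def load_gene_model(path_or_stream) -> tuple[GeneModel, WindowConfig]:
    """Read a gene-model YAML file (schema documented in the shipped default)."""
    if hasattr(path_or_stream, "read"):
        doc = yaml.safe_load(path_or_stream)
    else:
        with open(path_or_stream) as fh:
            doc = yaml.safe_load(fh)
    exons = tuple(Exon(int(e["number"]), int(e["start"]), int(e["end"]))
                  for e in doc["exons"])
    model = GeneModel(
        gene_symbol=doc["gene_symbol"],
        chromosome=str(doc["chromosome"]),
        strand=doc["strand"],
        transcript_id=doc["transcript_id"],
        exons=exons,
    )
    w = doc.get("window_config", {})
    wcfg = WindowConfig(
        acceptor_intronic_bp=int(w.get("acceptor_intronic_bp", 25)),
        acceptor_exonic_bp=int(w.get("acceptor_exonic_bp", 2)),
        donor_exonic_bp=int(w.get("donor_exonic_bp", 2)),
        donor_intronic_bp=int(w.get("donor_intronic_bp", 10)),
    )
    return model, wcfg


def default_met_model() -> tuple[GeneModel, WindowConfig]:
    """The packaged MET (GRCh37) exon 13/14/15 model and default windows."""
    ref = resources.files("metex14.data").joinpath("met_grch37.yaml")
    with ref.open() as fh:
        return load_gene_model(fh)
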