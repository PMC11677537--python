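"""Consensus driver triage of MET variants of uncertain significance.

Five precomputed predictor annotations are consumed per protein-level
variant — SIFT, PolyPhen-2, MutationTaster, CADD (Phred-scaled) and the
Cancer Genome Interpreter — and a variant is called a predicted driver only
when *every* predictor votes driver (strict conjunction).  CADD votes
driver only above 25 (strict), the conventional high-pathogenicity bound.
The module also maps protein residues to Met domains (juxtamembrane and
tyrosine-kinase by default) and screens patients for co-occurring
actionable variants in other genes, in any solid-tumour indication and
restricted to lung-actionable genes.

Running the predictor engines themselves is out of scope: annotations
arrive as a tab-separated table produced by an external annotator.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from importlib import resources
from typing import Iterable, Mapping, Sequence

import pandas as pd
import yaml

from .errors import MissingPredictorError, ValidationError

__all__ = [
    "PREDICTORS",
    "PredictorProfile",
    "DomainTable",
    "DriverCall",
    "predictor_votes",
    "consensus_driver",
    "map_to_domain",
    "parse_protein_change",
    "screen_other_actionable",
    "load_domain_table",
    "default_domain_table",
    "load_actionable_sets",
    "default_actionable_sets",
    "read_annotation_table",
    "triage_annotations",
    "domain_summary",
    "votes_matrix",
]

PREDICTORS = ("sift", "polyphen2", "mutation_taster", "cadd", "cgi")

_SIFT = {"deleterious", "tolerated"}
_POLYPHEN = {"benign", "possibly_damaging", "probably_damaging"}
_MT = {"disease_causing", "neutral"}
_CGI = {"known_driver", "predicted_driver", "predicted_passenger"}
ACTIONABLE_CLASSES = {"actionable", "likely_actionable"}


@dataclass(frozen=True)
class PredictorProfile:
    """The five predictor outputs for one protein-level variant."""

    variant_id: str
    sift: str | None
    polyphen2: str | None
    mutation_taster: str | None
    cadd_phred: float | None
    cgi: str | None

    def __post_init__(self) -> None:
        for name, value, allowed in (("sift", self.sift, _SIFT),
                                     ("polyphen2", self.polyphen2, _POLYPHEN),
                                     ("mutation_taster", self.mutation_taster, _MT),
                                     ("cgi", self.cgi, _CGI)):
            if value is not None and value not in allowed:
                raise ValidationError(f"{name} value {value!r} not in {sorted(allowed)}")
        if self.cadd_phred is not None and self.cadd_phred < 0:
            raise ValidationError("cadd_phred must be non-negative")


@dataclass(frozen=True)
class DomainTable:
    """Non-overlapping protein domains as (name, start_residue, end_residue)."""

    domains: tuple[tuple[str, int, int], ...]

    def __post_init__(self) -> None:
        ordered = tuple(sorted(self.domains, key=lambda d: d[1]))
        object.__setattr__(self, "domains", ordered)
        for name, s, e in ordered:
            if s > e:
                raise ValidationError(f"domain {name}: start {s} > end {e}")
        for (na, _, ea), (nb, sb, _) in zip(ordered, ordered[1:]):
            if sb <= ea:
                raise ValidationError(f"domains {na} and {nb} overlap")


@dataclass(frozen=True)
class DriverCall:
    variant_id: str
    is_predicted_driver: bool
    per_predictor_votes: Mapping[str, str]
    domain: str


def predictor_votes(p: PredictorProfile, cadd_threshold: float = 25.0,
                    missing_policy: str = "error") -> dict[str, str]:
    """Map each predictor output onto a driver / non_driver vote.

    ``missing_policy`` decides what a ``None`` annotation does: ``"error"``
    (default) raises; ``"abstain"`` records a non_driver vote, which can
    only make the conjunction stricter.
    """
    if missing_policy not in ("error", "abstain"):
        raise ValidationError("missing_policy must be 'error' or 'abstain'")

    def vote(name: str, value, is_driver: bool | None) -> str:
        if value is None:
            if missing_policy == "error":
                raise MissingPredictorError(
                    f"variant {p.variant_id}: missing {name} annotation")
            return "non_driver"
        return "driver" if is_driver else "non_driver"

    return {
        "sift": vote("sift", p.sift, p.sift == "deleterious"),
        "polyphen2": vote("polyphen2", p.polyphen2,
                          p.polyphen2 in ("possibly_damaging", "probably_damaging")),
        "mutation_taster": vote("mutation_taster", p.mutation_taster,
                                p.mutation_taster == "disease_causing"),
        "cadd": vote("cadd", p.cadd_phred,
                     None if p.cadd_phred is None else p.cadd_phred > cadd_threshold),
        "cgi": vote("cgi", p.cgi, p.cgi in ("known_driver", "predicted_driver")),
    }


def consensus_driver(p: PredictorProfile, domain_table: DomainTable | None = None,
                     cadd_threshold: float = 25.0,
                     missing_policy: str = "error") -> DriverCall:
    """Driver call: the conjunction (AND) of all five predictor votes."""
    votes = predictor_votes(p, cadd_threshold, missing_policy)
    residue = parse_protein_change(p.variant_id)[1]
    domain = (map_to_domain(residue, domain_table)
              if domain_table is not None and residue is not None else "other")
    return DriverCall(
        variant_id=p.variant_id,
        is_predicted_driver=all(v == "driver" for v in votes.values()),
        per_predictor_votes=votes,
        domain=domain,
    )


_PCHANGE_RE = re.compile(r"^(?:p\.)?([A-Za-z*]{1,3})(\d+)([A-Za-z*]{1,3}|fs.*|del|dup|ins.*)$")


def parse_protein_change(variant_id: str) -> tuple[str | None, int | None, str | None]:
    """Parse "T992I"-style protein changes; returns (ref, residue, alt)."""
    m = _PCHANGE_RE.match(variant_id.strip())
    if not m:
        return (None, None, None)
    return (m.group(1), int(m.group(2)), m.group(3))


def map_to_domain(protein_residue: int, table: DomainTable | None = None) -> str:
    """Name of the domain containing the residue, else "other"."""
    if protein_residue < 1:
        raise ValidationError("protein residues are 1-based")
    table = table or default_domain_table()
    for name, s, e in table.domains:
        if s <= protein_residue <= e:
            return name
    return "other"


def screen_other_actionable(patient_variants: Iterable[tuple[str, str]],
                            actionable_any_solid: set[str],
                            actionable_lung: set[str]) -> tuple[bool, bool]:
    """Does the patient carry a non-MET variant in an actionable gene?

    ``patient_variants`` holds (gene, actionability_class) pairs for one
    patient.  The first flag checks against genes actionable in any
    solid-tumour indication, the second against lung-actionable genes only
    (so e.g. a co-occurring PIK3CA variant raises the first but not the
    second).
    """
    has_any = False
    has_lung = False
    for gene, _cls in patient_variants:
        if gene == "MET":
            continue
        if gene in actionable_any_solid:
            has_any = True
        if gene in actionable_lung:
            has_lung = True
    return (has_any, has_lung)


# ---------------------------------------------------------------------------
# Configuration and table I/O

def load_domain_table(path_or_stream) -> DomainTable:
    doc = (yaml.safe_load(path_or_stream.read()) if hasattr(path_or_stream, "read")
           else yaml.safe_load(open(path_or_stream).read()))
    return DomainTable(tuple((d["name"], int(d["start"]), int(d["end"]))
                             for d in doc["domains"]))


def default_domain_table() -> DomainTable:
    ref = resources.files("metex14.data").joinpath("met_domains.yaml")
    with ref.open() as fh:
        return load_domain_table(fh)


def load_actionable_sets(path_or_stream) -> tuple[set[str], set[str]]:
    """Returns (actionable_any_solid, actionable_lung) gene-symbol sets."""
    doc = (yaml.safe_load(path_or_stream.read()) if hasattr(path_or_stream, "read")
           else yaml.safe_load(open(path_or_stream).read()))
    return set(doc["actionable_any_solid"]), set(doc["actionable_lung"])


def default_actionable_sets() -> tuple[set[str], set[str]]:
    ref = resources.files("metex14.data").joinpath("actionable_genes.yaml")
    with ref.open() as fh:
        return load_actionable_sets(fh)


_ANNOT_COLS = ["variant_id", "gene", "protein_change", "sift", "polyphen2",
               "mutation_taster", "cadd_phred", "cgi", "clinical_significance"]


def read_annotation_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#")
    missing = set(_ANNOT_COLS) - set(df.columns)
    if missing:
        raise ValidationError(f"annotation table missing columns: {sorted(missing)}")
    return df


def triage_annotations(annotations: pd.DataFrame,
                       domain_table: DomainTable | None = None,
                       cadd_threshold: float = 25.0,
                       missing_policy: str = "error") -> pd.DataFrame:
    """Consensus-triage every annotated variant; one output row per variant.

    Variants already classed actionable / likely actionable bypass
    prediction: they are flagged actionable and never downgraded by the
    consensus.  Output columns: variant_id, gene, domain, the five votes,
    is_predicted_driver, is_actionable.
    """
    domain_table = domain_table or default_domain_table()
    rows = []
    for r in annotations.itertuples():
        profile = PredictorProfile(
            variant_id=str(r.protein_change or r.variant_id),
            sift=_opt_str(r.sift), polyphen2=_opt_str(r.polyphen2),
            mutation_taster=_opt_str(r.mutation_taster),
            cadd_phred=None if pd.isna(r.cadd_phred) else float(r.cadd_phred),
            cgi=_opt_str(r.cgi),
        )
        call = consensus_driver(profile, domain_table, cadd_threshold, missing_policy)
        rows.append({
            "variant_id": r.variant_id, "gene": r.gene,
            "protein_change": profile.variant_id, "domain": call.domain,
            **{f"vote_{k}": v for k, v in call.per_predictor_votes.items()},
            "is_predicted_driver": call.is_predicted_driver,
            "is_actionable": str(r.clinical_significance) in ACTIONABLE_CLASSES,
        })
    return pd.DataFrame(rows)


def _opt_str(value) -> str | None:
    if value is None or (isinstance(value, float) and pd.isna(value)):
        return None
    return str(value)


def domain_summary(driver_calls: pd.DataFrame) -> dict[str, dict[str, int]]:
    """Per-domain counts of triaged and consensus-driver variants."""
    out: dict[str, dict[str, int]] = {}
    for domain, grp in driver_calls.groupby("domain"):
        out[str(domain)] = {
            "n_variants": int(len(grp)),
            "n_predicted_drivers": int(grp["is_predicted_driver"].sum()),
        }
    return out


def votes_matrix(driver_calls: pd.DataFrame) -> pd.DataFrame:
    """Variant x predictor 0/1 matrix (1 = driver vote), heatmap-ready."""
    mat = driver_calls.set_index("protein_change")[
        [f"vote_{p}" for p in PREDICTORS]]
    mat = (mat == "driver").astype(int)
    mat.columns = list(PREDICTORS)
    return mat
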