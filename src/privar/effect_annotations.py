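"""Functional-effect annotation parsing and the coding-effect calculator.

Consumes SnpEff-style ``ANN`` INFO strings and dbNSFP-style categorical
predictor fields (SIFT, PolyPhen2-HDIV/HVAR, PROVEAN, MutationTaster,
FATHMM, GERP RS), computes the three-predictor damaging consensus
(SIFT D + HDIV D + HVAR D), and converts CDS substitutions to protein
consequences (e.g. c.131G>T -> p.Arg44Leu).
"""

from __future__ import annotations

import logging
import math
import re
from dataclasses import dataclass
from typing import Dict, List, Optional, Tuple

__all__ = [
    "IMPACT_ORDER",
    "EffectAnnotation",
    "PredictorCalls",
    "CodingChange",
    "AnnParseError",
    "parse_ann",
    "worst_impact",
    "worst_annotation",
    "parse_predictors",
    "consensus_damaging",
    "gerp_pass",
    "cds_to_protein_position",
    "apply_cds_substitution",
    "annotate_coding_effect",
    "GENETIC_CODE",
    "AA_THREE_LETTER",
]

logger = logging.getLogger(__name__)

#: SnpEff impact classes, most severe first.
IMPACT_ORDER = ("HIGH", "MODERATE", "LOW", "MODIFIER")
_IMPACT_RANK = {imp: i for i, imp in enumerate(IMPACT_ORDER)}


class AnnParseError(ValueError):
    """Raised for malformed ANN entries."""


@dataclass(frozen=True)
class EffectAnnotation:
    """One SnpEff ANN entry (one allele/effect/transcript combination)."""

    allele: str
    gene: str
    impact: str
    effect_terms: Tuple[str, ...]
    transcript: str = ""
    hgvs_c: Optional[str] = None
    hgvs_p: Optional[str] = None

    def __post_init__(self) -> None:
        if self.impact not in _IMPACT_RANK:
            raise AnnParseError(f"unknown impact class {self.impact!r}")


@dataclass(frozen=True)
class PredictorCalls:
    """Categorical dbNSFP predictor calls, collapsed to one call per tool.

    ``sift``: D (damaging) / T (tolerated); ``pph2_*``: D (probably
    damaging) / P (possibly) / B (benign); ``provean``: D / N. ``None``
    means no call. ``gerp_rs`` is the GERP rejected-substitutions score.
    """

    sift: Optional[str] = None
    pph2_hdiv: Optional[str] = None
    pph2_hvar: Optional[str] = None
    provean: Optional[str] = None
    mutation_taster: Optional[str] = None
    fathmm: Optional[str] = None
    gerp_rs: Optional[float] = None


@dataclass(frozen=True)
class CodingChange:
    """A single-base CDS substitution and its protein consequence."""

    cds_pos: int
    ref_base: str
    alt_base: str
    codon_number: int
    ref_aa: str  # three-letter code
    alt_aa: str
    hgvs_c: str
    hgvs_p: str
    synonymous: bool = False
    protein_length: Optional[int] = None


# ---------------------------------------------------------------------------
# ANN parsing
# ---------------------------------------------------------------------------

def parse_ann(ann_value: str) -> List[EffectAnnotation]:
    """Parse a SnpEff ANN INFO value into annotations.

    Entries are comma-separated; sub-fields pipe-delimited in SnpEff order
    (Allele | Annotation | Impact | Gene_Name | Gene_ID | Feature_Type |
    Feature_ID | ... | HGVS.c | HGVS.p | ...). At least the first four
    sub-fields must be present.
    """
    annotations: List[EffectAnnotation] = []
    for entry in ann_value.split(","):
        entry = entry.strip()
        if not entry:
            continue
        fields = entry.split("|")
        if len(fields) < 4:
            raise AnnParseError(f"ANN entry has fewer than 4 sub-fields: {entry!r}")
        allele, effects, impact, gene = fields[0], fields[1], fields[2], fields[3]
        if impact not in _IMPACT_RANK:
            raise AnnParseError(f"unknown impact {impact!r} in ANN entry {entry!r}")
        if not gene and impact != "MODIFIER":
            raise AnnParseError(f"missing gene symbol in non-MODIFIER entry {entry!r}")
        transcript = fields[6] if len(fields) > 6 else ""
        hgvs_c = fields[9] if len(fields) > 9 and fields[9] else None
        hgvs_p = fields[10] if len(fields) > 10 and fields[10] else None
        annotations.append(
            EffectAnnotation(
                allele=allele,
                gene=gene,
                impact=impact,
                effect_terms=tuple(t for t in effects.split("&") if t),
                transcript=transcript,
                hgvs_c=hgvs_c,
                hgvs_p=hgvs_p,
            )
        )
    return annotations


def worst_impact(annotations: List[EffectAnnotation]) -> str:
    """Most severe impact class (HIGH > MODERATE > LOW > MODIFIER)."""
    if not annotations:
        raise ValueError("empty annotation list")
    return min(annotations, key=lambda a: _IMPACT_RANK[a.impact]).impact


def worst_annotation(annotations: List[EffectAnnotation]) -> EffectAnnotation:
    """The first annotation attaining the worst impact (ties by order)."""
    if not annotations:
        raise ValueError("empty annotation list")
    worst = worst_impact(annotations)
    for ann in annotations:
        if ann.impact == worst:
            return ann
    raise AssertionError("unreachable")


# ---------------------------------------------------------------------------
# dbNSFP predictor parsing
# ---------------------------------------------------------------------------

#: Default INFO key for each predictor (SnpSift dbNSFP naming).
DEFAULT_PREDICTOR_KEYS: Dict[str, str] = {
    "sift": "dbNSFP_SIFT_pred",
    "pph2_hdiv": "dbNSFP_Polyphen2_HDIV_pred",
    "pph2_hvar": "dbNSFP_Polyphen2_HVAR_pred",
    "provean": "dbNSFP_PROVEAN_pred",
    "mutation_taster": "dbNSFP_MutationTaster_pred",
    "fathmm": "dbNSFP_FATHMM_pred",
    "gerp_rs": "dbNSFP_GERP___RS",
}

# Severity orders per predictor, worst first. MutationTaster: A (disease
# causing automatic), D (disease causing), N (polymorphism), P (poly.
# automatic).
_SEVERITY: Dict[str, Tuple[str, ...]] = {
    "sift": ("D", "T"),
    "pph2_hdiv": ("D", "P", "B"),
    "pph2_hvar": ("D", "P", "B"),
    "provean": ("D", "N"),
    "mutation_taster": ("A", "D", "N", "P"),
    "fathmm": ("D", "T"),
}

_TOKEN_SPLIT = re.compile(r"[,;|]")


def _worst_call(raw: str, order: Tuple[str, ...]) -> Optional[str]:
    tokens = [t.strip() for t in _TOKEN_SPLIT.split(raw)]
    calls = [t for t in tokens if t and t != "."]
    if not calls:
        return None
    known = [c for c in calls if c in order]
    if not known:
        return None
    return min(known, key=order.index)


def parse_predictors(
    info: Dict[str, str], keys: Optional[Dict[str, str]] = None
) -> PredictorCalls:
    """Extract predictor calls from an INFO map.

    Multi-transcript values (separated by ``,``, ``;`` or ``|``) collapse to
    the worst call per predictor; ``.`` tokens are ignored. An unparseable
    GERP value is treated as absent (with a warning).
    """
    keys = {**DEFAULT_PREDICTOR_KEYS, **(keys or {})}
    calls: Dict[str, Optional[str]] = {}
    for name, order in _SEVERITY.items():
        raw = info.get(keys[name])
        calls[name] = _worst_call(raw, order) if raw is not None else None
    gerp: Optional[float] = None
    raw = info.get(keys["gerp_rs"])
    if raw is not None:
        tokens = [t for t in _TOKEN_SPLIT.split(raw) if t.strip() and t.strip() != "."]
        values = []
        for t in tokens:
            try:
                v = float(t)
            except ValueError:
                logger.warning("unparseable GERP RS token %r; ignoring", t)
                continue
            if math.isfinite(v):
                values.append(v)
        if values:
            gerp = max(values)  # most constrained transcript
    return PredictorCalls(gerp_rs=gerp, **calls)


def consensus_damaging(calls: PredictorCalls) -> bool:
    """Strict three-predictor consensus: SIFT damaging AND PolyPhen2-HDIV
    probably damaging AND PolyPhen2-HVAR probably damaging.

    Absent calls are non-damaging: a variant cannot qualify on missing
    evidence.
    """
    return calls.sift == "D" and calls.pph2_hdiv == "D" and calls.pph2_hvar == "D"


def gerp_pass(calls: PredictorCalls, threshold: float = 4.0) -> bool:
    """GERP RS strictly above ``threshold`` (absent score fails).

    An optional cascade stage, disabled by default: the RS > 4 literature
    threshold is reported alongside candidates rather than used to select
    them.
    """
    return calls.gerp_rs is not None and calls.gerp_rs > threshold


# ---------------------------------------------------------------------------
# CDS -> protein coding-effect calculator
# ---------------------------------------------------------------------------

#: Standard nuclear genetic code (DNA codons, one-letter amino acids,
#: * = stop).
GENETIC_CODE: Dict[str, str] = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L",
    "CTT": "L", "CTC": "L", "CTA": "L", "CTG": "L",
    "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V",
    "TCT": "S", "TCC": "S", "TCA": "S", "TCG": "S",
    "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T",
    "GCT": "A", "GCC": "A", "GCA": "A", "GCG": "A",
    "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q",
    "AAT": "N", "AAC": "N", "AAA": "K", "AAG": "K",
    "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGA": "*", "TGG": "W",
    "CGT": "R", "CGC": "R", "CGA": "R", "CGG": "R",
    "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}

AA_THREE_LETTER: Dict[str, str] = {
    "A": "Ala", "R": "Arg", "N": "Asn", "D": "Asp", "C": "Cys",
    "Q": "Gln", "E": "Glu", "G": "Gly", "H": "His", "I": "Ile",
    "L": "Leu", "K": "Lys", "M": "Met", "F": "Phe", "P": "Pro",
    "S": "Ser", "T": "Thr", "W": "Trp", "Y": "Tyr", "V": "Val",
    "*": "Ter",
}


def cds_to_protein_position(cds_pos: int) -> Tuple[int, int]:
    """Map a 1-based CDS position to (codon number, offset in codon).

    codon = ceil(cds_pos / 3); offset in {1, 2, 3}.
    """
    if cds_pos < 1:
        raise ValueError(f"cds_pos must be >= 1, got {cds_pos}")
    codon_number = (cds_pos + 2) // 3
    offset = (cds_pos - 1) % 3 + 1
    return codon_number, offset


def _translate_codon(codon: str) -> str:
    if len(codon) != 3 or any(b not in "ACGT" for b in codon):
        raise ValueError(f"invalid codon {codon!r}")
    return GENETIC_CODE[codon]


def apply_cds_substitution(
    codon: str, offset: int, alt_base: str
) -> Tuple[str, str, bool]:
    """Substitute ``alt_base`` at ``offset`` (1-3) of ``codon``; translate
    both. Returns three-letter (ref_aa, alt_aa, synonymous).
    """
    codon = codon.upper()
    if offset not in (1, 2, 3):
        raise ValueError(f"offset must be 1, 2 or 3, got {offset}")
    if alt_base not in "ACGT":
        raise ValueError(f"invalid alternate base {alt_base!r}")
    ref_base = codon[offset - 1] if len(codon) == 3 else None
    ref_aa1 = _translate_codon(codon)  # validates the codon
    if alt_base == ref_base:
        raise ValueError(
            f"not a substitution: base at offset {offset} of {codon} is already {alt_base}"
        )
    alt_codon = codon[: offset - 1] + alt_base + codon[offset:]
    alt_aa1 = _translate_codon(alt_codon)
    return AA_THREE_LETTER[ref_aa1], AA_THREE_LETTER[alt_aa1], ref_aa1 == alt_aa1


def annotate_coding_effect(
    cds_sequence: str, cds_pos: int, ref: str, alt: str
) -> CodingChange:
    """Full coding-effect annotation of a single-base CDS substitution.

    The CDS must be in frame (length divisible by 3) and carry ``ref`` at
    ``cds_pos``. The reported protein length is len(cds)/3 - 1 (the stop
    codon is excluded). HGVS strings follow ``c.<pos><ref>><alt>`` and
    ``p.<RefAa><codon><AltAa>``.
    """
    cds = cds_sequence.upper()
    if len(cds) % 3 != 0:
        raise ValueError(f"CDS length {len(cds)} is not a multiple of 3")
    if not 1 <= cds_pos <= len(cds):
        raise ValueError(f"cds_pos {cds_pos} outside CDS of length {len(cds)}")
    ref = ref.upper()
    alt = alt.upper()
    found = cds[cds_pos - 1]
    if found != ref:
        raise ValueError(
            f"reference mismatch at CDS position {cds_pos}: sequence has "
            f"{found!r}, caller said {ref!r}"
        )
    codon_number, offset = cds_to_protein_position(cds_pos)
    codon = cds[(codon_number - 1) * 3 : codon_number * 3]
    ref_aa, alt_aa, synonymous = apply_cds_substitution(codon, offset, alt)
    hgvs_p = (
        f"p.{ref_aa}{codon_number}="
        if synonymous
        else f"p.{ref_aa}{codon_number}{alt_aa}"
    )
    return CodingChange(
        cds_pos=cds_pos,
        ref_base=ref,
        alt_base=alt,
        codon_number=codon_number,
        ref_aa=ref_aa,
        alt_aa=alt_aa,
        hgvs_c=f"c.{cds_pos}{ref}>{alt}",
        hgvs_p=hgvs_p,
        synonymous=synonymous,
        protein_length=len(cds) // 3 - 1,
    )
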