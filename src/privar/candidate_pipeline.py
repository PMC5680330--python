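"""Case-versus-panel candidate-gene cascade.

Given a filtered, annotated cohort VCF, the cascade finds alternate alleles
private to the affected case (absent from every panel sample), keeps
HIGH- and MODERATE-impact variants, requires the strict three-predictor
damaging consensus, crosses surviving genes with an OMIM-style phenotype
table, and applies inheritance-mode and phenotype-category filters:

    private -> impact (HIGH / MODERATE branches) -> SIFT+HDIV+HVAR consensus
            -> phenotype match -> inheritance compatibility -> category

A heterozygous variant is only compatible with dominant phenotypes (AD or
X-linked dominant); a homozygous one with any Mendelian mode. Phenotypes
whose labels are all bracketed ("nondiseases"), braced ("susceptibility to
multifactorial disorders") or question-marked (provisional gene-phenotype
relationship) cannot rescue a gene on their own.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple

import pandas as pd

from .effect_annotations import (
    PredictorCalls,
    consensus_damaging,
    gerp_pass,
    parse_ann,
    parse_predictors,
    worst_annotation,
)
from .variant_io import VariantSite

__all__ = [
    "PhenotypeEntry",
    "PrivateVariant",
    "CandidateCall",
    "CandidateReport",
    "PhenotypeLabelError",
    "find_private_variants",
    "parse_phenotype_label",
    "normalize_inheritance",
    "load_phenotype_table",
    "inheritance_compatible",
    "category_pass",
    "run_cascade",
]

#: Normalized inheritance-mode vocabulary.
INHERITANCE_MODES = ("AD", "AR", "XLD", "XLR", "other")

_MODE_SYNONYMS: Dict[str, str] = {
    "AD": "AD",
    "AUTOSOMAL DOMINANT": "AD",
    "AR": "AR",
    "AUTOSOMAL RECESSIVE": "AR",
    "XLD": "XLD",
    "X-LINKED DOMINANT": "XLD",
    "XL DOMINANT": "XLD",
    "XLR": "XLR",
    "X-LINKED RECESSIVE": "XLR",
    "XL RECESSIVE": "XLR",
}

#: Cascade stage keys in execution order.
STAGES = (
    "private_high",
    "private_moderate",
    "consensus_high",
    "consensus_moderate",
    "omim_matched",
    "inheritance_kept",
    "category_kept",
    "final_genes",
)


class PhenotypeLabelError(ValueError):
    """Raised for unbalanced category markers in a phenotype label."""


@dataclass(frozen=True)
class PhenotypeEntry:
    """One OMIM-style gene-phenotype association row."""

    gene: str
    phenotype_label: str
    clean_name: str
    mim_number: Optional[int]
    inheritance_modes: frozenset
    nondisease: bool
    susceptibility: bool
    provisional: bool

    @property
    def flagged(self) -> bool:
        """True when the phenotype carries any excluded-category marker."""
        return self.nondisease or self.susceptibility or self.provisional


@dataclass(frozen=True)
class PrivateVariant:
    """A case-private alternate allele at one site."""

    site: VariantSite
    allele: str  # the private ALT allele string
    allele_index: int  # 1-based ALT index
    zygosity: str  # "het" | "hom"


@dataclass
class CandidateCall:
    """One cascade survivor (or near-survivor, with a removal reason)."""

    variant: PrivateVariant
    gene: str
    impact: str
    predictors: PredictorCalls
    phenotypes: List[PhenotypeEntry] = field(default_factory=list)
    removed_at: Optional[str] = None  # stage name, None = final candidate


@dataclass
class CandidateReport:
    """Per-stage survivor counts and the final candidate list."""

    stage_counts: Dict[str, int]
    candidates: List[CandidateCall]
    removed: List[CandidateCall] = field(default_factory=list)

    @property
    def final_genes(self) -> List[str]:
        seen: List[str] = []
        for c in self.candidates:
            if c.gene not in seen:
                seen.append(c.gene)
        return seen

    def stage_counts_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"stage": list(self.stage_counts), "survivors": list(self.stage_counts.values())}
        )

    def candidates_frame(self) -> pd.DataFrame:
        rows = []
        for c in self.candidates:
            site = c.variant.site
            rows.append(
                {
                    "chrom": site.chrom,
                    "pos": site.pos,
                    "ref": site.ref,
                    "alt": c.variant.allele,
                    "gene": c.gene,
                    "zygosity": c.variant.zygosity,
                    "impact": c.impact,
                    "sift": c.predictors.sift or ".",
                    "hdiv": c.predictors.pph2_hdiv or ".",
                    "hvar": c.predictors.pph2_hvar or ".",
                    "gerp": "." if c.predictors.gerp_rs is None else c.predictors.gerp_rs,
                    "phenotype": ";".join(p.phenotype_label for p in c.phenotypes),
                    "mim": ";".join(
                        "." if p.mim_number is None else str(p.mim_number)
                        for p in c.phenotypes
                    ),
                    "inheritance": ";".join(
                        ",".join(sorted(p.inheritance_modes)) for p in c.phenotypes
                    ),
                }
            )
        columns = [
            "chrom", "pos", "ref", "alt", "gene", "zygosity", "impact",
            "sift", "hdiv", "hvar", "gerp", "phenotype", "mim", "inheritance",
        ]
        return pd.DataFrame(rows, columns=columns)

    def to_tsv(self, stage_path, candidates_path) -> None:
        self.stage_counts_frame().to_csv(stage_path, sep="\t", index=False)
        self.candidates_frame().to_csv(candidates_path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Private-allele detection
# ---------------------------------------------------------------------------

def find_private_variants(
    case_id: str, sites: Iterable[VariantSite]
) -> List[PrivateVariant]:
    """Alternate alleles carried by the case and absent from every panel
    sample.

    Privacy is allele-level: other alternate alleles at the same site do not
    matter. Missing panel genotypes contribute no allele observations
    (sites are expected to be completeness-filtered upstream). Zygosity is
    ``het`` for one copy in the case, ``hom`` for two.
    """
    out: List[PrivateVariant] = []
    n_sites = 0
    case_seen = False
    for site in sites:
        n_sites += 1
        case_gt = None
        panel_counts = [0] * site.n_alleles
        for gt in site.genotypes:
            if gt.sample_id == case_id:
                case_gt = gt
            elif gt.allele_indices is not None:
                for i in gt.allele_indices:
                    panel_counts[i] += 1
        if case_gt is None:
            continue
        case_seen = True
        if case_gt.allele_indices is None:
            continue
        for alt_index in range(1, site.n_alleles):
            k = case_gt.allele_count(alt_index)
            if k >= 1 and panel_counts[alt_index] == 0:
                out.append(
                    PrivateVariant(
                        site=site,
                        allele=site.alts[alt_index - 1],
                        allele_index=alt_index,
                        zygosity="hom" if k == 2 else "het",
                    )
                )
    if n_sites and not case_seen:
        raise ValueError(f"case sample {case_id!r} not present in any site's cohort")
    return out


def _check_case_in_cohort(case_id: str, samples: Sequence[str]) -> None:
    if case_id not in samples:
        raise ValueError(f"case sample {case_id!r} not in cohort {list(samples)}")


# ---------------------------------------------------------------------------
# Phenotype table
# ---------------------------------------------------------------------------

def parse_phenotype_label(label: str) -> Tuple[str, bool, bool, bool]:
    """Split OMIM category markers off a phenotype label.

    Returns (clean name, nondisease, susceptibility, provisional):
    ``[...]`` marks a nondisease, ``{...}`` susceptibility to a
    multifactorial disorder, and a leading ``?`` a provisional
    gene-phenotype relationship.
    """
    s = label.strip()
    provisional = False
    if s.startswith("?"):
        provisional = True
        s = s[1:].strip()
    nondisease = susceptibility = False
    if s.startswith("[") or s.endswith("]"):
        if not (s.startswith("[") and s.endswith("]")):
            raise PhenotypeLabelError(f"unbalanced brackets in {label!r}")
        nondisease = True
        s = s[1:-1].strip()
    if s.startswith("{") or s.endswith("}"):
        if not (s.startswith("{") and s.endswith("}")):
            raise PhenotypeLabelError(f"unbalanced braces in {label!r}")
        susceptibility = True
        s = s[1:-1].strip()
    return s, nondisease, susceptibility, provisional


def normalize_inheritance(raw: str) -> frozenset:
    """Normalize a comma-separated inheritance string to the fixed
    vocabulary; unrecognized tokens map to ``other`` (never compatible)."""
    modes: Set[str] = set()
    for token in raw.split(","):
        token = token.strip()
        if not token:
            continue
        modes.add(_MODE_SYNONYMS.get(token.upper(), "other"))
    return frozenset(modes)


def make_phenotype_entry(
    gene: str, label: str, mim_number: Optional[int], inheritance: str
) -> PhenotypeEntry:
    clean, nondisease, susceptibility, provisional = parse_phenotype_label(label)
    return PhenotypeEntry(
        gene=gene,
        phenotype_label=label,
        clean_name=clean,
        mim_number=mim_number,
        inheritance_modes=normalize_inheritance(inheritance),
        nondisease=nondisease,
        susceptibility=susceptibility,
        provisional=provisional,
    )


def load_phenotype_table(path: str | Path) -> Dict[str, List[PhenotypeEntry]]:
    """Load a TSV phenotype snapshot (columns: gene, phenotype, mim_number,
    inheritance) into a gene -> entries map."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = {"gene", "phenotype", "mim_number", "inheritance"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing phenotype table columns {sorted(missing)}")
    table: Dict[str, List[PhenotypeEntry]] = {}
    for row in df.itertuples(index=False):
        mim = None
        if row.mim_number not in ("", "."):
            mim = int(row.mim_number)
        entry = make_phenotype_entry(row.gene, row.phenotype, mim, row.inheritance)
        table.setdefault(row.gene, []).append(entry)
    return table


# ---------------------------------------------------------------------------
# Inheritance / category filters
# ---------------------------------------------------------------------------

def inheritance_compatible(zygosity: str, entry: PhenotypeEntry) -> bool:
    """Whether the case's zygosity can express the phenotype.

    Heterozygous: only dominant modes (AD, XLD). Homozygous: any Mendelian
    mode (AD, AR, XLD, XLR). ``other``/unknown modes are never compatible.
    """
    if zygosity == "het":
        allowed = {"AD", "XLD"}
    elif zygosity == "hom":
        allowed = {"AD", "AR", "XLD", "XLR"}
    else:
        raise ValueError(f"zygosity must be 'het' or 'hom', got {zygosity!r}")
    return bool(entry.inheritance_modes & allowed)


def category_pass(entries: List[PhenotypeEntry]) -> List[PhenotypeEntry]:
    """Keep the entry list only if at least one entry is category-clean
    (not a nondisease, susceptibility or provisional phenotype).

    Returns the unflagged entries, or an empty list when the gene is
    supported only by excluded categories (or by nothing).
    """
    clean = [e for e in entries if not e.flagged]
    return clean


# ---------------------------------------------------------------------------
# Cascade
# ---------------------------------------------------------------------------

def _classify(variant: PrivateVariant, predictor_keys=None) -> Optional[CandidateCall]:
    """Attach worst-impact annotation and predictor calls; None when the
    site has no parseable ANN annotation."""
    ann_raw = variant.site.info.get("ANN")
    if not ann_raw:
        return None
    annotations = [a for a in parse_ann(ann_raw) if a.allele in ("", variant.allele)]
    if not annotations:
        return None
    ann = worst_annotation(annotations)
    calls = parse_predictors(variant.site.info, predictor_keys)
    return CandidateCall(
        variant=variant, gene=ann.gene, impact=ann.impact, predictors=calls
    )


def run_cascade(
    case_id: str,
    sites: Iterable[VariantSite],
    phenotype_table: Dict[str, List[PhenotypeEntry]],
    samples: Optional[Sequence[str]] = None,
    gerp_threshold: Optional[float] = None,
    predictor_keys: Optional[Dict[str, str]] = None,
) -> CandidateReport:
    """Run the full prioritization cascade for one case against the panel.

    ``phenotype_table`` maps gene symbol to its phenotype entries (an empty
    table yields pre-crossing counts only). When ``gerp_threshold`` is set,
    an optional GERP RS stage is applied after the predictor consensus.
    Deterministic given its inputs.
    """
    if samples is not None:
        _check_case_in_cohort(case_id, samples)
    sites = list(sites)
    if samples is None and sites:
        cohort = [gt.sample_id for gt in sites[0].genotypes]
        _check_case_in_cohort(case_id, cohort)

    private = find_private_variants(case_id, sites)
    calls = [c for v in private if (c := _classify(v, predictor_keys)) is not None]

    counts: Dict[str, int] = {k: 0 for k in STAGES}
    removed: List[CandidateCall] = []
    survivors: List[CandidateCall] = []

    for branch, stage_private, stage_consensus in (
        ("HIGH", "private_high", "consensus_high"),
        ("MODERATE", "private_moderate", "consensus_moderate"),
    ):
        branch_calls = [c for c in calls if c.impact == branch]
        counts[stage_private] = len(branch_calls)
        for c in branch_calls:
            if not consensus_damaging(c.predictors):
                c.removed_at = stage_consensus
                removed.append(c)
                continue
            if gerp_threshold is not None and not gerp_pass(
                c.predictors, gerp_threshold
            ):
                c.removed_at = "gerp"
                removed.append(c)
                continue
            counts[stage_consensus] += 1
            survivors.append(c)

    # Phenotype-table crossing, inheritance and category filters run on the
    # pooled consensus survivors of both branches.
    matched: List[CandidateCall] = []
    for c in survivors:
        entries = phenotype_table.get(c.gene, [])
        if not entries:
            c.removed_at = "omim_matched"
            removed.append(c)
            continue
        c.phenotypes = list(entries)
        matched.append(c)
    counts["omim_matched"] = len(matched)

    inher_kept: List[CandidateCall] = []
    for c in matched:
        compatible = [
            e for e in c.phenotypes
            if inheritance_compatible(c.variant.zygosity, e)
        ]
        if not compatible:
            c.removed_at = "inheritance_kept"
            removed.append(c)
            continue
        c.phenotypes = compatible
        inher_kept.append(c)
    counts["inheritance_kept"] = len(inher_kept)

    final: List[CandidateCall] = []
    for c in inher_kept:
        clean = category_pass(c.phenotypes)
        if not clean:
            c.removed_at = "category_kept"
            removed.append(c)
            continue
        c.phenotypes = clean
        final.append(c)
    counts["category_kept"] = len(final)
    counts["final_genes"] = len({c.gene for c in final})

    return CandidateReport(stage_counts=counts, candidates=final, removed=removed)
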