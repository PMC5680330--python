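"""Variant data model and VCF/BED input/output.

Coordinate conventions used throughout the package are centralized here:
VCF positions are 1-based (as in the format), BED intervals are half-open
0-based, and all internal window arithmetic is half-open 0-based.
``IntervalMask.contains`` takes a 1-based position and converts it.
"""

from __future__ import annotations

import itertools
from bisect import bisect_right
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, Iterator, List, Optional, Sequence, Tuple

import pysam

__all__ = [
    "SampleGenotype",
    "VariantSite",
    "IntervalMask",
    "VcfParseError",
    "BedFormatError",
    "CohortMismatchError",
    "FILTER_LABELS",
    "read_vcf",
    "write_vcf",
    "load_mappability",
]

#: FILTER column labels written by the quality filters, with descriptions
#: used in the VCF header.
FILTER_LABELS: Dict[str, str] = {
    "q30": "Site quality at or below the QUAL threshold (default 30), or missing",
    "dp5": "A polymorphic genotype with read depth at or below the DP threshold (default 5), or missing",
    "miss": "Genotype missing in one or more individuals",
    "ab": "A heterozygous genotype with allele balance outside the accepted band (default [0.2, 0.8])",
    "ab_missing": "A heterozygous genotype lacking AD, so allele balance could not be assessed",
    "hwe": "Exact Hardy-Weinberg test p-value below alpha on the pooled cohort",
    "unmap": "Position outside the mappability mask",
}


class VcfParseError(ValueError):
    """Raised when a VCF header or record cannot be parsed."""


class BedFormatError(ValueError):
    """Raised when a BED line is malformed (e.g. start >= end)."""


class CohortMismatchError(ValueError):
    """Raised when genotype lists or sample lists disagree with the cohort."""


@dataclass(slots=True)
class SampleGenotype:
    """One sample's call at one site.

    ``allele_indices`` is a pair of 0-based allele indices (0 = REF,
    k = k-th ALT) or ``None`` when the genotype is missing ("./.").
    ``depth`` is the DP field and ``allele_depths`` the AD field (one count
    per allele, REF first); either may be absent.
    """

    sample_id: str
    allele_indices: Optional[Tuple[int, int]]
    depth: Optional[int] = None
    allele_depths: Optional[Tuple[int, ...]] = None

    @property
    def is_missing(self) -> bool:
        return self.allele_indices is None

    @property
    def is_het(self) -> bool:
        """True for a called genotype carrying two distinct allele indices."""
        return (
            self.allele_indices is not None
            and self.allele_indices[0] != self.allele_indices[1]
        )

    @property
    def is_polymorphic(self) -> bool:
        """True for a called genotype carrying at least one non-REF allele."""
        return self.allele_indices is not None and any(
            i != 0 for i in self.allele_indices
        )

    def allele_count(self, allele_index: int) -> int:
        """Copies of ``allele_index`` carried (0 when missing)."""
        if self.allele_indices is None:
            return 0
        return sum(1 for i in self.allele_indices if i == allele_index)


@dataclass
class VariantSite:
    """One multi-sample VCF record (multiallelic records kept un-split)."""

    chrom: str
    pos: int  # 1-based
    ref: str
    alts: Tuple[str, ...]
    qual: Optional[float]
    genotypes: List[SampleGenotype]
    info: Dict[str, str] = field(default_factory=dict)
    variant_id: Optional[str] = None
    filters: List[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if not self.ref or any(b not in "ACGTN" for b in self.ref):
            raise ValueError(f"invalid REF allele {self.ref!r}")
        for gt in self.genotypes:
            if gt.allele_indices is not None:
                for i in gt.allele_indices:
                    if not 0 <= i <= len(self.alts):
                        raise ValueError(
                            f"allele index {i} out of range at "
                            f"{self.chrom}:{self.pos} (n_alts={len(self.alts)})"
                        )

    @property
    def n_alleles(self) -> int:
        return 1 + len(self.alts)

    @property
    def is_biallelic_snv(self) -> bool:
        return (
            len(self.alts) == 1
            and len(self.ref) == 1
            and len(self.alts[0]) == 1
            and self.ref in "ACGT"
            and self.alts[0] in "ACGT"
        )

    def genotype_of(self, sample_id: str) -> SampleGenotype:
        for gt in self.genotypes:
            if gt.sample_id == sample_id:
                return gt
        raise KeyError(f"sample {sample_id!r} not in cohort at {self.chrom}:{self.pos}")


class IntervalMask:
    """Per-chromosome sorted, merged, half-open 0-based intervals.

    Built from BED input; queries take 1-based positions (VCF convention).
    """

    def __init__(self, intervals: Dict[str, Sequence[Tuple[int, int]]]):
        self._starts: Dict[str, List[int]] = {}
        self._ends: Dict[str, List[int]] = {}
        for chrom, ivs in intervals.items():
            merged = _merge_intervals(ivs)
            self._starts[chrom] = [s for s, _ in merged]
            self._ends[chrom] = [e for _, e in merged]

    @property
    def chroms(self) -> List[str]:
        return sorted(self._starts)

    def intervals(self, chrom: str) -> List[Tuple[int, int]]:
        return list(zip(self._starts.get(chrom, []), self._ends.get(chrom, [])))

    def contains(self, chrom: str, pos_1based: int) -> bool:
        """Membership of a 1-based position in the mask."""
        starts = self._starts.get(chrom)
        if not starts:
            return False
        p = pos_1based - 1
        i = bisect_right(starts, p) - 1
        return i >= 0 and p < self._ends[chrom][i]

    def total_length(self) -> int:
        """Total masked length in bp."""
        return sum(
            e - s
            for chrom in self._starts
            for s, e in zip(self._starts[chrom], self._ends[chrom])
        )


def _merge_intervals(ivs: Iterable[Tuple[int, int]]) -> List[Tuple[int, int]]:
    out: List[Tuple[int, int]] = []
    for s, e in sorted(ivs):
        if s >= e:
            raise BedFormatError(f"interval start {s} >= end {e}")
        if out and s <= out[-1][1]:  # overlap or adjacency
            out[-1] = (out[-1][0], max(out[-1][1], e))
        else:
            out.append((s, e))
    return out


# ---------------------------------------------------------------------------
# VCF reading
# ---------------------------------------------------------------------------

def _record_to_site(rec: "pysam.VariantRecord", samples: Sequence[str]) -> VariantSite:
    alts = tuple(rec.alts) if rec.alts else ()
    genotypes: List[SampleGenotype] = []
    for s in samples:
        call = rec.samples[s]
        gt = call.get("GT")
        if gt is None or len(gt) == 0 or any(a is None for a in gt):
            indices: Optional[Tuple[int, int]] = None
        elif len(gt) == 1:  # haploid call, duplicated to diploid
            indices = (gt[0], gt[0])
        else:
            indices = (gt[0], gt[1])
        dp = call.get("DP")
        ad = call.get("AD")
        if ad is not None:
            ad = tuple(int(a) for a in ad if a is not None)
            if not ad:
                ad = None
        genotypes.append(
            SampleGenotype(
                sample_id=s,
                allele_indices=indices,
                depth=None if dp is None else int(dp),
                allele_depths=ad,
            )
        )
    info: Dict[str, str] = {}
    for key, value in rec.info.items():
        if isinstance(value, (tuple, list)):
            info[key] = ",".join("." if v is None else str(v) for v in value)
        elif value is True:
            info[key] = ""
        else:
            info[key] = str(value)
    filters = [f for f in rec.filter.keys() if f != "PASS"]
    return VariantSite(
        chrom=rec.chrom,
        pos=rec.pos,
        ref=rec.ref,
        alts=alts,
        qual=rec.qual,
        genotypes=genotypes,
        info=info,
        variant_id=rec.id,
        filters=filters,
    )


def read_vcf(
    path: str | Path,
    samples_expected: Optional[Sequence[str]] = None,
) -> Tuple[Iterator[VariantSite], List[str], Dict[str, int]]:
    """Read a VCF file.

    Returns ``(sites, samples, contigs)`` where ``sites`` is an iterator of
    :class:`VariantSite` in file order, ``samples`` the cohort sample list,
    and ``contigs`` maps contig name to length (0 when the header does not
    state one).

    Raises :class:`VcfParseError` on malformed input and
    :class:`CohortMismatchError` when ``samples_expected`` disagrees with
    the header sample list.
    """
    path = Path(path)
    try:
        vf = pysam.VariantFile(str(path))
    except (ValueError, OSError) as exc:
        raise VcfParseError(f"{path}: cannot parse VCF header: {exc}") from exc
    samples = list(vf.header.samples)
    if samples_expected is not None and list(samples_expected) != samples:
        vf.close()
        raise CohortMismatchError(
            f"{path}: sample list {samples} != expected {list(samples_expected)}"
        )
    contigs = {name: (c.length or 0) for name, c in vf.header.contigs.items()}

    def _iter() -> Iterator[VariantSite]:
        # pysam does not expose line numbers; count data lines ourselves so
        # parse errors can name the offending record.
        try:
            for lineno, rec in enumerate(vf, start=1):
                try:
                    yield _record_to_site(rec, samples)
                except (ValueError, KeyError) as exc:
                    raise VcfParseError(
                        f"{path}: bad record at data line {lineno}: {exc}"
                    ) from exc
        finally:
            vf.close()

    return _iter(), samples, contigs


# ---------------------------------------------------------------------------
# VCF writing
# ---------------------------------------------------------------------------

#: INFO keys the pipeline writes/consumes, all declared as free strings.
_INFO_KEYS = (
    ("ANN", "Functional annotations: 'Allele|Annotation|Impact|Gene|...' (SnpEff-style)"),
    ("dbNSFP_SIFT_pred", "SIFT prediction, D=damaging T=tolerated"),
    ("dbNSFP_Polyphen2_HDIV_pred", "PolyPhen2 HDIV prediction, D/P/B"),
    ("dbNSFP_Polyphen2_HVAR_pred", "PolyPhen2 HVAR prediction, D/P/B"),
    ("dbNSFP_PROVEAN_pred", "PROVEAN prediction, D=deleterious N=neutral"),
    ("dbNSFP_MutationTaster_pred", "MutationTaster prediction"),
    ("dbNSFP_FATHMM_pred", "FATHMM prediction"),
    ("dbNSFP_GERP___RS", "GERP++ rejected-substitutions score"),
)


def _build_header(
    samples: Sequence[str],
    contigs: Optional[Dict[str, int]] = None,
    extra_info_keys: Iterable[str] = (),
) -> pysam.VariantHeader:
    header = pysam.VariantHeader()
    for name, length in (contigs or {}).items():
        if length:
            header.contigs.add(name, length=length)
        else:
            header.contigs.add(name)
    header.formats.add("GT", 1, "String", "Genotype")
    header.formats.add("DP", 1, "Integer", "Read depth")
    header.formats.add("AD", ".", "Integer", "Per-allele read depths")
    known = set()
    for key, desc in _INFO_KEYS:
        header.info.add(key, ".", "String", desc)
        known.add(key)
    for key in extra_info_keys:
        if key not in known:
            header.info.add(key, ".", "String", "Pipeline INFO field")
            known.add(key)
    for label, desc in FILTER_LABELS.items():
        header.filters.add(label, None, None, desc)
    for s in samples:
        header.add_sample(s)
    return header


def write_vcf(
    sites: Iterable[VariantSite],
    samples: Sequence[str],
    path: str | Path,
    contigs: Optional[Dict[str, int]] = None,
) -> None:
    """Write sites to ``path`` as uncompressed VCF v4.2.

    Contigs absent from ``contigs`` are added to the header as encountered
    (without a length). Raises :class:`CohortMismatchError` when a site's
    genotype list does not match ``samples``.
    """
    sites = list(sites)
    extra_keys = sorted({k for s in sites for k in s.info})
    header = _build_header(samples, contigs, extra_keys)
    for site in sites:
        if site.chrom not in header.contigs:
            header.contigs.add(site.chrom)
    vf = pysam.VariantFile(str(path), "w", header=header)
    try:
        for site in sites:
            if len(site.genotypes) != len(samples) or any(
                gt.sample_id != s for gt, s in zip(site.genotypes, samples)
            ):
                raise CohortMismatchError(
                    f"genotype list at {site.chrom}:{site.pos} does not match "
                    f"the cohort sample list"
                )
            rec = vf.new_record(
                contig=site.chrom,
                start=site.pos - 1,
                stop=site.pos - 1 + len(site.ref),
                alleles=(site.ref, *site.alts) if site.alts else (site.ref,),
                id=site.variant_id,
            )
            rec.qual = site.qual
            if site.filters:
                for label in site.filters:
                    rec.filter.add(label)
            else:
                rec.filter.add("PASS")
            for key, value in site.info.items():
                rec.info[key] = value if value != "" else True
            for gt in site.genotypes:
                call = rec.samples[gt.sample_id]
                call["GT"] = gt.allele_indices if gt.allele_indices is not None else (None, None)
                if gt.depth is not None:
                    call["DP"] = gt.depth
                if gt.allele_depths is not None:
                    call["AD"] = list(gt.allele_depths)
                call.phased = False
            vf.write(rec)
    finally:
        vf.close()


# ---------------------------------------------------------------------------
# BED reading
# ---------------------------------------------------------------------------

def load_mappability(path: str | Path) -> IntervalMask:
    """Load a BED3+ file of mappable regions into an :class:`IntervalMask`.

    Overlapping or adjacent intervals are merged. Lines starting with
    ``track``, ``browser`` or ``#`` are skipped.
    """
    path = Path(path)
    intervals: Dict[str, List[Tuple[int, int]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            if len(fields) < 3:
                raise BedFormatError(f"{path}:{lineno}: expected >= 3 columns")
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise BedFormatError(f"{path}:{lineno}: non-integer bounds") from exc
            if start >= end:
                raise BedFormatError(
                    f"{path}:{lineno}: start {start} >= end {end}"
                )
            intervals.setdefault(chrom, []).append((start, end))
    return IntervalMask(intervals)
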