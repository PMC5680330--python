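"""Site- and genotype-level quality filters for a multi-sample callset.

The filter battery mirrors standard post-calling QC on a FreeBayes cohort
VCF: site quality (QUAL > 30), per-polymorphic-genotype depth (DP > 5),
call completeness across the cohort, heterozygote allele balance within
[0.2, 0.8], an exact Hardy-Weinberg equilibrium test on the pooled cohort,
and a mappability mask. Thresholds are strict inequalities; a missing value
where a rule needs one fails that rule (conservative).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Tuple

from .variant_io import FILTER_LABELS, IntervalMask, VariantSite

__all__ = [
    "FilterConfig",
    "FilterStats",
    "site_quality_pass",
    "depth_pass",
    "completeness_pass",
    "allele_balance_pass",
    "hwe_exact_pvalue",
    "hwe_pass",
    "site_filter_labels",
    "apply_site_filters",
]


@dataclass
class FilterConfig:
    """Thresholds for the site filter battery.

    min_qual
        Site QUAL must strictly exceed this (default 30).
    min_dp
        Every polymorphic genotype's DP must strictly exceed this (default 5).
    ab_low, ab_high
        Accepted heterozygote allele-balance band, inclusive (default
        [0.2, 0.8]); values strictly outside fail.
    hwe_alpha
        Sites with exact-test p-value below this are removed (default 1e-4).
    require_complete
        Remove sites with any missing genotype (default True).
    site_level_ab
        When True (default) one out-of-band heterozygote removes the whole
        site; when False allele balance is ignored at the site level (the
        per-genotype information remains available to callers).
    mappability
        Optional mask; when given, sites outside it are removed.
    """

    min_qual: float = 30.0
    min_dp: int = 5
    ab_low: float = 0.2
    ab_high: float = 0.8
    hwe_alpha: float = 1e-4
    require_complete: bool = True
    site_level_ab: bool = True
    mappability: Optional[IntervalMask] = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.ab_low < self.ab_high <= 1.0):
            raise ValueError(
                f"need 0 <= ab_low < ab_high <= 1, got [{self.ab_low}, {self.ab_high}]"
            )
        if self.min_dp < 0:
            raise ValueError("min_dp must be >= 0")
        if not (0.0 < self.hwe_alpha < 1.0):
            raise ValueError("hwe_alpha must be in (0, 1)")


@dataclass
class FilterStats:
    """Per-label removal tallies for one filter pass."""

    sites_seen: int = 0
    sites_passing: int = 0
    removed: Dict[str, int] = field(default_factory=dict)

    def record(self, labels: List[str]) -> None:
        self.sites_seen += 1
        if not labels:
            self.sites_passing += 1
        for label in labels:
            self.removed[label] = self.removed.get(label, 0) + 1

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("filter_label\tsites_removed\n")
            for label in FILTER_LABELS:
                fh.write(f"{label}\t{self.removed.get(label, 0)}\n")
            fh.write(f"total_seen\t{self.sites_seen}\n")
            fh.write(f"total_passing\t{self.sites_passing}\n")


# ---------------------------------------------------------------------------
# Single-site predicates
# ---------------------------------------------------------------------------

def site_quality_pass(site: VariantSite, min_qual: float = 30.0) -> bool:
    """QUAL strictly above ``min_qual``; missing QUAL fails."""
    return site.qual is not None and site.qual > min_qual


def depth_pass(site: VariantSite, min_dp: int = 5) -> bool:
    """Every polymorphic genotype has DP strictly above ``min_dp``.

    Hom-ref and missing genotypes are not depth-checked; a site with no
    polymorphic genotype passes vacuously. A polymorphic genotype without a
    DP value fails.
    """
    for gt in site.genotypes:
        if gt.is_polymorphic:
            if gt.depth is None or gt.depth <= min_dp:
                return False
    return True


def completeness_pass(site: VariantSite) -> bool:
    """No missing genotype in the cohort (empty cohort passes vacuously)."""
    return all(not gt.is_missing for gt in site.genotypes)


def allele_balance(gt) -> Optional[float]:
    """Heterozygote allele balance: reads for the higher allele index over
    reads for both carried alleles. ``None`` when AD is absent/uninformative.
    """
    if not gt.is_het or gt.allele_depths is None:
        return None
    lo, hi = sorted(gt.allele_indices)
    if hi >= len(gt.allele_depths) or lo >= len(gt.allele_depths):
        return None
    total = gt.allele_depths[lo] + gt.allele_depths[hi]
    if total == 0:
        return None
    return gt.allele_depths[hi] / total


def allele_balance_pass(
    site: VariantSite, ab_low: float = 0.2, ab_high: float = 0.8
) -> Tuple[bool, Optional[str]]:
    """Site-level allele-balance check over all heterozygous genotypes.

    Returns ``(ok, label)``: the site fails with label ``"ab"`` when any
    heterozygote's balance is strictly outside [ab_low, ab_high], and with
    ``"ab_missing"`` when a heterozygote lacks usable AD. Sites with no
    heterozygote pass.
    """
    for gt in site.genotypes:
        if not gt.is_het:
            continue
        ab = allele_balance(gt)
        if ab is None:
            return False, "ab_missing"
        if ab < ab_low or ab > ab_high:
            return False, "ab"
    return True, None


# ---------------------------------------------------------------------------
# Exact Hardy-Weinberg test
# ---------------------------------------------------------------------------

def _log_het_prob(n_ab: int, n_a: int, n: int) -> float:
    """log P(n_ab heterozygotes | n diploids, n_a copies of allele a)."""
    n_b = 2 * n - n_a
    n_aa = (n_a - n_ab) // 2
    n_bb = (n_b - n_ab) // 2
    return (
        math.lgamma(n + 1)
        - math.lgamma(n_aa + 1)
        - math.lgamma(n_ab + 1)
        - math.lgamma(n_bb + 1)
        + n_ab * math.log(2.0)
        + math.lgamma(n_a + 1)
        + math.lgamma(n_b + 1)
        - math.lgamma(2 * n + 1)
    )


def hwe_exact_pvalue(n_aa: int, n_ab: int, n_bb: int) -> float:
    """Two-sided exact Hardy-Weinberg test p-value.

    Conditions on the observed allele counts and sums, over all heterozygote
    counts of the correct parity, the probabilities of outcomes no more
    probable than the observed one. Monomorphic tables return 1.0 exactly.
    """
    if min(n_aa, n_ab, n_bb) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_aa + n_ab + n_bb
    if n == 0:
        raise ValueError("all genotype counts are zero")
    n_a = 2 * n_aa + n_ab
    if n_a == 0 or n_a == 2 * n:
        return 1.0
    n_minor = min(n_a, 2 * n - n_a)
    log_obs = _log_het_prob(n_ab, n_a, n)
    # Heterozygote count shares the parity of the minor-allele count and
    # ranges up to min(n_a, n_b).
    p = 0.0
    for h in range(n_minor % 2, n_minor + 1, 2):
        lp = _log_het_prob(h, n_a, n)
        if lp <= log_obs + 1e-12:
            p += math.exp(lp)
    return min(p, 1.0)


def _pooled_genotype_counts(site: VariantSite) -> Tuple[int, int, int]:
    """Collapse to ref vs any-alt over called genotypes: (n_aa, n_ab, n_bb)."""
    n_aa = n_ab = n_bb = 0
    for gt in site.genotypes:
        if gt.allele_indices is None:
            continue
        k = sum(1 for i in gt.allele_indices if i != 0)
        if k == 0:
            n_aa += 1
        elif k == 1:
            n_ab += 1
        else:
            n_bb += 1
    return n_aa, n_ab, n_bb


def hwe_pass(site: VariantSite, alpha: float = 1e-4) -> bool:
    """Exact HWE test on the pooled cohort (ref vs any-alt collapse)."""
    n_aa, n_ab, n_bb = _pooled_genotype_counts(site)
    if n_aa + n_ab + n_bb == 0:
        return True  # nothing callable to test
    return hwe_exact_pvalue(n_aa, n_ab, n_bb) >= alpha


# ---------------------------------------------------------------------------
# Battery
# ---------------------------------------------------------------------------

def site_filter_labels(site: VariantSite, config: FilterConfig) -> List[str]:
    """All filter labels the site fails (empty list = passes everything)."""
    labels: List[str] = []
    if not site_quality_pass(site, config.min_qual):
        labels.append("q30")
    if not depth_pass(site, config.min_dp):
        labels.append("dp5")
    if config.require_complete and not completeness_pass(site):
        labels.append("miss")
    if config.site_level_ab:
        ok, label = allele_balance_pass(site, config.ab_low, config.ab_high)
        if not ok:
            labels.append(label)
    if not hwe_pass(site, config.hwe_alpha):
        labels.append("hwe")
    if config.mappability is not None and not config.mappability.contains(
        site.chrom, site.pos
    ):
        labels.append("unmap")
    return labels


def apply_site_filters(
    sites: Iterable[VariantSite], config: FilterConfig
) -> Tuple[List[VariantSite], FilterStats]:
    """Run the full battery; return surviving sites and per-label tallies.

    Surviving sites have an empty ``filters`` list (PASS); removed sites are
    not returned but their failure labels are tallied in the stats (a site
    failing several rules increments several counters).
    """
    stats = FilterStats()
    survivors: List[VariantSite] = []
    for site in sites:
        labels = site_filter_labels(site, config)
        stats.record(labels)
        if not labels:
            site.filters = []
            survivors.append(site)
        else:
            site.filters = labels
    return survivors, stats
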