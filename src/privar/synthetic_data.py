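"""Synthetic annotated multi-sample cohorts with machine-readable truth.

Emulates the statistical structure the prioritization pipeline assumes: a
case genome plus a healthy panel drawn from several diverged populations
(four chimpanzee-subspecies-like clusters of five plus a more distant
bonobo-like cluster of five, 26 samples in all). Population structure
follows the Balding-Nichols model: per site an ancestral frequency p is
drawn (Uniform(0.05, 0.95) by default) and each population's frequency
from Beta(p(1-F)/F, (1-p)(1-F)/F) with divergence F; genotypes are
binomial (Hardy-Weinberg within population). Read depths are Poisson
(mean 30, matching a 30X genome), heterozygote allele depths binomial
(DP, 0.5), and site qualities comfortably above the QUAL filter.

On top of the background the generator can plant, with a truth record of
everything planted: case-private candidate variants with chosen impact and
predictor profiles, runs of homozygosity, and sites that fail exactly one
quality filter. SnpEff-style ANN strings and dbNSFP-style predictor INFO
fields are fabricated in the real field order, so a genuinely annotated
VCF is drop-in compatible.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np

from .effect_annotations import annotate_coding_effect
from .variant_io import IntervalMask, SampleGenotype, VariantSite

__all__ = [
    "PopulationSpec",
    "CohortSpec",
    "GeneModel",
    "PlantRecord",
    "default_cohort_spec",
    "simulate_cohort",
    "plant_candidate",
    "plant_roh",
    "plant_filter_failures",
    "make_mappability",
    "make_cds",
    "make_phenotype_table",
    "TABLE2_LRP5_ROWS",
    "build_case_study",
    "CaseStudy",
]

#: Bundled OMIM-style snapshot for the LRP5 gene: six phenotype rows, all
#: autosomal dominant; one bracketed "nondisease" and one braced
#: susceptibility phenotype.
TABLE2_LRP5_ROWS: Tuple[Tuple[str, str, int, str], ...] = (
    ("LRP5", "Hyperostosis, endosteal", 144750, "AD"),
    ("LRP5", "Osteopetrosis, autosomal dominant", 607634, "AD"),
    ("LRP5", "Osteosclerosis", 144750, "AD"),
    ("LRP5", "van Buchem disease, type 2", 607636, "AD"),
    ("LRP5", "[Bone mineral density variability]", 601884, "AD"),
    ("LRP5", "{Osteoporosis}", 166710, "AD"),
)

_BASES = np.array(list("ACGT"))

#: Genome-wide impact-class rates (fractions of all variants) emulating a
#: 22.4M-variant great-ape callset: ~1.7k HIGH, ~47k MODERATE, ~84k LOW.
_IMPACT_RATES = {"HIGH": 7.7e-5, "MODERATE": 2.1e-3, "LOW": 3.7e-3}

_EFFECT_TERM = {
    "HIGH": "stop_gained",
    "MODERATE": "missense_variant",
    "LOW": "synonymous_variant",
    "MODIFIER": "intergenic_region",
}


@dataclass(frozen=True)
class PopulationSpec:
    name: str
    n_samples: int
    fst: float

    def __post_init__(self) -> None:
        if not 0.0 < self.fst < 1.0:
            raise ValueError(f"fst must be in (0,1), got {self.fst}")
        if self.n_samples < 0:
            raise ValueError("n_samples must be >= 0")


@dataclass
class CohortSpec:
    """Dimensions and distributions of one synthetic cohort."""

    populations: List[PopulationSpec]
    case_population: str
    n_sites: int
    chrom_lengths: Dict[str, int]
    seed: int
    base_freq_range: Tuple[float, float] = (0.05, 0.95)
    mean_depth: float = 30.0
    case_id: str = "case"
    annotate: bool = True

    def __post_init__(self) -> None:
        if self.n_sites < 1:
            raise ValueError("n_sites must be >= 1")
        if self.case_population not in {p.name for p in self.populations}:
            raise ValueError(
                f"case_population {self.case_population!r} not among populations"
            )

    @property
    def sample_names(self) -> List[str]:
        names = [
            f"{pop.name}_{i + 1}"
            for pop in self.populations
            for i in range(pop.n_samples)
        ]
        return names + [self.case_id]


@dataclass(frozen=True)
class GeneModel:
    """A synthetic single-exon protein-coding gene: the CDS occupies a
    contiguous genomic block starting at ``cds_genomic_start`` (1-based)."""

    gene: str
    chrom: str
    cds_genomic_start: int
    cds_sequence: str


@dataclass
class PlantRecord:
    """Everything deliberately planted into a fixture; sufficient to
    compute every expected downstream result without re-deriving it."""

    candidates: List[dict] = field(default_factory=list)
    roh_segments: List[dict] = field(default_factory=list)
    filter_failures: List[dict] = field(default_factory=list)
    phenotype_rows: List[list] = field(default_factory=list)
    sample_populations: Dict[str, str] = field(default_factory=dict)
    case_id: str = "case"
    case_population: str = ""

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "PlantRecord":
        with open(path) as fh:
            return cls(**json.load(fh))


def default_cohort_spec(seed: int, n_sites: int = 20_000) -> CohortSpec:
    """The default 26-sample study emulation: four chimpanzee-subspecies
    clusters of five (F = 0.1), a more distant bonobo cluster of five
    (F = 0.3), and a case drawn from the central cluster; two 10 Mbp
    chromosomes."""
    return CohortSpec(
        populations=[
            PopulationSpec("nigeria_cameroon", 5, 0.1),
            PopulationSpec("central", 5, 0.1),
            PopulationSpec("western", 5, 0.1),
            PopulationSpec("eastern", 5, 0.1),
            PopulationSpec("bonobo", 5, 0.3),
        ],
        case_population="central",
        n_sites=n_sites,
        chrom_lengths={"chr1": 10_000_000, "chr2": 10_000_000},
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Cohort simulation
# ---------------------------------------------------------------------------

def _unique_positions(rng: np.random.Generator, length: int, n: int) -> np.ndarray:
    """n distinct 1-based positions in [1, length], sorted."""
    if n > length:
        raise ValueError(f"cannot place {n} sites on a {length} bp chromosome")
    draw = rng.integers(1, length + 1, size=int(n * 1.3) + 16)
    pos = np.unique(draw)
    while len(pos) < n:
        extra = rng.integers(1, length + 1, size=n)
        pos = np.unique(np.concatenate([pos, extra]))
    keep = rng.choice(len(pos), size=n, replace=False)
    return np.sort(pos[keep])


def _balding_nichols_freqs(
    rng: np.random.Generator, p: np.ndarray, fst: float
) -> np.ndarray:
    a = p * (1.0 - fst) / fst
    b = (1.0 - p) * (1.0 - fst) / fst
    q = rng.beta(a, b)
    # Guard degenerate draws (beta can hit exact 0/1 at tiny shapes).
    return np.clip(q, 1e-6, 1.0 - 1e-6)


def simulate_cohort(spec: CohortSpec) -> Tuple[List[VariantSite], PlantRecord]:
    """Simulate the background cohort; deterministic under ``spec.seed``.

    Returns the sites (sorted by chrom, pos) and a truth record holding the
    sample -> population map (plant_* calls append to it).
    """
    rng = np.random.default_rng(spec.seed)
    samples = spec.sample_names
    n_samples = len(samples)
    n_sites = spec.n_sites

    # Site placement proportional to chromosome length.
    chroms = list(spec.chrom_lengths)
    lengths = np.array([spec.chrom_lengths[c] for c in chroms], dtype=float)
    alloc = np.floor(n_sites * lengths / lengths.sum()).astype(int)
    alloc[0] += n_sites - alloc.sum()
    site_chrom: List[str] = []
    site_pos: List[np.ndarray] = []
    for c, k in zip(chroms, alloc):
        site_chrom.extend([c] * int(k))
        site_pos.append(_unique_positions(rng, spec.chrom_lengths[c], int(k)))
    positions = np.concatenate(site_pos) if site_pos else np.empty(0, dtype=int)

    # Alleles.
    ref_idx = rng.integers(0, 4, n_sites)
    alt_idx = (ref_idx + rng.integers(1, 4, n_sites)) % 4
    refs = _BASES[ref_idx]
    alts = _BASES[alt_idx]

    # Balding-Nichols genotypes, case drawn from its population.
    lo, hi = spec.base_freq_range
    p = rng.uniform(lo, hi, n_sites)
    geno = np.empty((n_samples, n_sites), dtype=np.int8)
    row = 0
    case_row = n_samples - 1
    pop_of_sample: Dict[str, str] = {}
    for pop in spec.populations:
        q = _balding_nichols_freqs(rng, p, pop.fst)
        g = rng.binomial(2, q[None, :], size=(pop.n_samples, n_sites))
        geno[row : row + pop.n_samples] = g
        for i in range(pop.n_samples):
            pop_of_sample[samples[row + i]] = pop.name
        if pop.name == spec.case_population:
            geno[case_row] = rng.binomial(2, q)
        row += pop.n_samples
    pop_of_sample[spec.case_id] = spec.case_population

    # Depths, allele depths, site qualities.
    depth = rng.poisson(spec.mean_depth, size=(n_samples, n_sites)).astype(np.int32)
    np.maximum(depth, 1, out=depth)
    alt_reads = rng.binomial(depth, 0.5)
    qual = np.round(rng.uniform(40.0, 1500.0, n_sites), 1)

    # Fabricated annotations.
    if spec.annotate:
        u = rng.random(n_sites)
        impact = np.full(n_sites, "MODIFIER", dtype=object)
        hi_r = _IMPACT_RATES["HIGH"]
        mo_r = _IMPACT_RATES["MODERATE"]
        lo_r = _IMPACT_RATES["LOW"]
        impact[u < hi_r] = "HIGH"
        impact[(u >= hi_r) & (u < hi_r + mo_r)] = "MODERATE"
        impact[(u >= hi_r + mo_r) & (u < hi_r + mo_r + lo_r)] = "LOW"
        sift = np.where(rng.random(n_sites) < 0.15, "D", "T")
        hdiv = np.select(
            [rng.random(n_sites) < 0.2, rng.random(n_sites) < 0.4],
            ["D", "P"],
            default="B",
        )
        hvar = np.select(
            [rng.random(n_sites) < 0.2, rng.random(n_sites) < 0.4],
            ["D", "P"],
            default="B",
        )
        gerp = np.round(np.clip(rng.normal(1.5, 2.0, n_sites), -12.3, 6.17), 2)
        impact_l = impact.tolist()
        sift_l = sift.tolist()
        hdiv_l = hdiv.tolist()
        hvar_l = hvar.tolist()
        gerp_l = gerp.tolist()
    # Plain-list views: per-site columns without numpy scalar overhead.
    geno_t = geno.T.tolist()
    depth_t = depth.T.tolist()
    alt_reads_t = alt_reads.T.tolist()
    qual_l = qual.tolist()
    pos_l = positions.tolist()
    refs_l = refs.tolist()
    alts_l = alts.tolist()

    sites: List[VariantSite] = []
    for j in range(n_sites):
        gcol = geno_t[j]
        dcol = depth_t[j]
        acol = alt_reads_t[j]
        genotypes = []
        for i, s in enumerate(samples):
            g = gcol[i]
            d = dcol[i]
            if g == 0:
                gt = (0, 0)
                ad = (d, 0)
            elif g == 2:
                gt = (1, 1)
                ad = (0, d)
            else:
                gt = (0, 1)
                a = acol[i]
                ad = (d - a, a)
            genotypes.append(SampleGenotype(s, gt, depth=d, allele_depths=ad))
        info: Dict[str, str] = {}
        if spec.annotate:
            imp = impact_l[j]
            gene = f"BG{j:06d}"
            info["ANN"] = (
                f"{alts_l[j]}|{_EFFECT_TERM[imp]}|{imp}|{gene}|{gene}|"
                f"transcript|{gene}.t1|protein_coding|1/1||"
            )
            if imp in ("MODERATE", "HIGH"):
                info["dbNSFP_SIFT_pred"] = sift_l[j]
                info["dbNSFP_Polyphen2_HDIV_pred"] = hdiv_l[j]
                info["dbNSFP_Polyphen2_HVAR_pred"] = hvar_l[j]
                info["dbNSFP_GERP___RS"] = str(gerp_l[j])
        sites.append(
            VariantSite(
                chrom=site_chrom[j],
                pos=pos_l[j],
                ref=refs_l[j],
                alts=(alts_l[j],),
                qual=qual_l[j],
                genotypes=genotypes,
                info=info,
            )
        )
    sites.sort(key=lambda s: (s.chrom, s.pos))
    truth = PlantRecord(
        sample_populations=pop_of_sample,
        case_id=spec.case_id,
        case_population=spec.case_population,
    )
    return sites, truth


# ---------------------------------------------------------------------------
# Planting
# ---------------------------------------------------------------------------

def make_cds(
    rng: np.random.Generator,
    n_codons: int,
    fixed_codons: Optional[Dict[int, str]] = None,
) -> str:
    """A random in-frame CDS: ATG start, no internal stop, stop at the end;
    ``fixed_codons`` pins specific 1-based codon numbers to given triplets.
    """
    stops = {"TAA", "TAG", "TGA"}
    non_stop = [c for c in _codon_list() if c not in stops]
    codons = ["ATG"]
    for _ in range(n_codons - 2):
        codons.append(non_stop[rng.integers(0, len(non_stop))])
    codons.append("TAA")
    for number, triplet in (fixed_codons or {}).items():
        if not 1 <= number <= n_codons:
            raise ValueError(f"codon number {number} outside CDS of {n_codons} codons")
        codons[number - 1] = triplet
    return "".join(codons)


def _codon_list() -> List[str]:
    return [a + b + c for a in "ACGT" for b in "ACGT" for c in "ACGT"]


def plant_candidate(
    sites: List[VariantSite],
    truth: PlantRecord,
    gene_model: GeneModel,
    profile: Dict[str, str],
    impact: str = "MODERATE",
    zygosity: str = "het",
    cds_pos: int = 131,
    alt_base: Optional[str] = None,
) -> VariantSite:
    """Plant one case-private coding variant; mutates ``sites`` in place
    (kept sorted) and appends to the truth record.

    ``profile`` maps dbNSFP INFO keys (e.g. ``dbNSFP_SIFT_pred``) to raw
    values. The substitution's HGVS strings come from the coding-effect
    calculator applied to the gene model. Raises on collision with an
    existing variant locus.
    """
    if not sites:
        raise ValueError("cannot plant into an empty site list")
    if zygosity not in ("het", "hom"):
        raise ValueError(f"zygosity must be het|hom, got {zygosity!r}")
    cds = gene_model.cds_sequence.upper()
    ref = cds[cds_pos - 1]
    if alt_base is None:
        alt_base = next(b for b in "ACGT" if b != ref)
    change = annotate_coding_effect(cds, cds_pos, ref, alt_base)
    pos = gene_model.cds_genomic_start + cds_pos - 1
    occupied = {
        (s.chrom, s.pos) for s in sites
    }
    if (gene_model.chrom, pos) in occupied:
        raise ValueError(
            f"locus collision: {gene_model.chrom}:{pos} already carries a variant"
        )
    samples = [gt.sample_id for gt in sites[0].genotypes]
    case_id = truth.case_id
    genotypes = []
    for s in samples:
        if s == case_id:
            gt = (1, 1) if zygosity == "hom" else (0, 1)
            ad = (0, 30) if zygosity == "hom" else (15, 15)
        else:
            gt = (0, 0)
            ad = (30, 0)
        genotypes.append(SampleGenotype(s, gt, depth=30, allele_depths=ad))
    effect = (
        "stop_gained"
        if change.alt_aa == "Ter"
        else ("synonymous_variant" if change.synonymous else "missense_variant")
    )
    info = {
        "ANN": (
            f"{alt_base}|{effect}|{impact}|{gene_model.gene}|{gene_model.gene}|"
            f"transcript|{gene_model.gene}.t1|protein_coding|2/2|"
            f"{change.hgvs_c}|{change.hgvs_p}"
        )
    }
    info.update(profile)
    site = VariantSite(
        chrom=gene_model.chrom,
        pos=pos,
        ref=ref,
        alts=(alt_base,),
        qual=60.0,
        genotypes=genotypes,
        info=info,
    )
    sites.append(site)
    sites.sort(key=lambda s: (s.chrom, s.pos))
    truth.candidates.append(
        {
            "chrom": gene_model.chrom,
            "pos": pos,
            "ref": ref,
            "alt": alt_base,
            "gene": gene_model.gene,
            "impact": impact,
            "zygosity": zygosity,
            "hgvs_c": change.hgvs_c,
            "hgvs_p": change.hgvs_p,
            "profile": dict(profile),
        }
    )
    return site


def plant_roh(
    sites: List[VariantSite],
    truth: PlantRecord,
    sample: str,
    chrom: str,
    start: int,
    end: int,
) -> int:
    """Force ``sample`` homozygous at every site in [start, end) (0-based
    bounds); returns the number of genotypes modified. A zero-length region
    is a no-op."""
    if end <= start:
        return 0
    n = 0
    for site in sites:
        if site.chrom != chrom or not (start < site.pos <= end):
            continue
        gt = site.genotype_of(sample)
        allele = 0 if gt.allele_indices is None else gt.allele_indices[0]
        depth = gt.depth if gt.depth is not None else 30
        ad = [0] * site.n_alleles
        ad[allele] = depth
        gt.allele_indices = (allele, allele)
        gt.allele_depths = tuple(ad)
        gt.depth = depth
        n += 1
    truth.roh_segments.append(
        {"sample": sample, "chrom": chrom, "start": start, "end": end}
    )
    return n


def plant_filter_failures(
    sites: List[VariantSite],
    truth: PlantRecord,
    labels: Sequence[str],
    seed: int = 0,
) -> List[VariantSite]:
    """Mutate distinct background sites so each fails exactly one filter.

    ``labels`` lists one entry per failure to plant, drawn from
    {q30, dp5, miss, ab, ab_missing, hwe}; ``unmap`` failures are planted by
    excluding positions from the mask instead (see :func:`make_mappability`).
    Returns the mutated sites in ``labels`` order.
    """
    rng = np.random.default_rng(seed)
    planted_loci = {(c["chrom"], c["pos"]) for c in truth.candidates}
    candidates = [
        i
        for i, s in enumerate(sites)
        if (s.chrom, s.pos) not in planted_loci
    ]
    if len(labels) > len(candidates):
        raise ValueError("more planted failures requested than available sites")
    chosen = rng.choice(len(candidates), size=len(labels), replace=False)
    out: List[VariantSite] = []
    for label, ci in zip(labels, chosen):
        site = sites[candidates[int(ci)]]
        _force_failure(site, label, rng)
        truth.filter_failures.append(
            {"chrom": site.chrom, "pos": site.pos, "label": label}
        )
        out.append(site)
    return out


def _force_failure(site: VariantSite, label: str, rng: np.random.Generator) -> None:
    def _make_het(gt: SampleGenotype) -> None:
        gt.allele_indices = (0, 1)
        gt.depth = 30
        gt.allele_depths = (15, 15)

    if label == "q30":
        site.qual = float(np.round(rng.uniform(0, 30), 1))
    elif label == "dp5":
        gt = site.genotypes[0]
        _make_het(gt)
        d = int(rng.integers(2, 6))  # 2..5: fails DP>5 with balanced AD
        gt.depth = d
        gt.allele_depths = (d - d // 2, d // 2)
    elif label == "miss":
        gt = site.genotypes[0]
        gt.allele_indices = None
        gt.allele_depths = None
        gt.depth = None
    elif label == "ab":
        gt = site.genotypes[0]
        _make_het(gt)
        gt.allele_depths = (27, 3)  # AB = 0.1
        gt.depth = 30
    elif label == "ab_missing":
        gt = site.genotypes[0]
        _make_het(gt)
        gt.allele_depths = None
    elif label == "hwe":
        for gt in site.genotypes:  # every sample heterozygous
            _make_het(gt)
    else:
        raise ValueError(f"cannot plant failure label {label!r}")


def make_mappability(
    chrom_lengths: Dict[str, int],
    exclude: Sequence[Tuple[str, int]] = (),
    truth: Optional[PlantRecord] = None,
) -> IntervalMask:
    """A mask covering every chromosome except the 1-based positions in
    ``exclude`` (recorded in the truth as planted ``unmap`` failures)."""
    by_chrom: Dict[str, List[int]] = {}
    for chrom, pos in exclude:
        by_chrom.setdefault(chrom, []).append(pos - 1)  # to 0-based
    intervals: Dict[str, List[Tuple[int, int]]] = {}
    for chrom, length in chrom_lengths.items():
        holes = sorted(by_chrom.get(chrom, []))
        ivs: List[Tuple[int, int]] = []
        prev = 0
        for h in holes:
            if h > prev:
                ivs.append((prev, h))
            prev = h + 1
        if prev < length:
            ivs.append((prev, length))
        intervals[chrom] = ivs
    if truth is not None:
        for chrom, pos in exclude:
            truth.filter_failures.append(
                {"chrom": chrom, "pos": pos, "label": "unmap"}
            )
    return IntervalMask(intervals)


# ---------------------------------------------------------------------------
# Phenotype table
# ---------------------------------------------------------------------------

def make_phenotype_table(
    rows: Iterable[Tuple[str, str, Optional[int], str]], path
) -> None:
    """Write an OMIM-style snapshot TSV (gene, phenotype, mim_number,
    inheritance). Raises on duplicate (gene, phenotype) rows."""
    seen = set()
    lines = ["gene\tphenotype\tmim_number\tinheritance"]
    for gene, label, mim, modes in rows:
        key = (gene, label)
        if key in seen:
            raise ValueError(f"duplicate phenotype row {key}")
        seen.add(key)
        lines.append(f"{gene}\t{label}\t{'' if mim is None else mim}\t{modes}")
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Ready-made end-to-end scenario
# ---------------------------------------------------------------------------

@dataclass
class CaseStudy:
    """A cohort with one qualifying planted candidate plus decoys."""

    sites: List[VariantSite]
    samples: List[str]
    truth: PlantRecord
    phenotype_rows: List[Tuple[str, str, Optional[int], str]]
    target_gene: str


def build_case_study(seed: int, n_sites: int = 20_000) -> CaseStudy:
    """Default cohort plus the planted scenario exercised end to end.

    Plants one qualifying candidate (heterozygous, MODERATE, damaging by
    all three consensus predictors, in a gene with a clean dominant
    phenotype) and four decoys: a HIGH-impact consensus-damaging variant in
    a recessive-only gene (discarded at the inheritance stage, as the
    real analysis discarded its high-impact survivor), a MODERATE
    consensus variant in a susceptibility-only gene (category stage), a
    MODERATE variant failing the predictor consensus, and a MODERATE
    consensus variant in a gene with no phenotype entry (crossing stage).
    """
    spec = default_cohort_spec(seed, n_sites=n_sites)
    sites, truth = simulate_cohort(spec)
    rng = np.random.default_rng(spec.seed + 1)

    ddd = {
        "dbNSFP_SIFT_pred": "D",
        "dbNSFP_Polyphen2_HDIV_pred": "D",
        "dbNSFP_Polyphen2_HVAR_pred": "D",
        "dbNSFP_PROVEAN_pred": "D",
        "dbNSFP_MutationTaster_pred": "D",
        "dbNSFP_GERP___RS": "4.23",
    }
    tdd = dict(ddd, dbNSFP_SIFT_pred="T")

    occupied = {(s.chrom, s.pos) for s in sites}

    def _gene(
        name: str, chrom: str, start: int, cds_pos: int = 131, n_codons: int = 200
    ) -> GeneModel:
        # Nudge the CDS start until the planted locus is collision-free.
        while (chrom, start + cds_pos - 1) in occupied:
            start += 1
        occupied.add((chrom, start + cds_pos - 1))
        return GeneModel(
            gene=name,
            chrom=chrom,
            cds_genomic_start=start,
            cds_sequence=make_cds(rng, n_codons, fixed_codons={44: "CGA"}),
        )

    target = _gene("LRP5", "chr1", 2_000_003)
    plant_candidate(sites, truth, target, ddd, impact="MODERATE", zygosity="het",
                    cds_pos=131, alt_base="T")
    # cds_pos 130 is offset 1 of the pinned CGA codon; C>T makes TGA (stop).
    decoy_ar = _gene("DECOY_AR", "chr1", 4_000_003, cds_pos=130)
    plant_candidate(sites, truth, decoy_ar, ddd, impact="HIGH", zygosity="het",
                    cds_pos=130, alt_base="T")
    decoy_susc = _gene("DECOY_SUSC", "chr2", 2_000_003)
    plant_candidate(sites, truth, decoy_susc, ddd, impact="MODERATE", zygosity="het")
    decoy_tdd = _gene("DECOY_TDD", "chr2", 4_000_003)
    plant_candidate(sites, truth, decoy_tdd, tdd, impact="MODERATE", zygosity="het")
    decoy_noomim = _gene("DECOY_NOOMIM", "chr2", 6_000_003)
    plant_candidate(sites, truth, decoy_noomim, ddd, impact="MODERATE", zygosity="het")

    phenotype_rows: List[Tuple[str, str, Optional[int], str]] = list(TABLE2_LRP5_ROWS)
    phenotype_rows += [
        ("DECOY_AR", "Recessive bone dysplasia", 600001, "AR"),
        ("DECOY_SUSC", "{Susceptibility phenotype}", 600002, "AD"),
        ("DECOY_TDD", "Dominant decoy phenotype", 600003, "AD"),
    ]
    truth.phenotype_rows = [list(r) for r in phenotype_rows]
    return CaseStudy(
        sites=sites,
        samples=spec.sample_names,
        truth=truth,
        phenotype_rows=phenotype_rows,
        target_gene="LRP5",
    )
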