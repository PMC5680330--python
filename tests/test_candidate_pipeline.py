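"""Private-allele detection, phenotype parsing, and the full cascade."""

import numpy as np
import pandas as pd
import pytest

from privar.candidate_pipeline import (
    PhenotypeLabelError,
    STAGES,
    category_pass,
    find_private_variants,
    inheritance_compatible,
    load_phenotype_table,
    make_phenotype_entry,
    normalize_inheritance,
    parse_phenotype_label,
    run_cascade,
)
from privar.synthetic_data import build_case_study, make_phenotype_table
from privar.variant_io import SampleGenotype, VariantSite

from conftest import make_site


# ---------------------------------------------------------------------------
# Private variants
# ---------------------------------------------------------------------------

class TestFindPrivate:
    def test_case_only_het_is_private(self):
        site = make_site([((0, 1), 30, (15, 15)), ((0, 0), 30, (30, 0))])
        (pv,) = find_private_variants("s0", [site])
        assert pv.allele == "G" and pv.zygosity == "het"

    def test_shared_allele_is_not_private(self):
        site = make_site([((0, 1), 30, (15, 15)), ((0, 1), 30, (15, 15))])
        assert find_private_variants("s0", [site]) == []

    def test_hom_case_zygosity(self):
        site = make_site([((1, 1), 30, (0, 30)), ((0, 0), 30, (30, 0))])
        (pv,) = find_private_variants("s0", [site])
        assert pv.zygosity == "hom"

    def test_allele_level_privacy_on_multiallelic_site(self):
        """The case's alt is private even when the panel carries another alt."""
        site = make_site(
            [((0, 2), 30, (15, 0, 15)), ((0, 1), 30, (15, 15, 0))],
            alts=("G", "T"),
        )
        (pv,) = find_private_variants("s0", [site])
        assert pv.allele == "T" and pv.allele_index == 2

    def test_absent_case_raises(self):
        site = make_site([((0, 1), 30, (15, 15))])
        with pytest.raises(ValueError, match="not present"):
            find_private_variants("absent_sample", [site])

    def test_matches_brute_force_oracle(self):
        """Randomized 1,000-site fixture vs an independent allele-count scan."""
        rng = np.random.default_rng(42)
        samples = [f"s{i}" for i in range(8)]
        case = "s0"
        sites = []
        for j in range(1000):
            n_alt = int(rng.integers(1, 3))
            alts = tuple("GT"[:n_alt])
            genotypes = []
            for s in samples:
                if rng.random() < 0.03:
                    genotypes.append(SampleGenotype(s, None))
                else:
                    idx = tuple(sorted(rng.integers(0, n_alt + 1, 2).tolist()))
                    genotypes.append(SampleGenotype(s, idx))
            sites.append(
                VariantSite("chr1", j + 1, "A", alts, 50.0, genotypes)
            )
        got = {
            (pv.site.pos, pv.allele_index, pv.zygosity)
            for pv in find_private_variants(case, sites)
        }
        # Oracle: per-site allele-count tables built the pedestrian way.
        expected = set()
        for site in sites:
            table_case: dict = {}
            table_panel: dict = {}
            for gt in site.genotypes:
                tab = table_case if gt.sample_id == case else table_panel
                for a in gt.allele_indices or ():
                    tab[a] = tab.get(a, 0) + 1
            for a, k in table_case.items():
                if a != 0 and table_panel.get(a, 0) == 0:
                    expected.add((site.pos, a, "hom" if k == 2 else "het"))
        assert got == expected


# ---------------------------------------------------------------------------
# Phenotype labels / inheritance / categories
# ---------------------------------------------------------------------------

class TestPhenotypeLabels:
    @pytest.mark.parametrize(
        "label,clean,flags",
        [
            ("[Bone mineral density variability]", "Bone mineral density variability", (True, False, False)),
            ("{Osteoporosis}", "Osteoporosis", (False, True, False)),
            ("Osteosclerosis", "Osteosclerosis", (False, False, False)),
            ("?Provisional syndrome", "Provisional syndrome", (False, False, True)),
            ("?{Combined}", "Combined", (False, True, True)),
        ],
    )
    def test_marker_parsing(self, label, clean, flags):
        got = parse_phenotype_label(label)
        assert got == (clean, *flags)

    @pytest.mark.parametrize("label", ["[Unbalanced", "Unbalanced}", "{Nope"])
    def test_unbalanced_markers_raise(self, label):
        with pytest.raises(PhenotypeLabelError):
            parse_phenotype_label(label)

    def test_inheritance_normalization(self):
        assert normalize_inheritance("AD, Autosomal recessive") == {"AD", "AR"}
        assert normalize_inheritance("X-linked dominant") == {"XLD"}
        assert normalize_inheritance("digenic") == {"other"}


class TestInheritance:
    @pytest.mark.parametrize(
        "zygosity,modes,expected",
        [
            ("het", "AD", True),
            ("het", "AR", False),
            ("hom", "AR", True),
            ("het", "XLD", True),
            ("het", "XLR", False),
            ("hom", "XLR", True),
            ("het", "other", False),
            ("hom", "other", False),
        ],
    )
    def test_compatibility(self, zygosity, modes, expected):
        entry = make_phenotype_entry("G", "Phenotype", 1, modes)
        assert inheritance_compatible(zygosity, entry) is expected


class TestCategory:
    def test_mixed_entries_keep_clean_ones(self):
        entries = [
            make_phenotype_entry("LRP5", "[Bone mineral density variability]", 601884, "AD"),
            make_phenotype_entry("LRP5", "Osteosclerosis", 144750, "AD"),
        ]
        kept = category_pass(entries)
        assert [e.clean_name for e in kept] == ["Osteosclerosis"]

    def test_flagged_only_gene_removed(self):
        entries = [make_phenotype_entry("G", "{Osteoporosis}", 166710, "AD")]
        assert category_pass(entries) == []

    def test_empty_entry_list_removed(self):
        assert category_pass([]) == []


# ---------------------------------------------------------------------------
# Cascade
# ---------------------------------------------------------------------------

def _table(tmp_path, rows):
    path = tmp_path / "ph.tsv"
    make_phenotype_table(rows, path)
    return load_phenotype_table(path)


class TestRunCascade:
    def test_planted_scenario_end_to_end(self, tmp_path):
        """Recovers exactly the planted gene; each decoy is removed at the
        intended stage."""
        study = build_case_study(11, n_sites=2_000)
        table = _table(tmp_path, study.phenotype_rows)
        report = run_cascade("case", study.sites, table, samples=study.samples)
        assert report.final_genes == ["LRP5"]
        removed_at = {c.gene: c.removed_at for c in report.removed}
        assert removed_at["DECOY_AR"] == "inheritance_kept"  # het vs AR-only
        assert removed_at["DECOY_SUSC"] == "category_kept"
        assert removed_at["DECOY_TDD"] == "consensus_moderate"
        assert removed_at["DECOY_NOOMIM"] == "omim_matched"

    def test_stage_counts_monotone_within_branch(self, tmp_path):
        study = build_case_study(12, n_sites=2_000)
        table = _table(tmp_path, study.phenotype_rows)
        c = run_cascade("case", study.sites, table).stage_counts
        assert list(c) == list(STAGES)
        assert c["consensus_high"] <= c["private_high"]
        assert c["consensus_moderate"] <= c["private_moderate"]
        assert (
            c["final_genes"]
            <= c["category_kept"]
            <= c["inheritance_kept"]
            <= c["omim_matched"]
            <= c["consensus_high"] + c["consensus_moderate"]
        )

    def test_empty_stream_all_zero(self):
        report = run_cascade("case", [], {}, samples=["case", "p1"])
        assert all(v == 0 for v in report.stage_counts.values())

    def test_single_qualifying_variant(self, tmp_path):
        site = make_site(
            [((0, 1), 30, (15, 15)), ((0, 0), 30, (30, 0))],
            info={
                "ANN": "G|missense_variant|MODERATE|GENE1|GENE1|transcript|t1|protein_coding|1/1||",
                "dbNSFP_SIFT_pred": "D",
                "dbNSFP_Polyphen2_HDIV_pred": "D",
                "dbNSFP_Polyphen2_HVAR_pred": "D",
            },
        )
        table = _table(tmp_path, [("GENE1", "Dominant disease", 100100, "AD")])
        report = run_cascade("s0", [site], table)
        assert len(report.candidates) == 1
        cand = report.candidates[0]
        assert cand.gene == "GENE1"
        assert [p.clean_name for p in cand.phenotypes] == ["Dominant disease"]

    def test_gerp_stage_optional(self, tmp_path):
        site = make_site(
            [((0, 1), 30, (15, 15)), ((0, 0), 30, (30, 0))],
            info={
                "ANN": "G|missense_variant|MODERATE|GENE1|GENE1|transcript|t1|protein_coding|1/1||",
                "dbNSFP_SIFT_pred": "D",
                "dbNSFP_Polyphen2_HDIV_pred": "D",
                "dbNSFP_Polyphen2_HVAR_pred": "D",
                "dbNSFP_GERP___RS": "3.5",
            },
        )
        table = _table(tmp_path, [("GENE1", "Dominant disease", 100100, "AD")])
        assert run_cascade("s0", [site], table).final_genes == ["GENE1"]
        gated = run_cascade("s0", [site], table, gerp_threshold=4.0)
        assert gated.final_genes == []

    def test_absent_case_id_raises(self, toy_sites):
        with pytest.raises(ValueError):
            run_cascade("absent_sample", toy_sites, {}, samples=["s0", "s1", "s2"])

    def test_report_tsv_round_trip(self, tmp_path):
        study = build_case_study(13, n_sites=2_000)
        table = _table(tmp_path, study.phenotype_rows)
        report = run_cascade("case", study.sites, table)
        p1, p2 = tmp_path / "stages.tsv", tmp_path / "cand.tsv"
        report.to_tsv(p1, p2)
        stages = pd.read_csv(p1, sep="\t")
        assert dict(zip(stages.stage, stages.survivors)) == report.stage_counts
        cands = pd.read_csv(p2, sep="\t")
        assert list(cands.gene) == [c.gene for c in report.candidates]
        # writing the re-read frame again is identical
        cands.to_csv(p2, sep="\t", index=False)
        assert pd.read_csv(p2, sep="\t").equals(cands)

    @pytest.mark.parametrize("seed", range(10))
    def test_planted_recovery_over_seeds(self, seed, tmp_path):
        study = build_case_study(100 + seed, n_sites=2_000)
        table = _table(tmp_path, study.phenotype_rows)
        report = run_cascade("case", study.sites, table)
        assert report.final_genes == ["LRP5"]
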