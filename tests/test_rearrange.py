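import numpy as np
import pytest

from svref.io_formats import GenomicInterval, revcomp
from svref.rearrange import (
    CoordinateMap,
    GermlineSpec,
    PlanError,
    RetroelementInsertion,
    RetrogeneInsertion,
    SvPlanEntry,
    apply_plan,
    inject_germline_artifacts,
    plan_from_table,
    plan_to_table,
)

from conftest import random_genome


@pytest.fixture
def genome(rng):
    return random_genome(rng, {"chr1": 10_000, "chr2": 8_000, "chr3": 6_000})


class TestApplyPlan:
    def test_empty_plan_identity(self, genome):
        derived, records, cmap = apply_plan(genome, [])
        assert derived == genome
        assert records == []

    def test_deletion_concatenates_flanks(self, genome):
        plan = [SvPlanEntry("d", "deletion", "chr1", 2000, size=1000)]
        derived, records, _ = apply_plan(genome, plan)
        assert len(derived["chr1"]) == 9000
        assert derived["chr1"] == genome["chr1"][:2000] + genome["chr1"][3000:]
        (rec,) = records
        assert rec.sv_type == "deletion" and rec.size == 1000

    def test_inversion_is_revcomp(self, genome):
        plan = [SvPlanEntry("i", "inversion", "chr1", 2000, size=500)]
        derived, _, _ = apply_plan(genome, plan)
        assert len(derived["chr1"]) == len(genome["chr1"])
        assert derived["chr1"][2000:2500] == revcomp(genome["chr1"][2000:2500])
        assert derived["chr1"][:2000] == genome["chr1"][:2000]
        assert derived["chr1"][2500:] == genome["chr1"][2500:]

    def test_tandem_duplication(self, genome):
        plan = [SvPlanEntry("t", "tandem_duplication", "chr1", 4000, size=300)]
        derived, _, _ = apply_plan(genome, plan)
        seg = genome["chr1"][4000:4300]
        assert derived["chr1"][4000:4600] == seg + seg
        assert len(derived["chr1"]) == 10_300

    def test_reciprocal_translocation_sequences(self, genome):
        plan = [SvPlanEntry("tr", "translocation", "chr1", 5000, chrom_b="chr2", pos_b=3000)]
        derived, records, _ = apply_plan(genome, plan)
        assert derived["chr1"] == genome["chr1"][:5000] + genome["chr2"][3000:]
        assert derived["chr2"] == genome["chr2"][:3000] + genome["chr1"][5000:]
        assert len(records) == 2
        assert all(r.sv_type == "translocation" for r in records)

    def test_length_conservation(self, genome, rng):
        plan = [
            SvPlanEntry("d1", "deletion", "chr1", 1000, size=700),
            SvPlanEntry("i1", "inversion", "chr1", 3000, size=400),
            SvPlanEntry("t1", "tandem_duplication", "chr2", 2000, size=900),
            SvPlanEntry("tr", "translocation", "chr1", 6000, chrom_b="chr3", pos_b=2000),
        ]
        derived, _, _ = apply_plan(genome, plan)
        assert sum(map(len, derived.values())) == sum(map(len, genome.values())) - 700 + 900

    def test_overlap_rejected(self, genome):
        plan = [
            SvPlanEntry("d1", "deletion", "chr1", 1000, size=1000),
            SvPlanEntry("d2", "deletion", "chr1", 1500, size=1000),
        ]
        with pytest.raises(PlanError, match="overlap"):
            apply_plan(genome, plan)

    def test_out_of_bounds_rejected(self, genome):
        plan = [SvPlanEntry("d", "deletion", "chr1", 9_500, size=1000)]
        with pytest.raises(PlanError, match="d"):
            apply_plan(genome, plan)


class TestCoordinateMap:
    def test_round_trip_deletion_only(self, genome):
        plan = [
            SvPlanEntry("d1", "deletion", "chr1", 2000, size=500),
            SvPlanEntry("d2", "deletion", "chr1", 5000, size=250),
        ]
        derived, _, cmap = apply_plan(genome, plan)
        rng = np.random.default_rng(0)
        for pos in rng.integers(0, len(derived["chr1"]), size=200):
            chrom, ref, strand = cmap.to_ref("chr1", int(pos))
            assert strand == "+"
            back = cmap.ref_to_derived(chrom, ref)
            assert back == ("chr1", int(pos))

    def test_derived_genome_matches_blocks(self, genome):
        plan = [SvPlanEntry("tr", "translocation", "chr1", 4000, chrom_b="chr2", pos_b=2000)]
        derived, _, cmap = apply_plan(genome, plan)
        assert cmap.build_genome(genome) == derived
        # a position past the junction lifts to chr2
        chrom, ref, strand = cmap.to_ref("chr1", 4100)
        assert (chrom, ref) == ("chr2", 2100)

    def test_tsv_round_trip(self, genome, tmp_path):
        plan = [SvPlanEntry("i", "inversion", "chr2", 1000, size=600)]
        _, _, cmap = apply_plan(genome, plan)
        cmap.write_tsv(tmp_path / "m.tsv")
        back = CoordinateMap.read_tsv(tmp_path / "m.tsv")
        assert back.blocks == cmap.blocks

    def test_compose(self, genome):
        spec = GermlineSpec(
            retroelements=(
                RetroelementInsertion("re", GenomicInterval("chr1", 100, 400), "chr2", 1000),
            )
        )
        germ, _, inner = inject_germline_artifacts(genome, spec)
        plan = [SvPlanEntry("d", "deletion", "chr3", 1000, size=500)]
        derived, _, outer = apply_plan(germ, plan)
        full = outer.compose(inner)
        # untouched position on chr1 maps through identically
        assert full.to_ref("chr1", 50) == ("chr1", 50, "+")
        # inserted copy on chr2 maps back to its donor on chr1
        assert full.to_ref("chr2", 1000) == ("chr1", 100, "+")
        # position after the chr3 deletion shifts by 500
        assert full.to_ref("chr3", 1000) == ("chr3", 1500, "+")
        assert full.build_genome(genome) == derived


class TestPlanTable:
    def test_round_trip(self, tmp_path):
        plan = [
            SvPlanEntry("d", "deletion", "chr1", 100, size=50),
            SvPlanEntry("tr", "translocation", "chr1", 500, chrom_b="chr2", pos_b=700),
        ]
        plan_to_table(plan, tmp_path / "p.tsv")
        assert plan_from_table(tmp_path / "p.tsv") == plan

    def test_zero_size_deletion_rejected(self, tmp_path):
        (tmp_path / "p.tsv").write_text(
            "name\tsv_type\tchrom_a\tpos_a\tchrom_b\tpos_b\tsize\n"
            "d\tdeletion\tchr1\t100\t-\t-\t0\n"
        )
        with pytest.raises(PlanError, match="row 2"):
            plan_from_table(tmp_path / "p.tsv")

    def test_dash_size_only_for_translocations(self, tmp_path):
        (tmp_path / "p.tsv").write_text(
            "name\tsv_type\tchrom_a\tpos_a\tchrom_b\tpos_b\tsize\n"
            "d\tdeletion\tchr1\t100\t-\t-\t-\n"
        )
        with pytest.raises(PlanError):
            plan_from_table(tmp_path / "p.tsv")


class TestGermline:
    def test_empty_spec_identity(self, genome):
        derived, records, _ = inject_germline_artifacts(genome, GermlineSpec())
        assert derived == genome and records == []

    def test_interchromosomal_retroelement(self, genome):
        spec = GermlineSpec(
            retroelements=(
                RetroelementInsertion("re", GenomicInterval("chr1", 100, 400), "chr2", 1000),
            )
        )
        derived, records, _ = inject_germline_artifacts(genome, spec)
        (rec,) = records
        assert rec.sv_type == "translocation" and rec.germline
        assert len(derived["chr2"]) == len(genome["chr2"]) + 300
        assert derived["chr2"][1000:1300] == genome["chr1"][100:400]

    def test_intrachromosomal_retroelement_is_deletion_pattern(self, genome):
        spec = GermlineSpec(
            retroelements=(
                RetroelementInsertion("re", GenomicInterval("chr1", 100, 400), "chr1", 5000),
            )
        )
        _, records, _ = inject_germline_artifacts(genome, spec)
        (rec,) = records
        assert rec.sv_type == "deletion" and rec.germline

    def test_retrogene_three_introns(self, genome):
        exons = tuple(
            GenomicInterval("chr1", 1000 + i * 800, 1000 + i * 800 + 300) for i in range(4)
        )
        spec = GermlineSpec(retrogenes=(RetrogeneInsertion("rg", exons, "chr2", 2000),))
        derived, records, _ = inject_germline_artifacts(genome, spec)
        types = sorted(r.sv_type for r in records)
        assert types == ["deletion"] * 3 + ["translocation"]
        assert all(r.germline for r in records)
        cdna = "".join(genome["chr1"][e.start : e.end] for e in exons)
        assert derived["chr2"][2000 : 2000 + len(cdna)] == cdna

    def test_donor_longer_than_target(self, genome):
        spec = GermlineSpec(
            retroelements=(
                RetroelementInsertion("re", GenomicInterval("chr1", 0, 9_000), "chr3", 100),
            )
        )
        with pytest.raises(PlanError, match="longer than target"):
            inject_germline_artifacts(genome, spec)
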