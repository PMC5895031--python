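import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from varstab import catalog, synth
from varstab.errors import (
    AnnotationGapError,
    ConfigurationError,
    InputError,
    ParseError,
)

AA = "ACDEFGHIKLMNPQRSTVWY"


class TestProteinTokens:
    @pytest.mark.parametrize(
        "token,expected",
        [("A147T", ("A", 147, "T")), ("W5R", ("W", 5, "R")), ("G63S", ("G", 63, "S"))],
    )
    def test_parse(self, token, expected):
        pv = catalog.parse_protein_token(token)
        assert (pv.ref_aa, pv.position, pv.alt_aa) == expected

    @pytest.mark.parametrize("token", ["A0T", "X5R", "A1A", "147T", "A-3T", ""])
    def test_malformed_tokens_raise_and_name_the_token(self, token):
        with pytest.raises(ParseError):
            catalog.parse_protein_token(token)

    @given(
        ref=st.sampled_from(AA),
        alt=st.sampled_from(AA),
        pos=st.integers(min_value=1, max_value=9999),
    )
    def test_parse_is_inverse_of_formatting(self, ref, alt, pos):
        if ref == alt:
            return
        pv = catalog.parse_protein_token(f"{ref}{pos}{alt}")
        assert pv.token == f"{ref}{pos}{alt}"

    def test_table1_maps_to_43_residues_with_9_double_hits(self, table1):
        pvs = [
            catalog.parse_protein_token(m, i)
            for i, m in zip(table1["id"], table1["mutation"])
        ]
        assert len(pvs) == 52
        assert len({p.position for p in pvs}) == 43
        multi = catalog.multiallelic_residues(pvs)
        assert sorted(multi) == [63, 120, 135, 139, 147, 156, 165, 166, 169]
        assert all(len({p.alt_aa for p in v}) >= 2 for v in multi.values())

    def test_all_distinct_positions_give_empty_map(self):
        pvs = [catalog.ProteinVariant("A", i, "T") for i in range(1, 10)]
        assert catalog.multiallelic_residues(pvs) == {}


class TestLoadVariantTable:
    def _write(self, tmp_path, text):
        p = tmp_path / "v.tsv"
        p.write_text(text)
        return p

    def test_well_formed_rows_parse_without_rejects(self, tmp_path):
        p = self._write(
            tmp_path,
            "id\tregion_class\tprotein_change\tmaf\n"
            "rs1\tintronic\t\t0.001\n"
            "rs6971\tcoding_nonsynonymous\tA147T\t0.30\n"
            "rs3\tutr\t\t\n",
        )
        res = catalog.load_variant_table(p)
        assert len(res.records) == 3 and not res.rejects
        assert res.records[1].protein_change == "A147T"
        assert res.records[2].maf is None

    def test_row_without_position_or_class_is_rejected_with_reason(self, tmp_path):
        p = self._write(
            tmp_path,
            "id\tposition\tregion_class\nrs1\t100\t\nrs2\t\t\n",
        )
        res = catalog.load_variant_table(p)
        assert len(res.records) == 1
        assert len(res.rejects) == 1
        assert "rs2" in str(res.rejects[0]["row"]) and res.rejects[0]["reason"]

    def test_missing_required_columns_is_a_configuration_error(self, tmp_path):
        p = self._write(tmp_path, "id\tmaf\nrs1\t0.1\n")
        with pytest.raises(ConfigurationError):
            catalog.load_variant_table(p)

    def test_empty_file_is_an_input_error(self, tmp_path):
        p = self._write(tmp_path, "")
        with pytest.raises(InputError):
            catalog.load_variant_table(p)

    def test_dialect_maps_foreign_column_names(self, tmp_path):
        p = self._write(tmp_path, "rsid\tclass\nrs1\tintronic\n")
        res = catalog.load_variant_table(
            p, dialect={"id": "rsid", "region_class": "class"}
        )
        assert res.records[0].id == "rs1"
        assert res.records[0].region_class == "intronic"


class TestClassifyRegion:
    def test_planted_classes_are_recovered(self):
        sim = synth.gen_variant_catalog(n=200, seed=3)
        truth = {t["id"]: t["region_class"] for t in sim.manifest["truth"]}
        rows = list(sim.table.to_dict("records"))
        for row in rows + rows[::-1]:  # order independence / idempotence
            rec = catalog.VariantRecord(
                id=row["id"],
                position=int(row["position"]),
                ref_base=row["ref_base"] if isinstance(row["ref_base"], str) else None,
                alt_base=row["alt_base"] if isinstance(row["alt_base"], str) else None,
            )
            assert catalog.classify_region(rec, sim.annotation, sim.cds) == truth[row["id"]]

    def test_intron_and_synonymous_examples(self):
        annotation, cds = synth.synthetic_gene(protein_length=169, seed=0)
        intron_pos = annotation.intron_intervals[0][0] + 5
        rec = catalog.VariantRecord(id="i1", position=intron_pos)
        assert catalog.classify_region(rec, annotation, cds) == "intronic"
        # third base of a CTx leucine codon is always synonymous (CTT<->CTG)
        idx = next(
            i for i in range(3, len(cds) - 3, 3) if cds[i : i + 2] == "CT"
        )
        genomic = synth._genomic_position(annotation, idx + 2)
        ref = cds[idx + 2]
        alt = "G" if ref != "G" else "A"  # CTN is leucine for any N
        rec = catalog.VariantRecord(id="s1", position=genomic, ref_base=ref, alt_base=alt)
        assert catalog.classify_region(rec, annotation, cds) == "coding_synonymous"

    def test_position_outside_gene_is_an_annotation_gap(self):
        annotation, cds = synth.synthetic_gene(protein_length=169, seed=0)
        rec = catalog.VariantRecord(id="x", position=10**7)
        with pytest.raises(AnnotationGapError):
            catalog.classify_region(rec, annotation, cds)


class TestDistributionSummary:
    def test_published_catalog_composition(self):
        counts = {
            "intronic": 674,
            "utr": 52,
            "coding_nonsynonymous": 52,
            "coding_synonymous": 40,
        }
        variants = [
            catalog.VariantRecord(id=f"{cls}{i}", region_class=cls)
            for cls, n in counts.items()
            for i in range(n)
        ]
        summary = catalog.summarize_distribution(variants)
        assert summary.total == 818
        assert summary.percentages["intronic"] == 82.4
        assert summary.percentages["coding_nonsynonymous"] == 6.4
        assert summary.percentages["utr"] == 6.4
        assert abs(sum(summary.percentages.values()) - 100.0) <= 0.2

    def test_single_class_is_100_percent(self):
        summary = catalog.summarize_distribution(
            [catalog.VariantRecord(id="a", region_class="utr")]
        )
        assert summary.percentages["utr"] == 100.0

    def test_sampled_fractions_are_recovered_within_binomial_error(self):
        fractions = {
            "intronic": 0.8,
            "utr": 0.1,
            "coding_nonsynonymous": 0.06,
            "coding_synonymous": 0.04,
        }
        sim = synth.gen_variant_catalog(n=1000, fractions=fractions, seed=11)
        recs = [
            catalog.VariantRecord(id=t["id"], region_class=t["region_class"])
            for t in sim.manifest["truth"]
        ]
        summary = catalog.summarize_distribution(recs)
        for cls, f in fractions.items():
            se = np.sqrt(f * (1 - f) / 1000)
            assert abs(summary.counts[cls] / 1000 - f) < 4 * se

    def test_empty_input_raises(self):
        with pytest.raises(InputError):
            catalog.summarize_distribution([])


class TestMafFilter:
    def test_common_variant_is_retained_at_published_threshold(self):
        rec = catalog.VariantRecord(id="rs6971", region_class="coding_nonsynonymous",
                                    protein_change="A147T", maf=0.30)
        part = catalog.filter_by_maf([rec], 0.003)
        assert part.retained == [rec]

    def test_all_zero_maf_is_rare(self):
        recs = [
            catalog.VariantRecord(id=str(i), region_class="intronic", maf=0.0)
            for i in range(5)
        ]
        part = catalog.filter_by_maf(recs, 0.003)
        assert len(part.rare) == 5 and not part.retained and not part.unknown

    @given(
        mafs=st.lists(
            st.one_of(st.none(), st.floats(min_value=0, max_value=1)), max_size=40
        ),
        threshold=st.floats(min_value=0, max_value=1),
    )
    def test_partition_matches_brute_force_and_covers_input(self, mafs, threshold):
        recs = [
            catalog.VariantRecord(id=str(i), region_class="intronic", maf=m)
            for i, m in enumerate(mafs)
        ]
        part = catalog.filter_by_maf(recs, threshold)
        assert len(part.retained) + len(part.rare) + len(part.unknown) == len(recs)
        assert part.retained == [r for r in recs if r.maf is not None and r.maf >= threshold]
        assert part.rare == [r for r in recs if r.maf is not None and r.maf < threshold]
        assert part.unknown == [r for r in recs if r.maf is None]
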