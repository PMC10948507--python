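"""Trait derivation: growth rates, tolerance/injury indices, table assembly and IO."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

import salicore as sc
from salicore.exceptions import (
    DivisionDomainError,
    ExclusionWarning,
    InvalidMassError,
    MissingTimepointError,
    SchemaError,
)
from salicore.traits import load_raw_phenotypes, write_raw_phenotypes


def _record(gid="g1", treatment="control", rep=1, gr=0.4, nil=2.0, ler=1.0,
            h2=10.0, leaves1=4.0, l2=5.0, **kw):
    """Record whose derived GR/NIL/LER equal the given rates exactly."""
    defaults = dict(
        shoot_fresh_g=4.0, shoot_dry_g=3.4, root_fresh_g=2.0, root_dry_g=1.78,
        senescence_score=6.0, shoot_na_mg_g=120.0, root_na_mg_g=45.0,
        shoot_k_mg_g=68.0, root_k_mg_g=26.0,
    )
    defaults.update(kw)
    return sc.RawPhenotypeRecord(
        genotype_id=gid, treatment=treatment, replicate=rep,
        height_cm_at_das={2: h2, 7: h2 + 5 * gr, 17: h2 + 15 * gr},
        leaf_count_at_das={1: leaves1, 17: leaves1 + nil},
        marked_leaf_length_cm_at_das={2: l2, 7: l2 + 5 * ler, 12: l2 + 10 * ler},
        **defaults,
    )


class TestDeriveGrowthRates:
    def test_gr_is_mean_of_the_two_interval_rates(self):
        rec = sc.RawPhenotypeRecord("g", "control", 1,
                                    height_cm_at_das={2: 10, 7: 12, 17: 20})
        gr = sc.derive_growth_rates(rec, which=("GR",))["GR"]
        assert gr == pytest.approx((0.4 + 10 / 15) / 2, abs=1e-12)

    def test_constant_heights_give_zero_growth(self):
        rec = sc.RawPhenotypeRecord("g", "control", 1,
                                    height_cm_at_das={2: 15, 7: 15, 17: 15})
        assert sc.derive_growth_rates(rec, which=("GR",))["GR"] == 0.0

    def test_ler_hand_value(self):
        rec = sc.RawPhenotypeRecord("g", "control", 1,
                                    marked_leaf_length_cm_at_das={2: 5, 7: 10, 12: 15})
        assert sc.derive_growth_rates(rec, which=("LER",))["LER"] == pytest.approx(1.0)

    def test_nil_is_leaf_count_difference(self):
        rec = sc.RawPhenotypeRecord("g", "control", 1,
                                    leaf_count_at_das={1: 4, 17: 7})
        assert sc.derive_growth_rates(rec, which=("NIL",))["NIL"] == 3

    def test_missing_timepoint_names_the_blocked_trait(self):
        rec = sc.RawPhenotypeRecord("g", "control", 1, height_cm_at_das={2: 10, 7: 12})
        with pytest.raises(MissingTimepointError, match="GR"):
            sc.derive_growth_rates(rec, which=("GR",))


class TestStiSii:
    @pytest.mark.parametrize("stress,control,sti", [
        (0.4, 0.4, 1.0), (0.0, 0.4, 0.0), (0.2, 0.4, 0.5),
    ])
    def test_examples(self, stress, control, sti):
        out = sc.compute_sti_sii(stress, control)
        assert out["STI"] == pytest.approx(sti)
        assert out["SII"] == pytest.approx(1 - sti)

    def test_zero_control_rejected(self):
        with pytest.raises(DivisionDomainError):
            sc.compute_sti_sii(0.2, 0.0)

    @given(stress=st.floats(0, 10, allow_nan=False),
           control=st.floats(0.01, 10, allow_nan=False))
    def test_sti_plus_sii_is_one(self, stress, control):
        out = sc.compute_sti_sii(stress, control)
        assert out["STI"] + out["SII"] == 1.0


class TestWaterContent:
    @pytest.mark.parametrize("fresh,dry,wc", [(10, 10, 0.0), (10, 0, 100.0), (8, 2, 75.0)])
    def test_fresh_basis(self, fresh, dry, wc):
        assert sc.compute_water_content(fresh, dry) == pytest.approx(wc)

    def test_dry_basis_alternative(self):
        assert sc.compute_water_content(8, 2, formula="dry_basis") == pytest.approx(300.0)

    def test_dry_above_fresh_rejected(self):
        with pytest.raises(InvalidMassError):
            sc.compute_water_content(2, 8)


class TestAssembleTraitTable:
    def test_matches_cellwise_hand_computation(self):
        records = []
        for gid, gr_s in (("a", 0.2), ("b", 0.3)):
            for rep in (1, 2, 3):
                records.append(_record(gid, "control", rep, gr=0.4, nil=2.0, ler=1.0))
                records.append(_record(gid, "stress", rep, gr=gr_s, nil=1.0, ler=0.5))
        result = sc.assemble_trait_table(records)
        t = result.table.data
        assert list(t.index) == ["a", "b"]
        assert t.loc["a", "RGR"] == pytest.approx(0.2 / 0.4)
        assert t.loc["b", "RGR"] == pytest.approx(0.3 / 0.4)
        assert t.loc["a", "RNIL"] == pytest.approx(0.5)
        assert t.loc["a", "RLER"] == pytest.approx(0.5)
        assert t.loc["a", "SWC"] == pytest.approx((4.0 - 3.4) / 4.0 * 100)
        assert t.loc["a", "SN/RN"] == pytest.approx(120.0 / 45.0)
        assert t.loc["a", "SK/N"] == pytest.approx(68.0 / 120.0)
        assert result.table.check_ion_ratio_consistency()
        assert not result.exclusions

    def test_stress_equal_control_gives_unit_indices(self):
        records = [_record("g", trt, rep) for trt in ("control", "stress")
                   for rep in (1, 2)]
        table = sc.assemble_trait_table(records).table.data
        for trait in ("RGR", "RNIL", "RLER"):
            assert table.loc["g", trait] == pytest.approx(1.0)

    def test_genotype_without_stress_arm_is_excluded(self):
        records = [_record("only_ck", "control", 1),
                   _record("ok", "control", 1), _record("ok", "stress", 1)]
        with pytest.warns(ExclusionWarning):
            result = sc.assemble_trait_table(records)
        assert [e.genotype_id for e in result.exclusions] == ["only_ck"]
        assert list(result.table.data.index) == ["ok"]

    def test_permutation_equivariant_in_genotype_order(self):
        records = []
        for gid, gr_s in (("a", 0.2), ("b", 0.3), ("c", 0.25)):
            records += [_record(gid, "control", 1), _record(gid, "stress", 1, gr=gr_s)]
        fwd = sc.assemble_trait_table(records).table.data
        rev = sc.assemble_trait_table(records[::-1]).table.data
        pd.testing.assert_frame_equal(fwd.sort_index(), rev.sort_index())
        assert list(rev.index) == list(fwd.index)[::-1]


class TestTraitTableIO:
    def test_roundtrip_preserves_values(self, tmp_path, panel300):
        path = tmp_path / "t.csv"
        small = panel300.subset(panel300.genotype_ids[:5])
        sc.write_trait_table(small, path)
        back = sc.load_trait_table(path)
        np.testing.assert_allclose(back.values, small.values, rtol=1e-12)

    def test_missing_trait_column_names_it(self, tmp_path, panel300):
        path = tmp_path / "t.csv"
        sc.write_trait_table(panel300.subset(panel300.genotype_ids[:3]), path)
        df = pd.read_csv(path).drop(columns=["Sen"])
        df.to_csv(path, index=False)
        with pytest.raises(SchemaError, match="Sen"):
            sc.load_trait_table(path)

    def test_extra_columns_preserved_but_ignored(self, tmp_path, panel300):
        path = tmp_path / "t.csv"
        small = panel300.subset(panel300.genotype_ids[:4])
        sc.write_trait_table(small, path)
        df = pd.read_csv(path)
        df["notes"] = "x"
        df.to_csv(path, index=False)
        back = sc.load_trait_table(path)
        assert list(back.trait_names) == list(sc.TRAIT_NAMES)
        assert "notes" in back.extra.columns

    def test_raw_phenotype_roundtrip(self, tmp_path):
        records = [_record("g", "control", 1), _record("g", "stress", 1, gr=0.2)]
        path = tmp_path / "raw.csv"
        write_raw_phenotypes(records, path)
        back = load_raw_phenotypes(path)
        t1 = sc.assemble_trait_table(records).table.data
        t2 = sc.assemble_trait_table(back).table.data
        pd.testing.assert_frame_equal(t1, t2)
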