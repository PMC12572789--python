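"""MLI scoring, portion resolution and %TFI exposure profiles."""

from datetime import date

import numpy as np
import pandas as pd
import pytest

from mupsurv.exposure import (
    MliTable,
    ProductRecord,
    RecallRecord,
    build_mli_table,
    build_profile,
    compute_mli,
    cumulative_intake,
    item_marker_grams,
    recall_exposure,
    resolve_portion,
)
from mupsurv.lexicon import IngredientText


def _products(item_id, texts, portion_g=50.0, energy=1000.0):
    return [
        ProductRecord(item_id=item_id, ingredients=IngredientText(t),
                      portion_g=portion_g, energy_kj_100g=energy)
        for t in texts
    ]


class TestComputeMli:
    def test_six_of_ten_products_with_flavour_gives_0_6(self, lexicon):
        texts = ["sugar, flavouring"] * 6 + ["sugar, cocoa"] * 4
        mli = compute_mli(_products("chocbar", texts), lexicon)
        assert mli.mli["flavour"] == pytest.approx(0.6)
        assert mli.mli["UPF"] == pytest.approx(0.6)
        assert mli.n_products == 10

    def test_single_markerless_product_all_zero(self, lexicon):
        mli = compute_mli(_products("i1", ["water, salt"]), lexicon)
        assert all(v == 0.0 for v in mli.mli.values())

    def test_zero_products_error(self, lexicon):
        with pytest.raises(ValueError, match="no products"):
            compute_mli([], lexicon)

    def test_matches_brute_force_recount_and_truncation(self, lexicon):
        """Random product sets: MLI equals per-key counting; truncation to
        the first k products equals recounting on the truncated list."""
        from mupsurv.lexicon import scan_ingredients

        rng = np.random.default_rng(7)
        terms = ["flavouring", "pectin", "aspartame", "lactose", "e471", "colour"]
        for trial in range(20):
            texts = [
                ", ".join(rng.choice(terms + ["water", "salt"] * 3,
                                     size=rng.integers(1, 5), replace=False))
                for _ in range(10)
            ]
            prods = _products(f"t{trial}", texts)
            for k in (10, 8, 6, 4):
                mli = compute_mli(prods, lexicon, max_products=k)
                present = [scan_ingredients(t, lexicon) for t in texts[:k]]
                for marker in lexicon.marker_names:
                    expected = sum(marker in s for s in present) / k
                    assert mli.mli[marker] == pytest.approx(expected)
                assert mli.mli["UPF"] == pytest.approx(
                    sum(bool(s) for s in present) / k
                )

    def test_upf_category_marker_hierarchy(self, lexicon):
        rng = np.random.default_rng(13)
        terms = ["flavouring", "pectin", "sucralose", "maltodextrin", "gluten"]
        for trial in range(10):
            texts = [", ".join(rng.choice(terms, size=rng.integers(0, 4), replace=False))
                     for _ in range(10)]
            mli = compute_mli(_products(f"h{trial}", texts), lexicon)
            for cat in lexicon.categories:
                assert mli.mli["UPF"] >= mli.mli[cat] - 1e-12
                members = lexicon.markers_in(cat)
                for m in members:
                    assert mli.mli[cat] >= mli.mli[m.name] - 1e-12
                assert mli.mli[cat] <= sum(mli.mli[m.name] for m in members) + 1e-12


class TestResolvePortion:
    def test_grams_identity(self):
        assert resolve_portion(100, "g") == 100.0

    def test_ml_uses_specific_gravity(self):
        assert resolve_portion(100, "mL", item_id="milk",
                               gravity_table={"milk": 1.03}) == pytest.approx(103.0)

    def test_ml_default_gravity_is_water(self):
        assert resolve_portion(250, "ml") == 250.0

    def test_ml_no_gravity_no_default_errors(self):
        with pytest.raises(KeyError):
            resolve_portion(100, "mL", item_id="oil", gravity_table={})

    def test_household_measure_uses_fallback(self):
        assert resolve_portion(1, "Mug/Cup", fallback_g=250.0) == 250.0

    def test_household_measure_without_fallback_errors(self):
        with pytest.raises(KeyError):
            resolve_portion(1, "Mug/Cup")


class TestItemMarkerGrams:
    @pytest.mark.parametrize("portion,mli,expected", [(50, 0.6, 30.0), (50, 0, 0.0), (50, 1, 50.0)])
    def test_portion_times_mli(self, portion, mli, expected):
        assert item_marker_grams(portion, mli) == pytest.approx(expected)

    def test_rejects_invalid_inputs(self):
        with pytest.raises(ValueError):
            item_marker_grams(-1, 0.5)
        with pytest.raises(ValueError):
            item_marker_grams(50, 1.5)


def _mini_table(lexicon):
    texts_a = ["flavouring"] * 6 + ["water"] * 4  # flavour MLI 0.6
    texts_b = ["water"] * 10
    items = {
        "choc": compute_mli(_products("choc", texts_a, portion_g=50, energy=2000), lexicon),
        "rice": compute_mli(_products("rice", texts_b, portion_g=100, energy=500), lexicon),
    }
    return MliTable(items=items, categories=tuple(lexicon.categories),
                    specific_markers=tuple(lexicon.marker_names))


class TestRecallExposure:
    def test_chocolate_bar_worked_example(self, lexicon):
        table = _mini_table(lexicon)
        rec = RecallRecord("p1", 1, date(2010, 1, 1), (("choc", 1.0),))
        out = recall_exposure(rec, table)
        assert out.total_food_g == pytest.approx(50.0)
        assert out.marker_g["flavour"] == pytest.approx(30.0)
        assert out.total_energy_kj == pytest.approx(50 * 2000 / 100)

    def test_empty_recall_zero(self, lexicon):
        table = _mini_table(lexicon)
        out = recall_exposure(RecallRecord("p1", 1, None, ()), table)
        assert out.total_food_g == 0.0
        assert all(v == 0.0 for v in out.marker_g.values())

    def test_unknown_item_errors_with_id(self, lexicon):
        table = _mini_table(lexicon)
        with pytest.raises(KeyError, match="nope"):
            recall_exposure(RecallRecord("p1", 1, None, (("nope", 1.0),)), table)

    def test_matches_loop_oracle(self, lexicon):
        table = _mini_table(lexicon)
        rng = np.random.default_rng(3)
        for _ in range(10):
            consumed = tuple(
                (i, float(rng.integers(1, 4)))
                for i in rng.choice(["choc", "rice"], size=rng.integers(1, 4))
            )
            out = recall_exposure(RecallRecord("p", 1, None, consumed), table)
            total = sum(n * table.items[i].mean_portion_g for i, n in consumed)
            flav = sum(n * table.items[i].mean_portion_g * table.items[i].mli["flavour"]
                       for i, n in consumed)
            assert out.total_food_g == pytest.approx(total)
            assert out.marker_g["flavour"] == pytest.approx(flav)


class TestBuildProfile:
    def test_50_percent_tfi_worked_example(self, lexicon):
        """1000 g flavoured food of 2000 g total -> 50 %TFI."""
        texts = ["flavouring"] * 10
        items = {
            "flav": compute_mli(_products("flav", texts, portion_g=100), lexicon),
            "plain": compute_mli(_products("plain", ["water"] * 10, portion_g=100), lexicon),
        }
        table = MliTable(items, tuple(lexicon.categories), tuple(lexicon.marker_names))
        rec = RecallRecord("p1", 1, None, (("flav", 10.0), ("plain", 10.0)))
        prof = build_profile([rec], table)
        assert prof.total_food_g == pytest.approx(2000.0)
        assert prof.tfi_percent["flavour"] == pytest.approx(50.0)
        assert prof.tfi_percent["UPF"] == pytest.approx(50.0)

    def test_no_markers_all_zero(self, lexicon):
        table = _mini_table(lexicon)
        prof = build_profile([RecallRecord("p", 1, None, (("rice", 2.0),))], table)
        assert all(v == 0.0 for v in prof.tfi_percent.values())

    def test_three_recalls_ratio_of_means(self, lexicon):
        """Gram intakes averaged across recalls first, then the ratio."""
        table = _mini_table(lexicon)
        recs = [
            RecallRecord("p", 1, None, (("choc", 2.0),)),           # 100 g, 60 flav
            RecallRecord("p", 2, None, (("rice", 1.0),)),           # 100 g, 0
            RecallRecord("p", 3, None, (("choc", 1.0), ("rice", 1.0))),  # 150 g, 30
        ]
        prof = build_profile(recs, table)
        mean_total = (100 + 100 + 150) / 3
        mean_flav = (60 + 0 + 30) / 3
        assert prof.tfi_percent["flavour"] == pytest.approx(100 * mean_flav / mean_total)

    def test_first_recall_mode(self, lexicon):
        table = _mini_table(lexicon)
        recs = [
            RecallRecord("p", 2, None, (("rice", 1.0),)),
            RecallRecord("p", 1, None, (("choc", 1.0),)),
        ]
        prof = build_profile(recs, table, mode="first_recall")
        assert prof.tfi_percent["flavour"] == pytest.approx(60.0)
        assert prof.n_recalls == 1

    def test_scale_invariance(self, lexicon):
        table = _mini_table(lexicon)
        r1 = [RecallRecord("p", 1, None, (("choc", 1.0), ("rice", 2.0)))]
        r2 = [RecallRecord("p", 1, None, (("choc", 2.0), ("rice", 4.0)))]
        p1, p2 = build_profile(r1, table), build_profile(r2, table)
        for k in p1.tfi_percent:
            assert p1.tfi_percent[k] == pytest.approx(p2.tfi_percent[k])
            assert 0.0 <= p1.tfi_percent[k] <= 100.0

    def test_zero_total_intake_errors(self, lexicon):
        table = _mini_table(lexicon)
        with pytest.raises(ValueError, match="zero total"):
            build_profile([RecallRecord("p", 1, None, ())], table)


class TestCumulativeIntake:
    def test_worked_example_3_2_5_gives_10(self, lexicon):
        table = _mini_table(lexicon)
        prof = build_profile([RecallRecord("p", 1, None, (("rice", 1.0),))], table)
        tfi = dict.fromkeys(prof.tfi_percent, 0.0)
        tfi["flavour"] = 3.0
        tfi["acesulfame"] = 2.0
        tfi["emulsifier"] = 5.0
        # category aggregates must not enter the sum
        tfi["sweetener"] = 2.0
        tfi["processing aid"] = 5.0
        tfi["UPF"] = 10.0
        prof2 = type(prof)(
            participant_id="p", tfi_percent=tfi,
            specific_markers=prof.specific_markers,
            total_food_g=100.0, total_energy_kj=0.0, n_recalls=1,
        )
        assert cumulative_intake(prof2) == pytest.approx(10.0)

    def test_matches_summation_oracle(self, small_profiles, lexicon):
        keys = [m for m in lexicon.marker_names]
        # flavour/fibre markers share their category's column; summed once
        expected = small_profiles[list(dict.fromkeys(keys))].sum(axis=1)
        assert np.allclose(small_profiles["cumulative_specific_mup"], expected)


class TestBuildMliTable:
    def test_missing_columns_rejected(self, lexicon):
        with pytest.raises(ValueError, match="missing columns"):
            build_mli_table(pd.DataFrame({"item_id": []}), lexicon)

    def test_fewer_than_ten_products_uses_all(self, lexicon):
        df = pd.DataFrame(
            {
                "item_id": ["a"] * 3,
                "product_id": ["p0", "p1", "p2"],
                "ingredients_text": ["flavouring", "water", "water"],
                "portion_value": [30.0, 40.0, 50.0],
                "portion_unit": ["g"] * 3,
                "energy_kj_per_100g": [100.0] * 3,
            }
        )
        table = build_mli_table(df, lexicon)
        assert table.items["a"].n_products == 3
        assert table.items["a"].mli["flavour"] == pytest.approx(1 / 3)
        assert table.items["a"].mean_portion_g == pytest.approx(40.0)
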