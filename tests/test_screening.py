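import math

import numpy as np
import pytest

from loopcraft.errors import LoopcraftError, ValidationError
from loopcraft.screening import (
    ScreeningTable,
    Well,
    call_hits,
    diastereomeric_excess,
    enantiomeric_excess,
    quantify,
    summarize_library,
)


def _table(wells, substrate=10.0, products=("p1", "p2"), rf=None):
    return ScreeningTable(
        wells=wells,
        internal_standard="biphenyl",
        is_concentration=1.0,
        substrate_initial=substrate,
        product_analytes=products,
        calibration=rf or {a: 1.0 for a in products},
    )


def _well(wid, role, areas, name=None):
    return Well(well_id=wid, role=role, variant_name=name, areas=areas)


class TestQuantify:
    def test_single_product_formation_and_distribution(self):
        # area ratio 5 with rf 1 and 1 mM IS -> 5 mM; 5/10 mM = 50%
        t = _table([_well("A1", "variant", {"biphenyl": 100.0, "p1": 500.0}, "v")],
                   products=("p1",))
        (r,) = quantify(t)
        assert r.formation == pytest.approx(50.0)
        assert r.distribution == {"p1": pytest.approx(100.0)}

    def test_equal_products_split_evenly(self):
        t = _table([_well("A1", "variant", {"biphenyl": 100.0, "p1": 300.0, "p2": 300.0})])
        (r,) = quantify(t)
        assert r.distribution["p1"] == pytest.approx(50.0)
        assert sum(r.distribution.values()) == pytest.approx(100.0)

    def test_response_factor_applied(self):
        t = _table(
            [_well("A1", "variant", {"biphenyl": 100.0, "p1": 300.0, "p2": 300.0})],
            rf={"p1": 1.0, "p2": 2.0},
        )
        (r,) = quantify(t)
        assert r.concentrations["p2"] == pytest.approx(r.concentrations["p1"] / 2)

    def test_invariant_under_uniform_area_rescaling(self):
        areas = {"biphenyl": 120.0, "p1": 340.0, "p2": 55.0}
        t1 = _table([_well("A1", "variant", areas)])
        t2 = _table([_well("A1", "variant", {k: 7.3 * v for k, v in areas.items()})])
        r1, r2 = quantify(t1)[0], quantify(t2)[0]
        assert r1.formation == pytest.approx(r2.formation)
        assert r1.concentrations["p1"] == pytest.approx(r2.concentrations["p1"])

    def test_no_product_gives_zero_formation_empty_distribution(self):
        t = _table([_well("A1", "empty_vector", {"biphenyl": 100.0, "p1": 0.0, "p2": 0.0})])
        (r,) = quantify(t)
        assert r.formation == 0.0
        assert r.distribution == {}

    def test_formation_clipped_at_100_with_warning(self):
        t = _table([_well("A1", "variant", {"biphenyl": 10.0, "p1": 2000.0})], products=("p1",))
        with pytest.warns(UserWarning, match="clipping"):
            (r,) = quantify(t)
        assert r.formation == 100.0

    def test_reported_split_representable(self, tmp_path):
        # a high-selectivity well: 89.2% formation split ~98.2/0.8/1.1 (the
        # printed shares sum to 100.1 from rounding) must survive
        # quantification and the report writer
        shares = {"pa": 98.2, "pb": 0.8, "pc": 1.1}
        total_mm = 8.92
        concs = {k: total_mm * v / sum(shares.values()) for k, v in shares.items()}
        areas = {"biphenyl": 1000.0}
        areas.update({k: 1000.0 * v for k, v in concs.items()})
        t = _table([_well("A1", "variant", areas, "A283del")],
                   substrate=10.0, products=("pa", "pb", "pc"),
                   rf={"pa": 1.0, "pb": 1.0, "pc": 1.0})
        (r,) = quantify(t)
        assert r.formation == pytest.approx(89.2, abs=1e-9)
        assert sum(r.distribution.values()) == pytest.approx(100.0, abs=1e-9)
        for k in shares:
            assert r.distribution[k] == pytest.approx(shares[k], abs=0.1)
        from loopcraft.screening import write_results_csv
        import pandas as pd

        write_results_csv(tmp_path / "res.csv", [r])
        back = pd.read_csv(tmp_path / "res.csv")
        assert back["formation_pct"][0] == pytest.approx(89.2)
        assert back["share_pa_pct"][0] == pytest.approx(r.distribution["pa"])

    def test_missing_internal_standard_rejected(self):
        with pytest.raises(ValidationError, match="A1"):
            _table([_well("A1", "variant", {"p1": 5.0})])


class TestStereoExcess:
    def test_racemic(self):
        assert enantiomeric_excess(50.0, 50.0) == (0.0, "racemic")

    def test_formula_and_major_label(self):
        ee, major = enantiomeric_excess(86.35, 13.65, "R", "S")
        assert ee == pytest.approx(72.7, abs=1e-9)
        assert major == "R"

    def test_boundary(self):
        assert enantiomeric_excess(100.0, 0.0) == (100.0, "R")

    def test_de_values(self):
        de, major = diastereomeric_excess(97.35, 2.65, "(1R,5S)", "(1R,5R)")
        assert de == pytest.approx(94.7, abs=1e-9)
        assert major == "(1R,5S)"
        de2, _ = diastereomeric_excess(69.05, 30.95, "(1R,5S)", "(1R,5R)")
        assert de2 == pytest.approx(38.1, abs=1e-9)

    def test_symmetry_and_bounds(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            a, b = rng.uniform(0, 100, size=2)
            e1, m1 = enantiomeric_excess(a, b, "R", "S")
            e2, m2 = enantiomeric_excess(b, a, "R", "S")
            assert e1 == pytest.approx(e2)
            assert 0 <= e1 <= 100
            if a != b:
                assert {m1, m2} == {"R", "S"}

    def test_both_zero_undefined(self):
        with pytest.raises(LoopcraftError):
            enantiomeric_excess(0.0, 0.0)


class TestCallHits:
    def _results(self):
        wells = [
            _well("A1", "wildtype", {"biphenyl": 100.0, "p1": 64.0}),
            _well("A2", "wildtype", {"biphenyl": 100.0, "p1": 64.0}),
            _well("A3", "empty_vector", {"biphenyl": 100.0, "p1": 0.0}),
            _well("B1", "variant", {"biphenyl": 100.0, "p1": 982.0}, "A283del"),
            _well("B2", "variant", {"biphenyl": 100.0, "p1": 64.0}, "neutral"),
        ]
        return quantify(_table(wells, substrate=10.0, products=("p1",)))

    def test_fold_change_vs_wildtype(self):
        ranked = call_hits(self._results(), fold_thr=2.0)
        top = ranked.iloc[0]
        assert top["variant"] == "A283del"
        assert top["fold_change"] == pytest.approx(98.2 / 6.4, rel=1e-9)
        assert bool(top["hit"])
        neutral = ranked[ranked["variant"] == "neutral"].iloc[0]
        assert neutral["fold_change"] == pytest.approx(1.0)
        assert not bool(neutral["hit"])

    def test_blank_subtraction_floors_at_zero(self):
        wells = [
            _well("A1", "wildtype", {"biphenyl": 100.0, "p1": 100.0}),
            _well("A2", "empty_vector", {"biphenyl": 100.0, "p1": 50.0}),
            _well("B1", "variant", {"biphenyl": 100.0, "p1": 50.0}, "ghost"),
        ]
        ranked = call_hits(quantify(_table(wells, products=("p1",))))
        assert ranked.iloc[0]["metric"] == pytest.approx(0.0)

    def test_zero_wildtype_mean_ranks_infinite_first(self):
        wells = [
            _well("A1", "wildtype", {"biphenyl": 100.0, "p1": 0.0}),
            _well("B1", "variant", {"biphenyl": 100.0, "p1": 10.0}, "x"),
            _well("B2", "variant", {"biphenyl": 100.0, "p1": 0.0}, "y"),
        ]
        ranked = call_hits(quantify(_table(wells, products=("p1",))))
        assert math.isinf(ranked.iloc[0]["fold_change"])
        assert ranked.iloc[0]["variant"] == "x"

    def test_no_wildtype_raises(self):
        wells = [_well("B1", "variant", {"biphenyl": 100.0, "p1": 10.0}, "x")]
        with pytest.raises(ValidationError):
            call_hits(quantify(_table(wells, products=("p1",))))


class TestSummary:
    def test_replicate_aggregation(self):
        wells = [
            _well("A1", "wildtype", {"biphenyl": 100.0, "p1": 50.0}),
            _well("B1", "variant", {"biphenyl": 100.0, "p1": 100.0}, "v1"),
            _well("B2", "variant", {"biphenyl": 100.0, "p1": 300.0}, "v1"),
        ]
        df = summarize_library(quantify(_table(wells, products=("p1",))))
        row = df[df["variant"] == "v1"].iloc[0]
        assert row["n"] == 2
        assert row["formation_mean"] == pytest.approx(20.0)
        assert row["formation_sd"] > 0
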