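import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sizehab.engine import ComparisonResult
from sizehab.mechanisms import (
    MechanismLedger,
    aggregate_mechanisms,
    annotate_migration,
    classify_mechanisms,
    continuous_association,
    ledgers_to_frame,
    migration_band,
    percentage_alignment,
)
from sizehab.stats import MetricOutcome


def ledger(A=None, Bi=None, C=None, D=None, A_prime=None, pair=("freshwater", "marine")):
    return MechanismLedger(
        scale="tax3", clade_id="c1", habitat_a=pair[0], habitat_b=pair[1],
        larger_habitat=pair[1], A=A, A_prime=A_prime, Bi=Bi, C=C, D=D,
    )


def make_summary(**cols):
    """Two-habitat summary table with given per-habitat column values."""
    habitats = ["freshwater", "marine"]
    data = {"habitat": habitats}
    for col, vals in cols.items():
        data[col] = vals
    return pd.DataFrame(data).set_index("habitat")


def comparison(larger="marine"):
    diff = -0.5 if larger == "marine" else 0.5
    out = MetricOutcome(
        metric="phylo_mean", habitat_a="freshwater", habitat_b="marine",
        larger_habitat=larger, signed_difference=diff, n_first=5, n_second=5,
    )
    return ComparisonResult(
        scale="tax3", clade_id="c1", habitat_a="freshwater", habitat_b="marine",
        outcomes={"phylo_mean": out},
    )


class TestClassifier:
    def test_rule_application_example(self):
        # size-larger habitat: higher trophic and migratory 50 vs 10
        summ = make_summary(
            trophic_phylo_mean=[3.0, 3.5],
            trophic_mean=[3.0, 3.4],
            migratory_pct=[10.0, 50.0],
            mean_tip_duration=[1.0, 1.0],
            richness=[5, 5],
        )
        led = classify_mechanisms(comparison("marine"), summ)
        assert (led.A, led.Bi, led.Bii, led.Biii) == (True, True, True, False)

    def test_migration_gap_boundary(self):
        base = dict(
            trophic_phylo_mean=[3.5, 3.0],
            trophic_mean=[3.5, 3.0],
            mean_tip_duration=[1.0, 1.0],
            richness=[5, 5],
        )
        exactly20 = make_summary(migratory_pct=[10.0, 30.0], **base)
        led = classify_mechanisms(comparison("marine"), exactly20)
        assert led.Bi is True  # "by at least 20" is inclusive
        just_under = make_summary(migratory_pct=[10.0, 29.9], **base)
        assert classify_mechanisms(comparison("marine"), just_under).Bi is False

    def test_biii_requires_not_a(self):
        summ = make_summary(
            trophic_phylo_mean=[3.5, 3.0],  # size-larger (marine) is LOWER
            trophic_mean=[3.5, 3.0],
            migratory_pct=[0.0, 40.0],
            mean_tip_duration=[2.0, 1.0],
            richness=[3, 9],
        )
        led = classify_mechanisms(comparison("marine"), summ)
        assert led.A is False and led.Bi is True
        assert led.Biii is True and led.Bii is False
        assert led.C is False and led.D is False

    def test_missing_data_unknown(self):
        summ = make_summary(
            trophic_phylo_mean=[np.nan, 3.0],
            trophic_mean=[np.nan, 3.0],
            migratory_pct=[np.nan, 40.0],
            mean_tip_duration=[1.0, 2.0],
            richness=[9, 3],
        )
        led = classify_mechanisms(comparison("marine"), summ)
        assert led.A is None and led.Bi is None
        assert led.Bii is None and led.Biii is None
        assert led.C is True and led.D is True

    def test_tie_direction_rejected(self):
        summ = make_summary(
            trophic_phylo_mean=[3.0, 3.0], trophic_mean=[3.0, 3.0],
            migratory_pct=[0.0, 0.0], mean_tip_duration=[1.0, 1.0],
            richness=[5, 5],
        )
        comp = comparison("marine")
        comp.outcomes["phylo_mean"].larger_habitat = "tie"
        with pytest.raises(ValueError, match="direction"):
            classify_mechanisms(comp, summ)


class TestLedgerLogic:
    def test_printed_row_any_of_four_positive(self):
        # indicators (A, Bi, C, D) = (1, 0, 0, 1) -> at least one suite active
        led = ledger(A=True, Bi=False, C=False, D=True)
        assert led.any_of_four is True

    def test_printed_row_all_zero(self):
        led = ledger(A=False, Bi=False, C=False, D=False)
        assert led.any_of_four is False
        assert led.A_or_Biii is False

    @given(
        st.lists(
            st.tuples(st.booleans(), st.booleans(), st.booleans(), st.booleans()),
            min_size=1,
            max_size=60,
        )
    )
    @settings(max_examples=60, deadline=None)
    def test_count_identities(self, rows):
        leds = [ledger(A=a, Bi=b, C=c, D=d) for a, b, c, d in rows]
        n = {
            col: sum(bool(getattr(l, col)) for l in leds)
            for col in ("A", "Bi", "Bii", "Biii", "A_or_Biii", "any_of_four", "C", "D")
        }
        assert n["Bii"] + n["Biii"] == n["Bi"]
        assert n["A_or_Biii"] == n["A"] + n["Bi"] - n["Bii"]
        for col in ("A", "Bi", "C", "D"):
            assert n["any_of_four"] >= n[col]


class TestAggregation:
    def build_92(self):
        leds = []
        for i in range(92):
            if i < 9:
                leds.append(ledger(A=True, Bi=True, C=False, D=False))
            elif i < 21:
                leds.append(ledger(A=False, Bi=True, C=False, D=False))
            else:
                leds.append(ledger(A=False, Bi=False, C=False, D=False))
        return leds

    def test_bii_prime(self):
        agg = aggregate_mechanisms(self.build_92())
        row = agg[agg.habitat_a == "all"].iloc[0]
        assert row.n_comparisons == 92
        assert row.Bi_n == 21 and row.Bii_n == 9 and row.Biii_n == 12
        assert round(row.Bii_prime_pct, 1) == 42.9
        assert round(row.Biii_prime_pct, 1) == 57.1

    def test_union_all_a(self):
        leds = [ledger(A=True, Bi=False, C=False, D=False) for _ in range(11)]
        agg = aggregate_mechanisms(leds)
        assert agg[agg.habitat_a == "all"].iloc[0].A_or_Biii_pct == pytest.approx(100.0)

    def test_bi_zero_gives_na_primes(self):
        leds = [ledger(A=True, Bi=False, C=False, D=False) for _ in range(4)]
        row = aggregate_mechanisms(leds)[lambda d: d.habitat_a == "all"].iloc[0]
        assert np.isnan(row.Bii_prime_pct) and np.isnan(row.Biii_prime_pct)

    def test_recount_oracle(self):
        rng = np.random.default_rng(3)
        leds = [
            ledger(A=bool(a), Bi=bool(b), C=bool(c), D=bool(d))
            for a, b, c, d in rng.integers(0, 2, size=(40, 4))
        ]
        agg = aggregate_mechanisms(leds)
        row = agg[agg.habitat_a == "all"].iloc[0]
        frame = ledgers_to_frame(leds)
        for col in ("A", "Bi", "Bii", "Biii", "A_or_Biii", "C", "D", "any_of_four"):
            assert row[f"{col}_n"] == frame[col].sum()

    def test_empty_error(self):
        with pytest.raises(ValueError):
            aggregate_mechanisms([])


class TestAlignment:
    def _table(self, d1, d2):
        n = len(d1)
        return pd.DataFrame(
            {
                "scale": ["tax3"] * n,
                "clade_id": [f"c{i}" for i in range(n)],
                "habitat_a": ["freshwater"] * n,
                "habitat_b": ["marine"] * n,
                "m1": d1,
                "m2": d2,
            }
        )

    def test_identical_metrics_100pct(self):
        rng = np.random.default_rng(0)
        d = rng.normal(size=30)
        cells = percentage_alignment(self._table(d, d), "m1", "m2")
        assert cells[0].pct_aligned == 100.0

    def test_negated_metric_0pct(self):
        rng = np.random.default_rng(1)
        d = rng.normal(size=30)
        cells = percentage_alignment(self._table(d, -d), "m1", "m2")
        assert cells[0].pct_aligned == 0.0

    def test_independent_signs_near_50(self):
        rng = np.random.default_rng(2)
        d1 = rng.choice([-1.0, 1.0], size=1000)
        d2 = rng.choice([-1.0, 1.0], size=1000)
        cells = percentage_alignment(self._table(d1, d2), "m1", "m2")
        assert 45.0 <= cells[0].pct_aligned <= 55.0

    def test_ties_excluded_and_counted(self):
        cells = percentage_alignment(
            self._table([1.0, 0.0, -1.0, np.nan], [1.0, 1.0, 1.0, 1.0]), "m1", "m2"
        )
        c = cells[0]
        assert c.n_compared == 2 and c.n_tied == 1 and c.n_aligned == 1


class TestContinuous:
    def _table(self, x, y):
        n = len(x)
        return pd.DataFrame(
            {
                "scale": ["order"] * n,
                "clade_id": [f"c{i}" for i in range(n)],
                "habitat_a": ["freshwater"] * n,
                "habitat_b": ["marine"] * n,
                "dx": x,
                "dy": y,
            }
        )

    def test_exact_linear(self):
        x = np.array([-2.0, -1.0, 1.0, 2.0, 3.0])
        out = continuous_association(
            self._table(x, 2 * x), "dx", "dy", ("freshwater", "marine")
        )
        assert out["r2"] == pytest.approx(1.0)
        assert out["slope"] == pytest.approx(2.0)
        assert out["quadrant_counts"]["+-"] == 0
        assert out["quadrant_counts"]["-+"] == 0

    def test_quadrant_recount(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=50)
        y = rng.normal(size=50)
        out = continuous_association(self._table(x, y), "dx", "dy", ("freshwater", "marine"))
        q = out["quadrant_counts"]
        assert q["++"] == int(np.sum((x > 0) & (y > 0)))
        assert q["--"] == int(np.sum((x < 0) & (y < 0)))
        assert sum(q.values()) == int(np.sum((x != 0) & (y != 0)))

    def test_outlier_flagged_by_jackknife(self):
        rng = np.random.default_rng(8)
        x = np.concatenate([rng.normal(0, 0.1, 8), [5.0]])
        y = np.concatenate([rng.normal(0, 0.1, 8), [5.0]])
        out = continuous_association(self._table(x, y), "dx", "dy", ("freshwater", "marine"))
        assert out["p"] < 0.05
        assert "c8" in out["influential_clades"]

    def test_zero_variance_x(self):
        x = np.zeros(5)
        y = np.arange(5.0) - 2
        out = continuous_association(self._table(x, y), "dx", "dy", ("freshwater", "marine"))
        assert np.isnan(out["slope"])
        assert sum(out["quadrant_counts"].values()) == 0


class TestMigrationBands:
    @pytest.mark.parametrize(
        "pct,band",
        [(31.0, "M"), (30.0, "m"), (5.0, "m"), (4.9, "none"), (100.0, "M"), (0.0, "none")],
    )
    def test_band_boundaries(self, pct, band):
        assert migration_band(pct) == band

    def test_annotate_frame(self):
        summ = make_summary(migratory_pct=[4.0, 50.0])
        df = annotate_migration({("order", "c1"): summ})
        bands = dict(zip(df["habitat"], df["band"]))
        assert bands == {"freshwater": "none", "marine": "M"}
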