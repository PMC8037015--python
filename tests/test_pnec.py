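"""Endpoint aggregation and assessment-factor selection.

The AF oracle here is an independent, literal enumeration of the
availability-pattern ladder, keyed by (acute coverage, chronic coverage,
whether the most sensitive acute taxon has chronic data).
"""

import math
import random

import pytest
from hypothesis import given
from hypothesis import strategies as st

from hbttc.core import Concentration, ValidationError
from hbttc.pnec import (
    TROPHIC_GROUPS,
    build_matrix,
    derive_pnec,
    geometric_mean,
    select_af,
)

from conftest import records_from_cells, rec


class TestGeometricMean:
    def test_identical(self):
        assert geometric_mean([4, 4]) == pytest.approx(4)

    def test_powers_of_ten(self):
        assert geometric_mean([1, 10, 100]) == pytest.approx(10)

    def test_sqrt(self):
        assert geometric_mean([2, 8]) == pytest.approx(4)

    def test_empty_rejected(self):
        with pytest.raises(ValidationError):
            geometric_mean([])

    def test_nonpositive_rejected(self):
        with pytest.raises(ValidationError):
            geometric_mean([1, 0])

    @given(st.lists(st.floats(min_value=1e-6, max_value=1e6), min_size=1, max_size=20))
    def test_log_base_invariance(self, values):
        # same result computed on log10 scale
        via_log10 = 10 ** (sum(math.log10(v) for v in values) / len(values))
        assert geometric_mean(values) == pytest.approx(via_log10, rel=1e-9)


class TestBuildMatrix:
    def test_single_cell_geomean(self):
        m = build_matrix(records_from_cells({("fish", "acute"): [2, 8]}))
        assert m.cells[("fish", "acute")] == (pytest.approx(4), 2)

    def test_all_six_cells(self):
        cells = {(g, d): [1.0] for g in TROPHIC_GROUPS for d in ("acute", "chronic")}
        m = build_matrix(records_from_cells(cells))
        assert len(m.cells) == 6

    def test_empty_rejected(self):
        with pytest.raises(ValidationError):
            build_matrix([])

    def test_mixed_chemicals_rejected(self):
        with pytest.raises(ValidationError):
            build_matrix([rec(chem="A"), rec(chem="B")])

    def test_unit_conversion_to_canonical(self):
        m = build_matrix([rec(value=1000, unit="µg/L")])
        assert m.cells[("fish", "acute")][0] == pytest.approx(1.0)


# ---------------------------------------------------------------------------
# independent AF oracle: literal ladder enumeration

LADDER = {
    # (n_acute, n_chronic, ms_has_chronic) -> (af, rule_id)
    (3, 0, False): (1000, "3-acute"),
    (3, 1, True): (100, "3+1-on-ms"),
    (3, 1, False): (1000, "3+1-not-ms"),
    (3, 2, True): (50, "3+2-incl-ms"),
    (3, 2, False): (1000, "fallback-3-acute"),
    (3, 3, True): (10, "3+3"),
}


def oracle_af(acute, chronic, ms_taxon, n_chronic_records, rich_af=5.0):
    if n_chronic_records > 10:
        return rich_af, "chronic-rich"
    na, nc = len(acute), len(chronic)
    if na == 3:
        return LADDER[(3, nc, ms_taxon in chronic)]
    if na == 2:
        return 5000, ("2-acute" if nc == 0 else "fallback-2-acute")
    if na == 1:
        return 10000, ("1-acute" if nc == 0 else "fallback-1-acute")
    return 10000, "fallback-chronic-only"


def oracle_most_sensitive(acute_geomeans):
    # lowest geomean; ties broken algae < invertebrate < fish
    return min(acute_geomeans, key=lambda g: (acute_geomeans[g], TROPHIC_GROUPS.index(g)))


class TestSelectAf:
    def test_one_acute(self):
        m = build_matrix(records_from_cells({("fish", "acute"): [5]}))
        af, rule, basis, fallback = select_af(m)
        assert (af, rule, fallback) == (10000, "1-acute", False)
        assert basis == ("fish", "acute")

    def test_two_acute(self):
        m = build_matrix(
            records_from_cells({("fish", "acute"): [5], ("algae", "acute"): [2]})
        )
        af, rule, basis, _ = select_af(m)
        assert (af, rule) == (5000, "2-acute")
        assert basis == ("algae", "acute")

    def test_three_acute_most_sensitive_basis(self):
        cells = {("algae", "acute"): [1], ("invertebrate", "acute"): [10], ("fish", "acute"): [100]}
        af, rule, basis, _ = select_af(build_matrix(records_from_cells(cells)))
        assert (af, rule, basis) == (1000, "3-acute", ("algae", "acute"))

    def test_chronic_on_most_sensitive(self):
        cells = {
            ("algae", "acute"): [1],
            ("invertebrate", "acute"): [10],
            ("fish", "acute"): [100],
            ("algae", "chronic"): [0.5],
        }
        af, rule, basis, _ = select_af(build_matrix(records_from_cells(cells)))
        assert (af, rule, basis) == (100, "3+1-on-ms", ("algae", "chronic"))

    def test_chronic_not_on_most_sensitive(self):
        cells = {
            ("algae", "acute"): [1],
            ("invertebrate", "acute"): [10],
            ("fish", "acute"): [100],
            ("fish", "chronic"): [0.5],
        }
        af, rule, basis, _ = select_af(build_matrix(records_from_cells(cells)))
        assert (af, rule, basis) == (1000, "3+1-not-ms", ("algae", "acute"))

    def test_two_chronic_including_ms(self):
        cells = {
            ("algae", "acute"): [1],
            ("invertebrate", "acute"): [10],
            ("fish", "acute"): [100],
            ("algae", "chronic"): [0.5],
            ("fish", "chronic"): [0.2],
        }
        af, rule, basis, _ = select_af(build_matrix(records_from_cells(cells)))
        assert (af, rule, basis) == (50, "3+2-incl-ms", ("fish", "chronic"))

    def test_full_matrix(self):
        cells = {(g, d): [1.0] for g in TROPHIC_GROUPS for d in ("acute", "chronic")}
        af, rule, basis, _ = select_af(build_matrix(records_from_cells(cells)))
        assert (af, rule) == (10, "3+3")

    def test_chronic_rich(self):
        cells = {
            ("algae", "acute"): [1],
            ("invertebrate", "acute"): [1],
            ("fish", "acute"): [1],
            ("fish", "chronic"): [0.5] * 11,
        }
        af, rule, _, _ = select_af(build_matrix(records_from_cells(cells)))
        assert (af, rule) == (5.0, "chronic-rich")

    def test_chronic_rich_configurable(self):
        cells = {("fish", "chronic"): [0.5] * 11}
        af, rule, _, _ = select_af(build_matrix(records_from_cells(cells)), rich_chronic_af=2.0)
        assert (af, rule) == (2.0, "chronic-rich")
        with pytest.raises(ValidationError):
            select_af(build_matrix(records_from_cells(cells)), rich_chronic_af=7.0)

    def test_fallback_patterns_flagged(self):
        # chronic data with incomplete acute coverage
        cells = {("fish", "acute"): [5], ("fish", "chronic"): [1]}
        af, rule, _, fallback = select_af(build_matrix(records_from_cells(cells)))
        assert (af, rule, fallback) == (10000, "fallback-1-acute", True)
        # chronic only
        af, rule, basis, fallback = select_af(
            build_matrix(records_from_cells({("algae", "chronic"): [1]}))
        )
        assert (af, rule, fallback) == (10000, "fallback-chronic-only", True)
        assert basis == ("algae", "chronic")

    def test_acute_ladder_monotone(self):
        afs = []
        cells = {}
        for g in TROPHIC_GROUPS:
            cells[(g, "acute")] = [1.0]
            af, _, _, _ = select_af(build_matrix(records_from_cells(dict(cells))))
            afs.append(af)
        assert afs == [10000, 5000, 1000]

    def test_ms_tie_broken_by_trophic_order(self):
        cells = {
            ("algae", "acute"): [1],
            ("invertebrate", "acute"): [1],
            ("fish", "acute"): [1],
            ("algae", "chronic"): [0.5],
        }
        af, rule, _, _ = select_af(build_matrix(records_from_cells(cells)))
        assert (af, rule) == (100, "3+1-on-ms")


class TestOracleAgreement:
    def test_random_availability_patterns(self):
        rng = random.Random(42)
        n_checked = 0
        while n_checked < 1200:
            n_acute = rng.randint(0, 3)
            n_chronic_groups = rng.randint(0, 3)
            if n_acute == 0 and n_chronic_groups == 0:
                continue
            acute = rng.sample(TROPHIC_GROUPS, n_acute)
            chronic = rng.sample(TROPHIC_GROUPS, n_chronic_groups)
            cells = {}
            for g in acute:
                cells[(g, "acute")] = [rng.lognormvariate(0, 2) for _ in range(rng.randint(1, 3))]
            total_chronic = 0
            for g in chronic:
                reps = rng.randint(1, 5) if rng.random() < 0.9 else rng.randint(4, 8)
                cells[(g, "chronic")] = [rng.lognormvariate(-1, 2) for _ in range(reps)]
                total_chronic += reps

            matrix = build_matrix(records_from_cells(cells))
            acute_geomeans = {
                g: matrix.geomean((g, "acute")) for g in acute
            }
            ms = oracle_most_sensitive(acute_geomeans) if acute else None
            exp_af, exp_rule = oracle_af(set(acute), set(chronic), ms, total_chronic)
            af, rule, _, _ = select_af(matrix)
            assert (af, rule) == (exp_af, exp_rule), cells
            n_checked += 1


class TestDerivePnec:
    def test_single_acute(self):
        res = derive_pnec(records_from_cells({("fish", "acute"): [5]}))
        assert res.pnec.mg_per_l == pytest.approx(0.0005)
        assert res.af == 10000

    def test_three_acute(self):
        cells = {("algae", "acute"): [1], ("invertebrate", "acute"): [10], ("fish", "acute"): [100]}
        res = derive_pnec(records_from_cells(cells))
        assert res.pnec.mg_per_l == pytest.approx(0.001)
        assert res.basis_cell == ("algae", "acute")

    def test_chronic_on_ms(self):
        cells = {
            ("algae", "acute"): [1],
            ("invertebrate", "acute"): [10],
            ("fish", "acute"): [100],
            ("algae", "chronic"): [0.5],
        }
        res = derive_pnec(records_from_cells(cells))
        assert res.pnec.mg_per_l == pytest.approx(0.005)
        assert (res.af, res.rule_id) == (100, "3+1-on-ms")

    def test_pnec_equals_basis_over_af(self):
        cells = {
            ("algae", "acute"): [3.7, 1.1],
            ("fish", "acute"): [9.0],
            ("fish", "chronic"): [0.8],
        }
        res = derive_pnec(records_from_cells(cells))
        assert res.pnec.mg_per_l == pytest.approx(res.basis_value.mg_per_l / res.af, rel=1e-15)
        assert res.pnec.mg_per_l <= res.basis_value.mg_per_l

    def test_order_invariance(self):
        cells = {
            ("algae", "acute"): [3.7, 1.1],
            ("invertebrate", "acute"): [2.0],
            ("fish", "acute"): [9.0],
            ("fish", "chronic"): [0.8],
        }
        recs = records_from_cells(cells)
        shuffled = list(recs)
        random.Random(7).shuffle(shuffled)
        assert derive_pnec(recs) == derive_pnec(shuffled)
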