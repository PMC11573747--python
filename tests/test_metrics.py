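"""Geometric MFI and the dependence calculus."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from scenith import (
    LowResolutionError,
    MetricError,
    aggregate_replicates,
    dependence_profile,
    fold_change,
    geometric_mfi,
    seahorse_glycolytic_capacity,
)
from scenith.metrics import (
    FLAG_MITA,
    FLAG_NEGATIVE_GLUCOSE_DEP,
    FLAG_OUT_OF_RANGE,
    POLICY_MEAN_FIRST,
    POLICY_PROFILE_FIRST,
)


def oracle_profile(d, g2, o, b):
    """Independent re-evaluation of the two published ratio formulas."""
    delta = d - b
    return (100.0 * (d - g2) / delta, 100.0 * (d - o) / delta)


class TestGeometricMFI:
    @pytest.mark.parametrize("c", [0.5, 1.0, 873.2])
    def test_constant_is_identity(self, c):
        assert geometric_mfi([c] * 30, min_events_error=10).gmfi == pytest.approx(c)

    def test_log_midpoint(self):
        assert geometric_mfi([1.0, 100.0] * 15, min_events_error=10).gmfi == (
            pytest.approx(10.0)
        )

    def test_lognormal_recovers_exp_mu(self, rng):
        # closed form: geometric mean of LogNormal(ln 500, 0.25) -> 500
        draws = rng.lognormal(np.log(500.0), 0.25, 50_000)
        res = geometric_mfi(draws)
        assert res.gmfi == pytest.approx(500.0, rel=0.02)

    def test_nonpositive_dropped_and_counted(self):
        values = np.array([-1.0, 0.0] + [10.0] * 30)
        res = geometric_mfi(values, min_events_error=10)
        assert res.n_dropped == 2
        assert res.n_events == 30

    def test_too_few_events_is_error(self):
        with pytest.raises(MetricError):
            geometric_mfi([5.0] * 10, min_events_error=25)

    def test_arithmetic_statistic_option(self):
        res = geometric_mfi([1.0, 100.0] * 15, min_events_error=5,
                            statistic="arithmetic")
        assert res.gmfi == pytest.approx(50.5)


class TestDependenceProfile:
    def test_reference_quadruple(self):
        p = dependence_profile(1000, 400, 700, 200)
        assert (p.glucose_dependence, p.mitochondrial_dependence) == (75.0, 37.5)
        assert (p.glycolytic_capacity, p.faoaao_capacity) == (62.5, 25.0)

    def test_zero_numerators(self):
        p = dependence_profile(1000, 1000, 1000, 200)
        assert (p.glucose_dependence, p.mitochondrial_dependence) == (0.0, 0.0)
        assert (p.glycolytic_capacity, p.faoaao_capacity) == (100.0, 100.0)

    def test_mita_flagged_on_negative_mito(self):
        p = dependence_profile(1000, 300, 1200, 200)
        assert p.mitochondrial_dependence == -25.0
        assert FLAG_MITA in p.flags and FLAG_OUT_OF_RANGE in p.flags

    def test_negative_glucose_flag(self):
        p = dependence_profile(1000, 1100, 700, 200)
        assert p.glucose_dependence < 0
        assert FLAG_NEGATIVE_GLUCOSE_DEP in p.flags

    def test_vanishing_denominator_raises(self):
        with pytest.raises(LowResolutionError):
            dependence_profile(1000, 400, 700, 1000)
        with pytest.raises(LowResolutionError):
            dependence_profile(900, 400, 700, 1000)

    def test_matches_independent_oracle_on_random_quadruples(self, rng):
        for _ in range(500):
            d = rng.uniform(100, 10_000)
            b = d - rng.uniform(1, d - 1)
            g2 = rng.uniform(0.5 * b, 1.5 * d)
            o = rng.uniform(0.5 * b, 1.5 * d)
            p = dependence_profile(d, g2, o, b)
            glucose, mito = oracle_profile(d, g2, o, b)
            assert p.glucose_dependence == pytest.approx(glucose, rel=1e-12)
            assert p.mitochondrial_dependence == pytest.approx(mito, rel=1e-12)

    @given(
        d=st.floats(10.0, 1e6),
        frac_b=st.floats(1e-3, 0.999),
        frac_g=st.floats(-0.5, 1.5),
        frac_o=st.floats(-0.5, 1.5),
    )
    def test_conservation_identities(self, d, frac_b, frac_g, frac_o):
        b = d * frac_b
        g2 = b + (d - b) * frac_g
        o = b + (d - b) * frac_o
        p = dependence_profile(d, g2, o, b)
        # complements are stored as 100 - dependence, so these hold bit-exactly
        assert p.faoaao_capacity == 100.0 - p.glucose_dependence
        assert p.glycolytic_capacity == 100.0 - p.mitochondrial_dependence
        assert p.glucose_dependence + p.faoaao_capacity == pytest.approx(100.0)
        assert p.mitochondrial_dependence + p.glycolytic_capacity == (
            pytest.approx(100.0)
        )

    @given(
        scale=st.floats(1e-3, 1e3),
        shift=st.floats(0.0, 1e4),
    )
    def test_affine_invariance(self, scale, shift):
        base = (1000.0, 400.0, 700.0, 200.0)
        p = dependence_profile(*base)
        q = dependence_profile(*(scale * x + shift for x in base))
        assert q.glucose_dependence == pytest.approx(p.glucose_dependence,
                                                     rel=1e-9, abs=1e-9)
        assert q.mitochondrial_dependence == pytest.approx(
            p.mitochondrial_dependence, rel=1e-9, abs=1e-9
        )

    def test_swap_symmetry(self, rng):
        for _ in range(50):
            d, b = 1000.0, rng.uniform(10, 900)
            g2, o = rng.uniform(b, d, 2)
            p = dependence_profile(d, g2, o, b)
            q = dependence_profile(d, o, g2, b)
            assert q.glucose_dependence == pytest.approx(p.mitochondrial_dependence)
            assert q.mitochondrial_dependence == pytest.approx(p.glucose_dependence)

    def test_clamped_view_preserves_complements(self):
        p = dependence_profile(1000, 300, 1200, 200).clamped()
        assert p.mitochondrial_dependence == 0.0
        assert p.glycolytic_capacity == 100.0


class TestFoldChange:
    def test_equal_inputs_is_one(self):
        assert fold_change(500.0, 500.0).fold_change == 1.0

    def test_ratio(self):
        assert fold_change(2000.0, 500.0).fold_change == 4.0

    def test_nonpositive_rejected(self):
        with pytest.raises(MetricError):
            fold_change(0.0, 500.0)


class TestSeahorseCapacity:
    @pytest.mark.parametrize(
        "basal, oligo, expected", [(10, 25, 15), (25, 25, 0), (25, 10, -15)]
    )
    def test_difference(self, basal, oligo, expected):
        capacity, warnings = seahorse_glycolytic_capacity(basal, oligo)
        assert capacity == expected
        assert bool(warnings) == (expected < 0)


def _mfi_frame(rows):
    return pd.DataFrame(
        rows, columns=["population", "condition", "replicate_id", "gmfi"]
    )


class TestAggregateReplicates:
    DUPLICATES = _mfi_frame(
        [
            ("mac", "DMSO", "r1", 900), ("mac", "DMSO", "r2", 1100),
            ("mac", "2DG", "r1", 380), ("mac", "2DG", "r2", 420),
            ("mac", "Oligo", "r1", 680), ("mac", "Oligo", "r2", 720),
            ("mac", "2DG+Oligo", "r1", 190), ("mac", "2DG+Oligo", "r2", 210),
        ]
    )

    def test_mean_first_matches_hand_computation(self):
        out = aggregate_replicates(self.DUPLICATES, policy=POLICY_MEAN_FIRST)
        assert out.loc[0, "glucose_dependence"] == pytest.approx(75.0)
        assert out.loc[0, "mitochondrial_dependence"] == pytest.approx(37.5)

    def test_identical_replicates_agree_across_policies(self):
        frame = _mfi_frame(
            [("mac", c, r, v)
             for r in ("r1", "r2")
             for c, v in [("DMSO", 1000), ("2DG", 400), ("Oligo", 700),
                          ("2DG+Oligo", 200)]]
        )
        a = aggregate_replicates(frame, policy=POLICY_MEAN_FIRST)
        b = aggregate_replicates(frame, policy=POLICY_PROFILE_FIRST)
        for col in ("glucose_dependence", "mitochondrial_dependence"):
            assert a.loc[0, col] == pytest.approx(b.loc[0, col])

    def test_policies_match_two_path_oracle(self, rng):
        # oracle: explicit computation of both aggregation paths
        for _ in range(20):
            reps = {c: rng.uniform(50, 1000, 2) for c in
                    ("DMSO", "2DG", "Oligo", "2DG+Oligo")}
            reps["DMSO"] += 1200  # keep dMFI > 0 per replicate
            frame = _mfi_frame(
                [("p", c, f"r{i + 1}", v)
                 for c, vals in reps.items() for i, v in enumerate(vals)]
            )
            mean_first = aggregate_replicates(frame, policy=POLICY_MEAN_FIRST)
            per_rep = aggregate_replicates(frame, policy=POLICY_PROFILE_FIRST)

            means = {c: v.mean() for c, v in reps.items()}
            expected_mean_first = oracle_profile(
                means["DMSO"], means["2DG"], means["Oligo"], means["2DG+Oligo"]
            )
            expected_per_rep = np.mean(
                [
                    oracle_profile(reps["DMSO"][i], reps["2DG"][i],
                                   reps["Oligo"][i], reps["2DG+Oligo"][i])
                    for i in range(2)
                ],
                axis=0,
            )
            assert mean_first.loc[0, "glucose_dependence"] == pytest.approx(
                expected_mean_first[0]
            )
            assert per_rep.loc[0, "glucose_dependence"] == pytest.approx(
                expected_per_rep[0]
            )
            assert per_rep.loc[0, "mitochondrial_dependence"] == pytest.approx(
                expected_per_rep[1]
            )

    def test_missing_condition_is_undefined_profile(self):
        frame = self.DUPLICATES[self.DUPLICATES["condition"] != "Oligo"]
        with pytest.raises(LowResolutionError, match="Oligo"):
            aggregate_replicates(frame)
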