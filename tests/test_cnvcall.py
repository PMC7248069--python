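"""Copy-number procedure: reference building, the doubling rule, thresholded
calls and the noiseless closed-form oracle."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import zygocall as z


def exact_profile(units, genome, depth, sample_id="s", sex_label="unknown"):
    """A noise-free count profile: proportions times depth, apportioned by
    largest remainder so the counts sum to depth exactly."""
    props = z.proportions_from_units(units, genome)
    names = list(props)
    raw = np.array([props[n] * depth for n in names])
    counts = np.floor(raw).astype(int)
    short = depth - counts.sum()
    for i in np.argsort(raw - np.floor(raw))[::-1][:short]:
        counts[i] += 1
    return z.CountProfile(sample_id, sex_label, dict(zip(names, counts.tolist())), depth)


@pytest.fixture
def toy20_ref(toy20):
    """Noise-free sex reference on the equal-length toy (female-only genome
    has no Y, so build the reference profile object directly)."""
    female = z.proportions_from_units(
        {n: 2 for n in toy20.female_names}, toy20
    )
    return z.ReferenceProfile(
        proportions={"female": female, "male": female},
        n_female=1,
        n_male=1,
        mode="sex_matched",
    )


@pytest.fixture
def mouse_ref(mouse):
    female = z.proportions_from_units(z.euploid_reference_units("female", mouse), mouse)
    male = z.proportions_from_units(z.euploid_reference_units("male", mouse), mouse)
    return z.ReferenceProfile(
        proportions={"female": female, "male": male},
        n_female=1,
        n_male=1,
        mode="sex_matched",
    )


class TestBuildReference:
    def test_single_noiseless_female_equals_expected_proportions(self, toy20):
        prof = exact_profile({n: 2 for n in toy20.names}, toy20, 20_000, sex_label="female")
        male = exact_profile({n: 2 for n in toy20.names}, toy20, 20_000, "m", "male")
        ref = z.build_reference([prof, male])
        expected = z.proportions_from_units({n: 2 for n in toy20.names}, toy20)
        assert ref.proportions["female"] == pytest.approx(expected, abs=1e-12)

    def test_idempotent_on_identical_profiles(self, toy20):
        prof = exact_profile({n: 2 for n in toy20.names}, toy20, 20_000, sex_label="female")
        male = exact_profile({n: 2 for n in toy20.names}, toy20, 20_000, "m", "male")
        one = z.build_reference([prof, male])
        two = z.build_reference([prof, prof, male, male])
        for sex in ("female", "male"):
            assert one.proportions[sex] == pytest.approx(two.proportions[sex], abs=1e-15)

    def test_simulated_reference_near_analytic_expectation(self, mouse, rng):
        noise = z.NoiseModel(depth=200_000, rho=0.0)
        profiles = z.simulate_reference_cohort(10, 10, noise, mouse, rng)
        ref = z.build_reference(profiles)
        expected = z.proportions_from_units(
            z.euploid_reference_units("female", mouse), mouse
        )
        for n in mouse.autosomes:
            p = expected[n]
            se = np.sqrt(p * (1 - p) / (200_000 * 10))
            assert abs(ref.proportions["female"][n] - p) < 3 * se

    def test_missing_sex_rejected_in_sex_matched_mode(self, toy20):
        prof = exact_profile({n: 2 for n in toy20.names}, toy20, 20_000, sex_label="female")
        with pytest.raises(ValueError, match="sex_matched"):
            z.build_reference([prof])
        # pooled mode accepts a single-sex set
        pooled = z.build_reference([prof], mode="pooled")
        assert pooled.mode == "pooled" and "pooled" in pooled.proportions

    def test_empty_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            z.build_reference([])


class TestInferSex:
    def test_noiseless_euploid_profiles(self, mouse, mouse_ref):
        male_units = z.euploid_reference_units("male", mouse)
        props = z.proportions_from_units(male_units, mouse)
        counts = {n: round(p * 1_000_000) for n, p in props.items()}
        total = sum(counts.values())
        prof = z.CountProfile("m", "unknown", counts, total)
        assert z.infer_sex(prof, mouse_ref, mouse) == "male"

    def test_zero_y_reads_is_female(self, mouse, mouse_ref):
        prof = exact_profile({n: 2 for n in mouse.female_names}, mouse, 200_000)
        assert prof.counts["Y"] == 0
        assert z.infer_sex(prof, mouse_ref, mouse) == "female"

    def test_noisy_euploid_female_always_female(self, mouse, mouse_ref, rng):
        props = z.proportions_from_units(
            z.euploid_reference_units("female", mouse), mouse
        )
        noise = z.NoiseModel(depth=200_000, rho=0.002)
        for _ in range(100):
            prof = z.simulate_counts_from_proportions(props, noise, rng)
            assert z.infer_sex(prof, mouse_ref, mouse) == "female"

    def test_zero_male_y_reference_unusable(self, toy20_ref, mouse):
        # toy reference carries no Y proportion at all
        bad = z.ReferenceProfile(
            proportions={
                "female": dict(toy20_ref.proportions["female"]),
                "male": dict(toy20_ref.proportions["male"]),
            },
            n_female=1,
            n_male=1,
            mode="sex_matched",
        )
        prof_counts = {n: 1000 for n in bad.proportions["female"]}
        prof = z.CountProfile("s", "unknown", prof_counts, sum(prof_counts.values()))
        with pytest.raises(ValueError, match="zero Y"):
            z.infer_sex(prof, bad, mouse)


class TestPredictCopyNumber:
    def test_doubling_rule_female(self, mouse, mouse_ref):
        props = z.proportions_from_units(
            z.euploid_reference_units("female", mouse), mouse
        )
        cnp = z.predict_copy_number_from_proportions(props, mouse_ref, "female", mouse)
        for n in (*mouse.autosomes, "X"):
            assert cnp.copy_number[n] == pytest.approx(2.0, abs=1e-12)
        assert "Y" in cnp.absent and "Y" not in cnp.copy_number

    def test_single_copy_rule_male(self, mouse, mouse_ref):
        props = z.proportions_from_units(
            z.euploid_reference_units("male", mouse), mouse
        )
        cnp = z.predict_copy_number_from_proportions(props, mouse_ref, "male", mouse)
        assert cnp.copy_number["X"] == pytest.approx(1.0, abs=1e-12)
        assert cnp.copy_number["Y"] == pytest.approx(1.0, abs=1e-12)
        for n in mouse.autosomes:
            assert cnp.copy_number[n] == pytest.approx(2.0, abs=1e-12)

    def test_extra_chromatid_closed_form(self, toy20, toy20_ref):
        # Equal-length toy, chr1 at 3 chromatid units: proportions renormalise
        # over 41 units, so CN(chr1) = 2*(3/41)/(2/40) = 120/41 and every other
        # chromosome reads 80/41.
        units = {n: 2 for n in toy20.names}
        units["1"] = 3
        props = z.proportions_from_units(units, toy20)
        cnp = z.predict_copy_number_from_proportions(props, toy20_ref, "female", toy20)
        assert cnp.copy_number["1"] == pytest.approx(120 / 41, abs=1e-9)
        for n in toy20.names:
            if n != "1":
                assert cnp.copy_number[n] == pytest.approx(80 / 41, abs=1e-9)

    def test_noiseless_exactness_general(self, mouse, mouse_ref, rng):
        # CN_c = 2 u_c / sum_j u_j w_j with w the length shares of the female
        # reference complement: verify on random unit maps.
        w = z.proportions_from_units({n: 1 for n in mouse.female_names}, mouse)
        for _ in range(50):
            units = {n: int(rng.integers(1, 5)) for n in mouse.female_names}
            s = sum(units[n] * w[n] for n in mouse.female_names)
            props = z.proportions_from_units(units, mouse)
            cnp = z.predict_copy_number_from_proportions(
                props, mouse_ref, "female", mouse
            )
            for n in mouse.female_names:
                assert cnp.copy_number[n] == pytest.approx(2 * units[n] / s, rel=1e-9)

    def test_reads_on_zero_reference_chromosome_rejected(self, mouse, mouse_ref):
        units = z.euploid_reference_units("male", mouse)
        props = z.proportions_from_units(units, mouse)
        with pytest.raises(ValueError, match="inconsistent reference"):
            z.predict_copy_number_from_proportions(props, mouse_ref, "female", mouse)


class TestCallAneuploidy:
    def _cnp(self, cn, sex="female"):
        return z.CopyNumberProfile("s", sex, {n: v / 2 for n, v in cn.items()}, cn)

    def test_exact_baseline_is_euploid(self, mouse):
        cn = {n: 2.0 for n in mouse.female_names}
        calls = z.call_aneuploidy(self._cnp(cn), z.CallThresholds(), mouse)
        assert calls.n_aneuploid == 0 and calls.complexity == "euploid"

    def test_half_chromatid_gain_detected(self, mouse):
        cn = {n: 2.0 for n in mouse.female_names}
        cn["5"] = 2.5  # 2.5/2 - 1 = 0.25 >= 0.2
        calls = z.call_aneuploidy(self._cnp(cn), z.CallThresholds(0.2), mouse)
        assert calls.calls["5"] == "gain" and calls.complexity == "simple"

    def test_male_baselines(self, mouse):
        cn = {n: 2.0 for n in mouse.autosomes}
        cn["X"] = 1.0
        cn["Y"] = 0.4
        calls = z.call_aneuploidy(self._cnp(cn, sex="male"), z.CallThresholds(), mouse)
        assert calls.calls["X"] == "neutral"
        assert calls.calls["Y"] == "loss"

    def test_calls_invariant_to_uniform_count_scaling(self, mouse, mouse_ref, rng):
        units = {n: 2 for n in mouse.female_names}
        units["3"] = 3
        props = z.proportions_from_units(units, mouse)
        prof = z.simulate_counts_from_proportions(
            props, z.NoiseModel(depth=100_000, rho=0.0), rng, sample_id="a"
        )
        scaled = z.CountProfile(
            "a5", "unknown", {n: 5 * c for n, c in prof.counts.items()},
            5 * prof.total_mapped,
        )
        th = z.CallThresholds()
        one = z.call_aneuploidy(
            z.predict_copy_number(prof, mouse_ref, "female", mouse), th, mouse
        )
        five = z.call_aneuploidy(
            z.predict_copy_number(scaled, mouse_ref, "female", mouse), th, mouse
        )
        assert one.calls == five.calls

    @given(
        devs=st.lists(
            st.floats(min_value=0.0, max_value=2.0, allow_nan=False),
            min_size=20, max_size=20,
        ),
        d1=st.floats(min_value=0.05, max_value=0.9),
        d2=st.floats(min_value=0.05, max_value=0.9),
    )
    @settings(max_examples=60, derandomize=True)
    def test_threshold_monotonicity(self, devs, d1, d2):
        genome = z.mouse_genome()
        lo, hi = sorted((d1, d2))
        cn = dict(zip(genome.female_names, devs))
        cnp = z.CopyNumberProfile("s", "female", {n: v / 2 for n, v in cn.items()}, cn)
        n_lo = z.call_aneuploidy(cnp, z.CallThresholds(lo), genome).n_aneuploid
        n_hi = z.call_aneuploidy(cnp, z.CallThresholds(hi), genome).n_aneuploid
        assert n_hi <= n_lo


class TestComplexity:
    @pytest.mark.parametrize(
        "n,expected",
        [(0, "euploid"), (1, "simple"), (2, "simple"), (3, "complex"), (7, "complex")],
    )
    def test_boundaries(self, n, expected):
        assert z.classify_complexity(n) == expected

    def test_rederivable_from_call_map(self, mouse):
        calls = {n: "neutral" for n in mouse.female_names}
        for n in ("1", "2", "3"):
            calls[n] = "gain"
        cs = z.AneuploidyCallSet("s", calls, 3, "complex")
        assert z.classify_complexity(cs) == "complex"

    def test_inconsistent_callset_rejected(self, mouse):
        calls = {n: "neutral" for n in mouse.female_names}
        with pytest.raises(ValueError):
            z.AneuploidyCallSet("s", calls, 1, "simple")


class TestRoundTrip:
    def test_true_status_recovered_at_high_depth(self, mouse, rng):
        """Karyotype -> deep noise-free counts -> CN -> calls recovers the true
        integer gain/loss status of every perturbed chromosome.

        Random zygote karyotypes carry up to three single-chromatid autosomal
        imbalances; larger distortions shift the proportion baseline itself
        and are outside the method's per-chromosome guarantee.
        """
        female = z.proportions_from_units(
            z.euploid_reference_units("female", mouse), mouse
        )
        male = z.proportions_from_units(
            z.euploid_reference_units("male", mouse), mouse
        )
        ref = z.ReferenceProfile(
            {"female": female, "male": male}, 1, 1, "sex_matched"
        )
        noise = z.NoiseModel(depth=10_000_000, rho=0.0)
        th = z.CallThresholds(0.2)
        autos = list(mouse.autosomes)
        for _ in range(1000):
            units = {n: 2 for n in mouse.female_names}
            sex = "female" if rng.random() < 0.5 else "male"
            if sex == "male":
                units["X"] = 1
                units["Y"] = 1
            k = int(rng.integers(0, 4))
            targets = rng.choice(len(autos), size=k, replace=False)
            for t in targets:
                units[autos[t]] += int(rng.choice([-1, 1]))
            props = z.proportions_from_units(units, mouse)
            prof = z.simulate_counts_from_proportions(props, noise, rng)
            cnp = z.predict_copy_number_from_proportions(
                prof.proportions, ref, sex, mouse
            )
            calls = z.call_aneuploidy(cnp, th, mouse)
            for n in autos:
                truth = (
                    "gain" if units[n] > 2 else ("loss" if units[n] < 2 else "neutral")
                )
                assert calls.calls[n] == truth
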