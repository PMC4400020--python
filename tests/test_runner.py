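"""Run orchestration: initialization, introduction, equilibrium detection,
determinism and the qualitative orderings of the fixation dynamics."""

import numpy as np
import pytest

import upievol as uv


def test_init_population_linked():
    cfg = uv.RunConfig(n=20, mu=1e-4, scenario=uv.build_linked(),
                       fitness=uv.FitnessSpec(0.2))
    g = uv.init_population(cfg)
    assert g.props["B1"][0] == 0.5
    assert g.props["B2"][0] == 0.5
    assert "U1" not in g.props
    assert g.total() == pytest.approx(1.0)


def test_init_population_no_mating_types():
    cfg = uv.RunConfig(n=8, mu=1e-4, scenario=uv.build_no_mating_types("biparental"),
                       fitness=uv.FitnessSpec(0.2))
    g = uv.init_population(cfg)
    assert g.props["B"][0] == 1.0


def test_config_validation():
    sc = uv.build_linked()
    fit = uv.FitnessSpec(0.2)
    with pytest.raises(ValueError):
        uv.RunConfig(n=21, mu=1e-4, scenario=sc, fitness=fit)
    with pytest.raises(ValueError):
        uv.RunConfig(n=20, mu=1e-4, scenario=sc, fitness=fit, intro_freq=0.7)
    with pytest.raises(ValueError):
        uv.RunConfig(n=20, mu=1e-4, scenario=sc, fitness=fit, eq_tol=0.0)
    # the tighter default tolerance kicks in only at mu = 1e-10
    assert uv.RunConfig(n=20, mu=1e-10, scenario=sc, fitness=fit).tol == 1e-13
    assert uv.RunConfig(n=20, mu=1e-7, scenario=sc, fitness=fit).tol == 1e-12


class TestStepGeneration:
    def test_all_wild_no_mutation_is_stationary(self):
        cfg = uv.RunConfig(n=8, mu=0.0, scenario=uv.build_linked(),
                           fitness=uv.FitnessSpec(0.2))
        g = uv.init_population(cfg)
        out, _ = uv.step_generation(g, cfg)
        for allele, v in g.props.items():
            np.testing.assert_allclose(out.props[allele], v, atol=1e-15)

    def test_b2_pinned_at_half(self, linked_small):
        g = uv.init_population(linked_small)
        g, _, _ = uv.run_to_equilibrium(g, linked_small)
        g = uv.introduce_upi(g, linked_small)
        for _ in range(5):
            g, _ = uv.step_generation(g, linked_small)
            assert g.allele_frequencies()["B2"] == pytest.approx(0.5, abs=1e-12)


class TestEquilibrium:
    def test_stationary_input_zero_generations(self):
        cfg = uv.RunConfig(n=8, mu=0.0, scenario=uv.build_linked(),
                           fitness=uv.FitnessSpec(0.2))
        g = uv.init_population(cfg)
        _, gens, converged = uv.run_to_equilibrium(g, cfg)
        assert gens == 0 and converged

    def test_burn_in_reaches_balance(self, linked_small):
        g = uv.init_population(linked_small)
        g, gens, converged = uv.run_to_equilibrium(g, linked_small)
        assert converged and gens > 0
        # heteroplasmic mass present at balance
        het = 1.0 - g.props["B1"][0] - g.props["B2"][0]
        assert het > 0
        # one more generation changes nothing beyond tolerance
        out, _ = uv.step_generation(g, linked_small)
        delta = np.max(np.abs(out.as_vector() - g.as_vector()))
        assert delta < linked_small.tol

    def test_max_generations_guard(self, linked_small):
        cfg = uv.RunConfig(
            n=8, mu=1e-3, scenario=uv.build_linked(),
            fitness=uv.FitnessSpec(0.2), eq_tol=1e-10, max_generations=3,
        )
        g = uv.init_population(cfg)
        _, gens, converged = uv.run_to_equilibrium(g, cfg)
        assert gens == 3 and not converged


class TestIntroduction:
    def test_default_placement(self, linked_small):
        g = uv.init_population(linked_small)
        g, _, _ = uv.run_to_equilibrium(g, linked_small)
        before = g.props["B1"][0]
        out = uv.introduce_upi(g, linked_small)
        assert out.props["U1"][0] == pytest.approx(0.01)
        assert out.props["B1"][0] == pytest.approx(before - 0.01)
        assert out.total() == pytest.approx(1.0, abs=1e-12)

    def test_zero_freq_identity(self, linked_small):
        cfg = uv.RunConfig(n=8, mu=1e-3, scenario=uv.build_linked(),
                           fitness=uv.FitnessSpec(0.2), intro_freq=0.0)
        g = uv.init_population(cfg)
        assert uv.introduce_upi(g, cfg) is g

    def test_heteroplasmic_placement_picks_highest_count(self):
        cfg = uv.RunConfig(
            n=8, mu=1e-3, scenario=uv.build_linked(),
            fitness=uv.FitnessSpec(0.2), intro_freq=1e-3,
            intro_placement="most_heteroplasmic_above_freq", eq_tol=1e-10,
        )
        g = uv.init_population(cfg)
        g, _, _ = uv.run_to_equilibrium(g, cfg)
        src = g.props["B1"]
        expected_idx = max(p for p in range(len(src)) if src[p] > cfg.intro_freq)
        out = uv.introduce_upi(g, cfg)
        assert out.props["U1"][expected_idx] == pytest.approx(cfg.intro_freq)

    def test_insufficient_mass_raises(self):
        g = uv.GameteDistribution(
            8,
            {"B1": np.array([0.005, 0, 0, 0, 0]), "B2": np.full(5, 0.199)},
        )
        cfg = uv.RunConfig(n=8, mu=1e-3, scenario=uv.build_linked(),
                           fitness=uv.FitnessSpec(0.2), intro_freq=0.01)
        with pytest.raises(ValueError, match="B1"):
            uv.introduce_upi(g, cfg)  # source state holds only 0.005

    def test_no_state_above_threshold_raises(self):
        cfg = uv.RunConfig(n=8, mu=1e-3, scenario=uv.build_linked(),
                           fitness=uv.FitnessSpec(0.2), intro_freq=0.2,
                           intro_placement="most_heteroplasmic_above_freq")
        g = uv.GameteDistribution(
            8,
            {"B1": np.full(5, 0.1), "B2": np.array([0.5, 0, 0, 0, 0])},
        )
        with pytest.raises(ValueError, match="cannot place"):
            uv.introduce_upi(g, cfg)


class TestUpiFrequency:
    def test_pure_biparental_is_zero(self):
        sc = uv.build_linked()
        d = uv.DiploidDistribution(4, {"B1B2": np.array([1.0, 0, 0, 0, 0])})
        assert uv.upi_frequency(d, sc) == 0.0

    def test_pure_uniparental_is_one(self):
        sc = uv.build_linked()
        d = uv.DiploidDistribution(4, {"U1B2": np.array([1.0, 0, 0, 0, 0])})
        assert uv.upi_frequency(d, sc) == 1.0

    def test_didymium_weights_by_leak(self):
        sc = uv.build_didymium(0.4, 0.3, 0.3)
        d = uv.DiploidDistribution(4, {"U1U2": np.array([1.0, 0, 0, 0, 0])})
        assert uv.upi_frequency(d, sc) == pytest.approx(0.7)


class TestSimulate:
    def test_deterministic_traces(self, linked_small):
        a = uv.simulate(linked_small)
        b = uv.simulate(linked_small)
        assert a.trace.equals(b.trace)
        assert a.equilibrium_allele_freqs == b.equilibrium_allele_freqs

    def test_uniparental_allele_fixes(self, linked_small):
        s = uv.simulate(linked_small)
        assert s.fixation
        assert s.equilibrium_genotype_freqs["U1B2"] > 1 - 1e-6
        assert s.equilibrium_upi_frequency == pytest.approx(1.0, abs=1e-6)
        assert s.equilibrium_allele_freqs["B2"] == pytest.approx(0.5, abs=1e-9)

    def test_trace_generations_start_at_introduction(self, linked_small):
        s = uv.simulate(linked_small)
        main = s.trace[s.trace.phase == "main"]
        assert main.generation.min() == 0
        assert s.generations_to_first_equilibrium > 0


def _gens_until(cfg, threshold=0.99, genotype="U1B2"):
    """Generations after introduction until ``genotype`` passes ``threshold``
    (cheaper than running out the full equilibrium tail)."""
    from upievol.runner import _Engine

    g = uv.init_population(cfg)
    g, _, _ = uv.run_to_equilibrium(g, cfg)
    g = uv.introduce_upi(g, cfg)
    engine = _Engine(cfg)
    A = engine.state_from(g)
    gi = cfg.scenario.genotypes.index(genotype)
    for t in range(cfg.max_generations):
        A, D2, _ = engine.step(A)
        if D2[gi].sum() > threshold:
            return t
    raise AssertionError("no replacement")


def _generations_to_replacement(n, mu, threshold=0.99):
    cfg = uv.RunConfig(n=n, mu=mu, scenario=uv.build_linked(),
                       fitness=uv.FitnessSpec(0.2, "concave"))
    return _gens_until(cfg, threshold)


@pytest.mark.parametrize(
    "scenario, fitness",
    [
        (uv.build_linked(), uv.FitnessSpec(0.2, "concave")),
        (
            uv.build_recombination(0.3, "mixture", 0.2),
            uv.FitnessSpec(0.5, "linear", "deleterious", 0.05),
        ),
        (uv.build_no_mating_types("mixture", 0.4), uv.FitnessSpec(0.9, "convex")),
        (uv.build_mitosis(4, "midway"), uv.FitnessSpec(0.2, "concave")),
        (uv.build_didymium(0.3, 0.4, 0.3), uv.FitnessSpec(0.1, "linear")),
    ],
    ids=["linked", "recombination", "no-mating-types", "mitosis-midway", "didymium"],
)
def test_engine_matches_stage_composition(scenario, fitness):
    """The precompiled iteration engine and the public stage functions give
    the same generation update, for every scenario family."""
    from upievol.runner import _Engine

    cfg = uv.RunConfig(n=8, mu=1e-3, scenario=scenario, fitness=fitness)
    rng = np.random.default_rng(1)
    props = {g: rng.random(5) for g in scenario.alleles}
    tot = sum(v.sum() for v in props.values())
    g = uv.GameteDistribution(8, {k: v / tot for k, v in props.items()})
    ref, ref_diag = uv.step_generation(g, cfg)
    engine = _Engine(cfg)
    A2, D2, diag = engine.step(engine.state_from(g), want_diag=True)
    out = engine.gametes_from(A2)
    for allele in scenario.alleles:
        np.testing.assert_allclose(out.props[allele], ref.props[allele], atol=1e-15)
    assert diag["upi_frequency"] == pytest.approx(ref_diag["upi_frequency"], abs=1e-14)
    for G in scenario.genotypes:
        assert diag["genotype_freqs"][G] == pytest.approx(
            ref_diag["genotype_freqs"][G], abs=1e-14
        )
        assert diag["mean_fitness"][G] == pytest.approx(
            ref_diag["mean_fitness"][G], abs=1e-12
        )


class TestFixationOrderings:
    def test_slower_with_more_mitochondria(self):
        assert _generations_to_replacement(50, 1e-4) > _generations_to_replacement(20, 1e-4)

    def test_slower_with_lower_mutation_rate(self):
        assert _generations_to_replacement(20, 1e-7) > _generations_to_replacement(20, 1e-4)

    def test_heteroplasmic_introduction_is_faster(self):
        def gens(placement):
            cfg = uv.RunConfig(
                n=20, mu=1e-4, scenario=uv.build_linked(),
                fitness=uv.FitnessSpec(0.2, "concave"), intro_placement=placement,
            )
            return _gens_until(cfg)

        assert gens("most_heteroplasmic_above_freq") < gens("homoplasmic_wild")

    def test_lower_introduction_frequency_takes_longer(self):
        def gens(freq):
            cfg = uv.RunConfig(
                n=8, mu=1e-3, scenario=uv.build_linked(),
                fitness=uv.FitnessSpec(0.2, "concave"), intro_freq=freq,
            )
            return _gens_until(cfg, threshold=0.9)

        assert gens(1e-3) > gens(1e-2)

    def test_deleterious_mutations_slow_the_spread(self):
        """With deleterious mutant haplotypes (back-mutation at mu/100) the
        uniparental allele still spreads, but more slowly than when the
        haplotypes are neutral."""
        neutral = uv.RunConfig(n=8, mu=1e-5, scenario=uv.build_linked(),
                               fitness=uv.FitnessSpec(0.2, "concave"))
        delet = uv.RunConfig(
            n=8, mu=1e-5, mu_b=1e-7, scenario=uv.build_linked(),
            fitness=uv.FitnessSpec(0.2, "concave", "deleterious", 0.05, "concave"),
        )
        assert _gens_until(delet, 0.9) > _gens_until(neutral, 0.9)

    def test_mildly_advantageous_mutations_speed_the_spread(self):
        """Mildly advantageous mutant haplotypes (back-mutation at 100 mu)
        accelerate the spread: mutant-carrying gametes gain a fitness edge
        and homoplasmic-mutant partners appear sooner."""
        neutral = uv.RunConfig(n=8, mu=1e-5, scenario=uv.build_linked(),
                               fitness=uv.FitnessSpec(0.2, "concave"))
        adv = uv.RunConfig(
            n=8, mu=1e-5, mu_b=1e-3, scenario=uv.build_linked(),
            fitness=uv.FitnessSpec(0.2, "concave", "advantageous", 0.01, "concave"),
        )
        assert _gens_until(adv, 0.9) < _gens_until(neutral, 0.9)

    def test_insufficient_mitosis_slows_but_does_not_stop_spread(self):
        """A few mitotic divisions before selection leave enough residual
        heteroplasmy for the uniparental allele to keep its advantage: it
        still replaces the biparental allele, just more slowly."""
        plain = uv.RunConfig(n=8, mu=1e-3, scenario=uv.build_linked(),
                             fitness=uv.FitnessSpec(0.2, "concave"))
        mito = uv.RunConfig(n=8, mu=1e-3, scenario=uv.build_mitosis(2),
                            fitness=uv.FitnessSpec(0.2, "concave"))
        assert _gens_until(mito, 0.9) > _gens_until(plain, 0.9)
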