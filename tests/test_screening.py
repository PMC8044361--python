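"""Genome decoding, objectives, post-filters and reporting."""

import numpy as np
import pytest

from dfmscreen.errors import DfmError
from dfmscreen.model_io import ProblemDefinition
from dfmscreen.screening import (
    FilterConfig,
    Solution,
    TherapyProblem,
    decode,
    evaluate,
    filter_solutions,
    parse_perturbation,
    render_perturbation,
    report,
    solve,
)
from dfmscreen.synthetic import PlantedSpec, make_planted_dfm


@pytest.fixture(scope="module")
def pair_problem():
    """Planted pair {Target0 high, Target1 low}, effects 0.5 each."""
    _, definition = make_planted_dfm(
        PlantedSpec(d=4, planted={0: 2, 1: 1}, effects={0: 0.5, 1: 0.5})
    )
    return TherapyProblem(definition)


@pytest.fixture(scope="module")
def trio_problem_3obj():
    _, definition = make_planted_dfm(
        PlantedSpec(
            d=4,
            planted={0: 2, 2: 1},
            effects={0: 0.6, 2: 0.5},
            necrosis_effects={(1, 2): 0.4, (0, 2): 0.2},
            objectives="3obj",
        )
    )
    return TherapyProblem(definition)


class TestDecode:
    def test_zero_genome_decodes_to_nothing(self, pair_problem):
        assert len(decode((0, 0, 0, 0), pair_problem)) == 0

    def test_single_symbol_forces_setpoint_over_whole_run(self, pair_problem):
        pi = decode((0, 1, 0, 0), pair_problem)
        (p,) = tuple(pi)
        assert p.variable == "Target1"
        assert p.t_begin == 0
        assert p.t_end == pair_problem.model.t_max
        assert p.function(0) == 0.0  # low setpoint

    def test_symbol_two_forces_high_setpoint(self, pair_problem):
        (p,) = tuple(decode((2, 0, 0, 0), pair_problem))
        assert p.variable == "Target0"
        assert p.function(5) == 1.0

    def test_three_symbols_give_three_perturbations(self, pair_problem):
        assert len(decode((1, 2, 1, 0), pair_problem)) == 3

    def test_bad_symbol_rejected(self, pair_problem):
        with pytest.raises(DfmError, match="symbol"):
            decode((0, 0, 3, 0), pair_problem)

    def test_length_mismatch_rejected(self, pair_problem):
        with pytest.raises(DfmError, match="length"):
            decode((0, 0), pair_problem)


def planted_oracle(spec: PlantedSpec, genome):
    """Closed-form objective values of the planted construction, computed
    independently of the simulation engine."""
    forced = {i: s for i, s in enumerate(genome) if s != 0}
    hits = [i for i, s in spec.planted.items() if forced.get(i) == s]
    full = len(hits) == len(spec.planted)
    conj = spec.epistasis or len(spec.planted) >= 2
    num = den = 0.0
    if not spec.epistasis:
        num += sum(spec.effects[i] for i in hits)
        den += len(hits)
    if conj and full:
        num += min(1.0, sum(spec.effects.values()))
        den += 1
    apo = num / den if den else 0.0
    nec_hits = [e for (i, s), e in spec.necrosis_effects.items() if forced.get(i) == s]
    nec = sum(nec_hits) / len(nec_hits) if nec_hits else 0.0
    return apo, nec, len(forced)


class TestObjectives:
    def test_zero_genome_is_neutral(self, pair_problem):
        assert evaluate((0, 0, 0, 0), pair_problem) == (0.0, 0.0)

    def test_complexity_counts_nonzero_positions(self, pair_problem):
        fit = evaluate((1, 0, 2, 0), pair_problem)
        assert fit[-1] == 2.0

    def test_single_planted_effect_is_exact(self):
        _, definition = make_planted_dfm(
            PlantedSpec(d=3, planted={0: 2}, effects={0: 0.8})
        )
        problem = TherapyProblem(definition)
        sol = solve((2, 0, 0), problem)
        assert sol.apoptosis_change == pytest.approx(0.8)
        assert sol.complexity == 1

    def test_apoptosis_is_negated_for_minimization(self, pair_problem):
        fit = evaluate((2, 1, 0, 0), pair_problem)
        sol = solve((2, 1, 0, 0), pair_problem)
        assert fit[0] == -sol.apoptosis_change
        assert sol.apoptosis_change > 0

    def test_every_genome_matches_closed_form_oracle(self):
        """Exhaustive check of the simulated objectives against independent
        closed-form arithmetic, over all 81 genomes of a 3-objective planted
        problem with unequal effects."""
        spec = PlantedSpec(
            d=4,
            planted={0: 2, 2: 1},
            effects={0: 0.6, 2: 0.5},
            necrosis_effects={(1, 2): 0.4, (0, 2): 0.2},
            objectives="3obj",
        )
        _, definition = make_planted_dfm(spec)
        problem = TherapyProblem(definition)
        import itertools

        for genome in itertools.product(range(3), repeat=4):
            sol = solve(genome, problem)
            apo, nec, com = planted_oracle(spec, genome)
            assert sol.apoptosis_change == pytest.approx(apo), genome
            assert sol.necrosis_change == pytest.approx(nec), genome
            assert sol.complexity == com

    def test_condition_binding_pins_input(self):
        model, definition = make_planted_dfm(
            PlantedSpec(d=3, planted={0: 2}, effects={0: 0.5})
        )
        from dataclasses import replace

        bound = replace(definition, condition={"Stimulus": "low"})
        problem = TherapyProblem(bound)
        from dfmscreen.engine import simulate

        traj = simulate(problem.model)
        assert np.all(traj["Stimulus"] == 0.0)

    def test_condition_binding_on_non_input_rejected(self):
        model, definition = make_planted_dfm(
            PlantedSpec(d=3, planted={0: 2}, effects={0: 0.5})
        )
        from dataclasses import replace

        with pytest.raises(DfmError, match="non-input"):
            TherapyProblem(replace(definition, condition={"Target0": "low"}))


class TestRendering:
    def test_treatment_string_style(self):
        names = ("Attachment", "Bcl2", "Ca2+", "ERK")
        assert render_perturbation((0, 1, 2, 0), names) == "Bcl2 IS low, Ca2+ IS high"
        assert render_perturbation((0, 0, 0, 0), names) == ""

    @pytest.mark.parametrize("genome", [(0, 0, 0, 0), (1, 0, 0, 0), (0, 1, 2, 1), (2, 2, 2, 2)])
    def test_render_parse_round_trip(self, genome):
        names = ("Attachment", "Bcl2", "Ca2+", "ERK")
        assert parse_perturbation(render_perturbation(genome, names), names) == genome

    def test_parse_unknown_variable_rejected(self):
        with pytest.raises(DfmError, match="unknown perturbable"):
            parse_perturbation("Ghost IS low", ("A", "B"))


def apply_predicates(sol, problem, config):
    """Independent predicate-by-predicate filter oracle."""
    names = problem.definition.perturbable
    targets = [(names[i], {1: "low", 2: "high"}[s]) for i, s in enumerate(sol.genome) if s]
    ok = True
    if config.max_elements is not None:
        ok &= sol.complexity <= config.max_elements
    if config.min_elements is not None:
        ok &= sol.complexity >= config.min_elements
    if config.no_same_pathway_or_adjacent:
        model = problem.model
        vs = [v for v, _ in targets]
        edges = {frozenset((a, b)) for a, b, _ in model.graph_edges}
        for i in range(len(vs)):
            for j in range(i + 1, len(vs)):
                same_pw = model.variable(vs[i]).pathway == model.variable(vs[j]).pathway
                adjacent = frozenset((vs[i], vs[j])) in edges
                ok &= not (same_pw or adjacent)
    ok &= not any(t in set(config.forbidden) for t in targets)
    if config.tau_nec is not None:
        ok &= sol.necrosis_change <= config.tau_nec
    return ok


class TestFilters:
    def _solutions(self, problem):
        import itertools

        sols = []
        for genome in itertools.product(range(3), repeat=problem.genome_length):
            sols.append(solve(genome, problem))
        return sols

    def test_more_than_three_elements_rejected(self, pair_problem):
        sol = solve((1, 1, 1, 1), pair_problem)
        kept, rejected = filter_solutions([sol], pair_problem, FilterConfig(max_elements=3))
        assert kept == []
        assert rejected[0].failed_filter == "max_elements"

    def test_singleton_rejected_under_three_objective_filters(self, trio_problem_3obj):
        sol = solve((2, 0, 0, 0), trio_problem_3obj)
        config = FilterConfig.for_objectives("3obj")
        kept, rejected = filter_solutions([sol], trio_problem_3obj, config)
        assert kept == []
        assert rejected[0].failed_filter == "min_elements"

    def test_forbidden_forcings_rejected(self, trio_problem_3obj):
        config = FilterConfig(
            max_elements=3, forbidden=(("Target1", "high"),), min_elements=None
        )
        sol = solve((2, 2, 1, 0), trio_problem_3obj)
        kept, rejected = filter_solutions([sol], trio_problem_3obj, config)
        assert rejected[0].failed_filter == "forbidden_perturbation"

    def test_high_necrosis_rejected(self, trio_problem_3obj):
        config = FilterConfig(max_elements=3, tau_nec=0.25)
        sol = solve((0, 2, 0, 0), trio_problem_3obj)  # necrosis 0.4
        kept, rejected = filter_solutions([sol], trio_problem_3obj, config)
        assert rejected[0].failed_filter == "high_necrosis"

    def test_adjacent_pair_rejected(self, trio_problem_3obj):
        """Planted model wires every target into Apoptosis; make two targets
        adjacent by adding a direct edge and check the pair is filtered."""
        from dataclasses import replace as dreplace

        model = trio_problem_3obj.model
        model2 = dreplace(
            model, graph_edges=model.graph_edges + (("Target0", "Target2", "positive"),)
        )
        definition = dreplace(trio_problem_3obj.definition, model=model2)
        problem = TherapyProblem(definition)
        config = FilterConfig(max_elements=3, no_same_pathway_or_adjacent=True)
        sol = solve((2, 0, 1, 0), problem)
        kept, rejected = filter_solutions([sol], problem, config)
        assert rejected[0].failed_filter == "adjacent"

    def test_kept_set_matches_predicate_oracle(self, trio_problem_3obj):
        config = FilterConfig.for_objectives("3obj")
        # replace ROS/Src defaults with forcings this toy model can express
        config = FilterConfig(
            max_elements=3,
            min_elements=2,
            no_same_pathway_or_adjacent=True,
            forbidden=(("Target1", "high"), ("Target3", "high")),
            tau_nec=0.25,
        )
        sols = self._solutions(trio_problem_3obj)
        kept, rejected = filter_solutions(sols, trio_problem_3obj, config)
        expected = {
            s.genome for s in sols if apply_predicates(s, trio_problem_3obj, config)
        }
        assert {s.genome for s in kept} == expected
        assert all(s.failed_filter for s in rejected)

    def test_duplicates_removed_before_filtering(self, pair_problem):
        sol = solve((2, 1, 0, 0), pair_problem)
        kept, rejected = filter_solutions([sol, sol, sol], pair_problem, FilterConfig())
        assert len(kept) == 1 and rejected == []

    def test_pathway_filter_without_labels_is_config_error(self):
        _, definition = make_planted_dfm(PlantedSpec(d=3, planted={0: 2}, effects={0: 0.5}))
        problem = TherapyProblem(definition)
        from dataclasses import replace as dreplace
        from dfmscreen.fuzzy import LinguisticVariable

        stripped = tuple(
            dreplace(v, pathway=None) for v in problem.model.variables
        )
        model2 = dreplace(problem.model, variables=stripped)
        problem2 = TherapyProblem(dreplace(definition, model=model2))
        sol = solve((2, 1, 0), problem2)
        with pytest.raises(DfmError, match="pathway"):
            filter_solutions([sol], problem2, FilterConfig(no_same_pathway_or_adjacent=True))


class TestReport:
    def test_artifacts_written_and_parseable(self, pair_problem, tmp_path):
        kept = [solve((2, 1, 0, 0), pair_problem), solve((2, 0, 0, 0), pair_problem)]
        manifest = {"seed": 1, "n_evaluations": 42}
        paths = report(kept, pair_problem, manifest, tmp_path)
        import json

        import pandas as pd

        frame = pd.read_csv(paths["csv"])
        assert list(frame["perturbation"])[0] == "Target0 IS high, Target1 IS low"
        assert json.loads(paths["manifest"].read_text())["n_evaluations"] == 42

    def test_empty_kept_set_valid_table(self, pair_problem, tmp_path):
        paths = report([], pair_problem, {}, tmp_path)
        import pandas as pd

        frame = pd.read_csv(paths["csv"])
        assert len(frame) == 0
        assert "perturbation" in frame.columns

    def test_rendered_strings_round_trip_through_csv(self, pair_problem, tmp_path):
        kept = [solve((0, 1, 2, 0), pair_problem)]
        paths = report(kept, pair_problem, {}, tmp_path)
        import pandas as pd

        frame = pd.read_csv(paths["csv"])
        names = pair_problem.definition.perturbable
        assert parse_perturbation(frame["perturbation"][0], names) == (0, 1, 2, 0)
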