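import random

import pytest

from semmerge import (
    Resolution,
    dependency_graph,
    find_overlaps,
    merge,
    prune,
    resolution_from_file,
    simulate,
    validate_model,
)
from semmerge.errors import MergeError
from semmerge import fixtures as fx
from semmerge.units import commensurable

from conftest import trajectories_close


def _all_ignore(report):
    return [Resolution(it, "keep_left" if it.kind == "solution_domain" else "ignore")
            for it in report.items]


def _keep_count(resolutions):
    return sum(1 for r in resolutions if r.choice != "ignore")


class TestMergeBookkeeping:
    def test_resolved_fixture_merge_count(self, suite):
        result = fx.merge_excitation_calcium(suite)
        n_keep = sum(1 for entry in result.log if entry["action"] == "resolve")
        assert n_keep == 6  # domain + calcium + current + volume + Faraday + voltage
        assert len(result.merged.variables) == \
            len(suite.E.variables) + len(suite.C_prime.variables) - n_keep
        assert validate_model(result.merged) == []

    def test_all_ignore_count(self, suite):
        report = find_overlaps(suite.E, suite.C_prime)
        result = merge(suite.E, suite.C_prime, _all_ignore(report))
        assert len(result.merged.variables) == \
            len(suite.E.variables) + len(suite.C_prime.variables) - 1

    def test_random_merges_obey_count_invariant(self):
        rng = random.Random(42)
        for _ in range(25):
            a = fx.random_annotated_model(rng.randrange(4, 40), rng.randrange(2**31))
            b = fx.random_annotated_model(rng.randrange(4, 40), rng.randrange(2**31))
            report = find_overlaps(a, b)
            resolutions = []
            for it in report.items:
                if it.kind == "solution_domain":
                    resolutions.append(Resolution(it, "keep_left"))
                elif it.conversion_factor is None:
                    resolutions.append(Resolution(it, "ignore"))
                else:
                    resolutions.append(Resolution(it, rng.choice(["keep_left", "keep_right", "ignore"])))
            result = merge(a, b, resolutions)
            expected = len(a.variables) + len(b.variables) - _keep_count(resolutions)
            assert len(result.merged.variables) == expected
            assert validate_model(result.merged) == []


class TestMergeSemantics:
    def test_volume_substitution_uses_exact_factor(self, suite):
        merged = fx.merge_excitation_calcium(suite).merged
        glue = merged.get("i_b_Ca_C")
        from semmerge.expr import to_string
        rendered = to_string(glue.expr)
        assert "Vol_C" not in rendered
        assert "1000000000.0 * Vol_myo_E" in rendered

    def test_discarded_calcium_equation_gone_and_coupling_live(self, suite):
        merged = fx.merge_excitation_calcium(suite).merged
        assert not merged.has("Ca_i_E")
        # E-side Nernst potential now reads the calcium model's state
        base = simulate(merged, 0.0, 1.0, 0.001)
        perturbed_suite = fx.generate_suite({"C.k_b_C": 0.03})
        pert = simulate(fx.merge_excitation_calcium(perturbed_suite).merged, 0.0, 1.0, 0.001)
        dev = max(abs(x - y) for x, y in zip(base.column("E_Ca"), pert.column("E_Ca")))
        assert dev > 1e-3

    def test_name_collision_disambiguated_with_model_suffix(self, suite):
        result = fx.merge_excitation_calcium(suite)
        renames = [e for e in result.log if e["action"] == "rename"]
        assert renames == [{"action": "rename", "old": "Ca_rest", "new": "Ca_rest__C_prime"}]
        assert result.merged.has("Ca_rest") and result.merged.has("Ca_rest__C_prime")

    def test_incommensurable_keep_rejected_pre_glue(self, suite):
        """Pairing a nanoamp current with a mM/s flux must be fixed by glue, not by a keep."""
        report = find_overlaps(suite.E, suite.C)
        report = __import__("semmerge").add_manual_mapping(report, "i_b_Ca", "J_b_Ca")
        item = report.find("i_b_Ca", "J_b_Ca")
        assert not commensurable(suite.E.unit_of("i_b_Ca"), suite.C.unit_of("J_b_Ca"))
        resolutions = _all_ignore(find_overlaps(suite.E, suite.C)) + [Resolution(item, "keep_left")]
        with pytest.raises(MergeError, match="incommensurable"):
            merge(suite.E, suite.C, resolutions)

    def test_unresolved_solution_domain_rejected(self, suite):
        report = find_overlaps(suite.E, suite.C_prime)
        resolutions = [Resolution(it, "ignore") for it in report.items]
        with pytest.raises(MergeError, match="solution-domain"):
            merge(suite.E, suite.C_prime, resolutions)

    def test_non_interference_of_all_ignore_merge(self, suite):
        report = find_overlaps(suite.E, suite.C_prime)
        result = merge(suite.E, suite.C_prime, _all_ignore(report))
        renames = {e["old"]: e["new"] for e in result.log if e["action"] == "rename"}
        merged_traj = simulate(result.merged, 0.0, 2.0, 0.001)
        for source in (suite.E, suite.C_prime):
            solo = simulate(source, 0.0, 2.0, 0.001)
            names = [v.name for v in source.variables
                     if v.role not in ("constant", "solution_domain")]
            trajectories_close(solo, merged_traj, names, rel=1e-6, rename=renames)


class TestPrune:
    def test_terminal_branch_removed_without_trajectory_change(self, suite):
        merged = fx.merge_with_tension(suite).merged
        outputs = ["tension", "V_m", "Ca_i_C"]
        pruned = prune(merged, outputs)
        removed = {v.name for v in merged.variables} - {v.name for v in pruned.variables}
        assert {"Ca_SR_E", "J_up_E"} <= removed  # the vestigial SR branch
        assert len(pruned.variables) < len(merged.variables)
        full_traj = simulate(merged, 0.0, 2.0, 0.001)
        pruned_traj = simulate(pruned, 0.0, 2.0, 0.001)
        names = [v.name for v in pruned.variables if v.role not in ("constant", "solution_domain")]
        trajectories_close(full_traj, pruned_traj, names, abs_tol=1e-9)

    def test_pruned_branch_has_no_path_to_outputs(self, suite):
        merged = fx.merge_with_tension(suite).merged
        import networkx as nx
        g = dependency_graph(merged)
        assert not nx.has_path(g, "Ca_SR_E", "tension")

    def test_keep_everything_is_identity(self, decay_model):
        assert prune(decay_model, ["x", "k"]) == decay_model

    def test_all_feed_output_is_identity(self, decay_model):
        assert prune(decay_model, ["x"]) == decay_model

    def test_unknown_output_rejected(self, decay_model):
        with pytest.raises(MergeError, match="unknown output"):
            prune(decay_model, ["ghost"])


class TestResolutionFromFile:
    def test_empty_decisions_defaults(self, suite):
        report = find_overlaps(suite.E, suite.C_prime)
        resolutions = resolution_from_file(report, [])
        by_pair = {r.item.pair(): r.choice for r in resolutions}
        assert by_pair[("t", "time")] == "keep_left"
        assert all(choice == "ignore" for pair, choice in by_pair.items() if pair != ("t", "time"))

    def test_decisions_by_concept_label(self, suite):
        report = find_overlaps(suite.E, suite.C_prime)
        label = report.find("Ca_i_E", "Ca_i_C").concept
        resolutions = resolution_from_file(report, [{"concept": label, "choice": "keep_right"}])
        assert {r.item.pair(): r.choice for r in resolutions}[("Ca_i_E", "Ca_i_C")] == "keep_right"

    def test_decisions_by_pair(self, suite):
        report = find_overlaps(suite.E, suite.C_prime)
        resolutions = resolution_from_file(
            report, [{"left_var": "Vol_myo_E", "right_var": "Vol_C", "choice": "keep_left"}])
        assert {r.item.pair(): r.choice for r in resolutions}[("Vol_myo_E", "Vol_C")] == "keep_left"

    def test_duplicate_decision_rejected(self, suite):
        report = find_overlaps(suite.E, suite.C_prime)
        label = report.find("Ca_i_E", "Ca_i_C").concept
        with pytest.raises(MergeError, match="duplicate"):
            resolution_from_file(report, [
                {"concept": label, "choice": "keep_left"},
                {"left_var": "Ca_i_E", "right_var": "Ca_i_C", "choice": "keep_right"},
            ])

    def test_unknown_reference_rejected(self, suite):
        report = find_overlaps(suite.E, suite.C_prime)
        with pytest.raises(MergeError, match="unknown"):
            resolution_from_file(report, [{"concept": "no such concept", "choice": "ignore"}])
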