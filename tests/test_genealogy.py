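"""Ascendant-tree tracing, merging, sampling and selective omission."""

import numpy as np
import pandas as pd
import pytest

from lineagebias.engine import FEMALE, OPEN
from lineagebias.genealogy import (
    ExperimentConfig,
    GenealogicalSubset,
    add_ancestor_offspring,
    eligible_for_omission,
    merge_trees,
    omit_individuals,
    sample_genealogists,
    trace_ancestor_trees,
    trace_direct_ancestors,
)

from conftest import make_registry, y


def brute_force_ancestors(reg, ego, max_gen):
    """Independent recursive enumeration of occupied pedigree positions."""
    out = []

    def walk(pid, gen):
        if gen >= max_gen:
            return
        for parent in (reg.mother_pid[pid - 1], reg.father_pid[pid - 1]):
            if parent > 0:
                out.append((int(parent), gen + 1))
                walk(int(parent), gen + 1)

    walk(ego, 0)
    return sorted(out)


def complete_pedigree_registry(generations=9):
    """Ego plus a fully occupied pedigree: 2^g ancestors per generation."""
    rows = [("f", y(2000), None, 0, 0)]  # ego, parents patched below
    parents_of = {}
    level = [1]
    pid = 1
    for g in range(1, generations + 1):
        nxt = []
        for child in level:
            pid += 1
            mother = pid
            rows.append(("f", y(2000 - 30 * g), y(2000 - 30 * g + 70 * 12), 0, 0))
            pid += 1
            father = pid
            rows.append(("m", y(2000 - 30 * g - 2), y(2000 - 30 * g + 68 * 12), 0, 0))
            parents_of[child] = (mother, father)
            nxt += [mother, father]
        level = nxt
    reg_rows = []
    for i, row in enumerate(rows, start=1):
        mother, father = parents_of.get(i, (0, 0))
        reg_rows.append((row[0], row[1], row[2], mother, father))
    return make_registry(reg_rows, span=(y(1500), y(2100)), end_year=2022)


class TestTracing:
    def test_orphan_ego_attributes_only_itself(self, toy_registry):
        sub = trace_direct_ancestors(toy_registry, 9)
        assert list(sub.member_set) == [9]
        assert list(sub.attributions.kin_type) == ["ego"]

    def test_matches_brute_force_closure(self, toy_registry):
        sub = trace_direct_ancestors(toy_registry, 7)
        got = sorted(
            (int(p), int(g))
            for p, g in sub.attributions.query("kin_type == 'direct_ancestor'")
            [["member_pid", "generation"]].itertuples(index=False))
        assert got == brute_force_ancestors(toy_registry, 7, 9)

    def test_matches_brute_force_on_simulated_registry(self, sim_registry):
        rng = np.random.default_rng(0)
        alive = sim_registry.pids[sim_registry.alive_at(1900 * 12)]
        for ego in rng.choice(alive, size=5, replace=False):
            sub = trace_direct_ancestors(sim_registry, int(ego), 9)
            got = sorted(
                (int(p), int(g))
                for p, g in sub.attributions.query("kin_type == 'direct_ancestor'")
                [["member_pid", "generation"]].itertuples(index=False))
            assert got == brute_force_ancestors(sim_registry, int(ego), 9)

    def test_complete_pedigree_yields_1022_positions(self):
        reg = complete_pedigree_registry(9)
        sub = trace_direct_ancestors(reg, 1, max_generations=9)
        anc = sub.attributions.query("kin_type == 'direct_ancestor'")
        assert len(anc) == 1022  # sum of 2^g for g = 1..9
        assert anc.generation.value_counts().sort_index().tolist() == \
            [2 ** g for g in range(1, 10)]

    def test_generation_cap_respected(self):
        reg = complete_pedigree_registry(4)
        sub = trace_direct_ancestors(reg, 1, max_generations=2)
        anc = sub.attributions.query("kin_type == 'direct_ancestor'")
        assert len(anc) == 6  # 2 + 4


class TestAncestorOffspring:
    def test_siblings_enter_with_parent_generation(self, toy_registry):
        sub = trace_direct_ancestors(toy_registry, 7)
        full = add_ancestor_offspring(sub, toy_registry)
        off = full.attributions.query("kin_type == 'ancestor_offspring'")
        # mother (pid 3) has children 7 and 8 -> sibling 8 enters at gen 1;
        # grandma (1) has children 3, 4, 5 -> aunt 4 and uncle 5 at gen 2
        assert 8 in off.query("generation == 1").member_pid.tolist()
        assert {4, 5} <= set(off.query("generation == 2").member_pid)

    def test_input_members_subset_of_output(self, sim_registry):
        egos = sim_registry.pids[sim_registry.alive_at(1900 * 12)][:50]
        sub = trace_ancestor_trees(sim_registry, egos)
        full = add_ancestor_offspring(sub, sim_registry)
        assert set(sub.member_set) <= set(full.member_set)

    def test_single_child_lineages_add_no_members(self):
        reg = complete_pedigree_registry(3)
        sub = trace_direct_ancestors(reg, 1)
        full = add_ancestor_offspring(sub, reg)
        assert set(full.member_set) == set(sub.member_set)

    def test_offspring_generation_restriction(self, toy_registry):
        sub = trace_direct_ancestors(toy_registry, 7)
        only_sibs = add_ancestor_offspring(sub, toy_registry,
                                           max_offspring_generation=1)
        off = only_sibs.attributions.query("kin_type == 'ancestor_offspring'")
        assert set(off.generation) == {1}


class TestMerging:
    def test_self_merge_doubles_attributions_not_members(self, toy_registry):
        sub = trace_direct_ancestors(toy_registry, 7)
        merged = merge_trees([sub, sub])
        assert len(merged.attributions) == 2 * len(sub.attributions)
        assert np.array_equal(merged.member_set, sub.member_set)

    def test_sibling_genealogists_share_ancestors(self, toy_registry):
        t7 = trace_direct_ancestors(toy_registry, 7)
        t8 = trace_direct_ancestors(toy_registry, 8)
        merged = merge_trees([t7, t8])
        pids, counts = merged.attribution_counts()
        assert dict(zip(pids, counts))[3] == 2  # shared mother, one per tree
        assert (merged.attributions.member_pid == 3).sum() == 2

    def test_merge_order_insensitive_on_members(self, toy_registry):
        t7 = trace_direct_ancestors(toy_registry, 7)
        t9 = trace_direct_ancestors(toy_registry, 9)
        a = merge_trees([t7, t9]).member_set
        b = merge_trees([t9, t7]).member_set
        assert np.array_equal(a, b)

    def test_disjoint_trees_add_counts(self, toy_registry):
        t6 = trace_direct_ancestors(toy_registry, 6)
        t9 = trace_direct_ancestors(toy_registry, 9)
        merged = merge_trees([t6, t9])
        assert len(merged.attributions) == len(t6.attributions) + len(t9.attributions)
        assert len(merged.member_set) == len(t6.member_set) + len(t9.member_set)

    def test_cross_registry_merge_rejected(self, toy_registry):
        other = complete_pedigree_registry(2)
        with pytest.raises(ValueError, match="different registries"):
            merge_trees([trace_direct_ancestors(toy_registry, 7),
                         trace_direct_ancestors(other, 1)])

    def test_dedup_idempotent(self, toy_registry):
        merged = merge_trees([trace_direct_ancestors(toy_registry, 7),
                              trace_direct_ancestors(toy_registry, 8)])
        once = merged.dedup()
        twice = once.dedup()
        pd.testing.assert_frame_equal(once.attributions, twice.attributions)


class TestSampling:
    def test_fraction_one_returns_all_eligible(self, sim_registry):
        cfg = ExperimentConfig(sample_fraction=1.0, reference_month=1900 * 12)
        rng = np.random.default_rng(0)
        egos = sample_genealogists(sim_registry, cfg, rng)
        ref = 1900 * 12
        eligible = sim_registry.pids[
            sim_registry.alive_at(ref)
            & ((ref - sim_registry.birth_month) >= 18 * 12)]
        assert np.array_equal(egos, np.sort(eligible))

    def test_ten_percent_of_thousand_is_hundred(self):
        rows = [("f", y(1950), None, 0, 0)] * 1000
        reg = make_registry(rows, span=(y(1940), y(2000)))
        cfg = ExperimentConfig(sample_fraction=0.10, reference_month=y(1990))
        egos = sample_genealogists(reg, cfg, np.random.default_rng(1))
        assert len(egos) == 100

    def test_zero_fraction_rejected(self, sim_registry):
        cfg = ExperimentConfig(sample_fraction=1e-9, reference_month=1900 * 12)
        with pytest.raises(ValueError, match="empty sample"):
            sample_genealogists(sim_registry, cfg, np.random.default_rng(0))

    def test_no_eligible_individuals_rejected(self, toy_registry):
        cfg = ExperimentConfig(reference_month=y(1890))
        with pytest.raises(ValueError, match="no eligible"):
            sample_genealogists(toy_registry, cfg, np.random.default_rng(0))

    def test_deterministic_given_seed(self, sim_registry):
        cfg = ExperimentConfig(sample_fraction=0.2, reference_month=1900 * 12)
        a = sample_genealogists(sim_registry, cfg, np.random.default_rng(42))
        b = sample_genealogists(sim_registry, cfg, np.random.default_rng(42))
        assert np.array_equal(a, b)


class TestOmission:
    def _complete(self, toy_registry):
        return add_ancestor_offspring(
            merge_trees([trace_direct_ancestors(toy_registry, 7),
                         trace_direct_ancestors(toy_registry, 8)]),
            toy_registry)

    def test_zero_proportion_identity(self, toy_registry):
        sub = self._complete(toy_registry)
        cfg = ExperimentConfig(omission_target="under5_deaths",
                               omission_proportion=0.0)
        out = omit_individuals(sub, toy_registry, cfg, np.random.default_rng(0))
        assert np.array_equal(out.member_set, sub.dedup().member_set)

    def test_full_omission_removes_all_under5_deaths(self, toy_registry):
        sub = self._complete(toy_registry)
        cfg = ExperimentConfig(omission_target="under5_deaths",
                               omission_proportion=1.0)
        out = omit_individuals(sub, toy_registry, cfg, np.random.default_rng(0))
        b = toy_registry.birth_month[out.member_set - 1]
        d = toy_registry.death_month[out.member_set - 1]
        died_young = (d != OPEN) & (d - b < 60)
        assert not died_young.any()
        assert 5 not in out.member_set and 8 not in out.member_set

    def test_rounding_of_removal_count(self):
        # 10 eligible children dead before five, proportion 0.5 -> exactly 5
        rows = [("f", y(1900), None, 0, 0), ("m", y(1900), None, 0, 0)]
        for k in range(10):
            rows.append(("m", y(1930), y(1932), 1, 2))
        reg = make_registry(rows, span=(y(1890), y(2000)))
        sub = GenealogicalSubset(
            pd.DataFrame({"genealogist_pid": 1,
                          "member_pid": np.arange(1, 13),
                          "kin_type": "ego", "generation": 0}),
            reg.token)
        cfg = ExperimentConfig(omission_target="under5_deaths",
                               omission_proportion=0.5)
        out = omit_individuals(sub, reg, cfg, np.random.default_rng(3))
        assert len(out.member_set) == 12 - 5

    def test_removals_nested_and_monotone_in_proportion(self, toy_registry):
        sub = self._complete(toy_registry)
        removed_sets = []
        for p in (0.25, 0.5, 0.75, 1.0):
            cfg = ExperimentConfig(omission_target="under5_deaths",
                                   omission_proportion=p)
            out = omit_individuals(sub, toy_registry, cfg,
                                   np.random.default_rng(11))
            removed_sets.append(set(sub.dedup().member_set) - set(out.member_set))
        for small, big in zip(removed_sets, removed_sets[1:]):
            assert small <= big

    def test_childless_women_class(self, toy_registry):
        # aunt (4) reached 15 and had no children; grandma/mother had children;
        # ego (7) is alive, childless and past 15 at the registry end
        elig = eligible_for_omission(toy_registry, "childless_women",
                                     ExperimentConfig())
        assert set(elig) == {4, 7, 9}

    def test_invalid_proportion_rejected(self):
        with pytest.raises(ValueError, match="\\[0, 1\\]"):
            ExperimentConfig(omission_proportion=1.3)


class TestSubsetStructure:
    def test_exp1_members_subset_of_exp2(self, sim_registry):
        from lineagebias.experiments import build_subsets
        cfg = ExperimentConfig(seed=3, reference_month=1900 * 12)
        e1 = build_subsets(sim_registry, cfg, "1")
        e2 = build_subsets(sim_registry, cfg, "2")
        assert set(e1["direct_dedup"][0].member_set) <= \
            set(e2["complete"][0].member_set)

    def test_direct_ancestors_all_reproduced(self, sim_registry):
        cfg = ExperimentConfig(seed=3, reference_month=1900 * 12)
        from lineagebias.experiments import build_subsets
        sub = build_subsets(sim_registry, cfg, "1")["direct_dedup"][0]
        anc = sub.attributions.query("kin_type == 'direct_ancestor'")
        counts = sim_registry.child_counts()
        assert (counts[anc.member_pid.to_numpy()] >= 1).all()

    def test_no_ancestor_died_before_lineage_child_conception(self, sim_registry):
        """Female ancestors outlive the birth, male ones the conception,
        of their in-lineage child."""
        cfg = ExperimentConfig(seed=3, reference_month=1900 * 12)
        from lineagebias.experiments import build_subsets
        sub = build_subsets(sim_registry, cfg, "1")["direct_dedup"][0]
        reg = sim_registry
        for pid in sub.attributions.query("kin_type == 'direct_ancestor'").member_pid.unique():
            kids = reg.children_of(int(pid))
            d = reg.death_month[pid - 1]
            if d == OPEN:
                continue
            first_kid_birth = reg.birth_month[kids - 1].min()
            margin = 0 if reg.sex[pid - 1] == FEMALE else 9
            assert d >= first_kid_birth - margin

    def test_ancestor_attributions_capped_at_1022(self, sim_registry):
        cfg = ExperimentConfig(seed=3, reference_month=1900 * 12)
        from lineagebias.experiments import build_subsets
        sub = build_subsets(sim_registry, cfg, "1")["direct_dup"][0]
        per_geno = sub.attributions.query("kin_type == 'direct_ancestor'") \
            .groupby("genealogist_pid").size()
        assert (per_geno <= 1022).all()

    def test_subset_roundtrip_bit_exact(self, toy_registry, tmp_path):
        sub = self_complete = add_ancestor_offspring(
            trace_direct_ancestors(toy_registry, 7), toy_registry)
        p = tmp_path / "subset.csv"
        sub.to_csv(p)
        again = GenealogicalSubset.from_csv(p)
        pd.testing.assert_frame_equal(
            again.attributions, sub.attributions[again.attributions.columns])
        assert again.registry_token == sub.registry_token
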