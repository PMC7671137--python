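"""Unordered parsimony: exactness, polytomy semantics, transition reports."""

import random
import subprocess
import textwrap

import pytest

from chaenopsid.characters import MISSING
from chaenopsid.parsimony import (
    ParsimonyError,
    TipStateAssignment,
    count_transitions,
    fitch_hartigan,
    map_dimorphism,
    reconstruct,
    soft_polytomy_steps,
)
from chaenopsid.phylo import Phylogeny

from oracles import (
    brute_force_hard,
    brute_force_soft,
    random_assignment,
    random_binary_newick,
    random_multifurcating_newick,
    random_one_polytomy_newick,
)


def assignment(mapping, alphabet=None):
    return TipStateAssignment(mapping, alphabet=alphabet or ())


class TestBasics:
    def test_constant_character_needs_no_changes(self):
        t = Phylogeny.from_newick("((a,b),(c,(d,e)));")
        tips = assignment({x: "A" for x in "abcde"}, alphabet=("A", "B"))
        res = fitch_hartigan(t, tips)
        assert res.min_steps == 0
        assert res.transitions == []
        assert all(s == frozenset({"A"}) for s in res.node_state_sets.values())

    def test_star_two_and_two_hard_versus_soft(self):
        t = Phylogeny.from_newick("(a,b,c,d);")
        tips = assignment(
            {"a": "A", "b": "A", "c": "B", "d": "B"}, alphabet=("A", "B")
        )
        assert fitch_hartigan(t, tips).min_steps == 2
        # a refinement can group the like states: ((a,b),(c,d))
        assert soft_polytomy_steps(t, tips).min_steps == 1

    def test_modes_coincide_on_binary_trees(self):
        rng = random.Random(5)
        for _ in range(30):
            labels = [f"t{i}" for i in range(rng.randint(3, 8))]
            t = Phylogeny.from_newick(random_binary_newick(rng, labels))
            tips = random_assignment(rng, labels, rng.randint(2, 4))
            assert (
                fitch_hartigan(t, tips).min_steps
                == soft_polytomy_steps(t, tips).min_steps
            )

    def test_missing_tips_accept_any_state_free(self):
        t = Phylogeny.from_newick("((a,b),(c,d));")
        tips = assignment(
            {"a": "A", "b": MISSING, "c": "B", "d": MISSING},
            alphabet=("A", "B"),
        )
        assert fitch_hartigan(t, tips).min_steps == 1

    def test_state_outside_alphabet_rejected(self):
        with pytest.raises(ParsimonyError, match="outside alphabet"):
            assignment({"a": "Z"}, alphabet=("A", "B"))

    def test_tip_tree_mismatch_lists_offenders(self):
        t = Phylogeny.from_newick("(a,b,c);")
        tips = assignment({"a": "A", "b": "A", "x": "B"}, alphabet=("A", "B"))
        with pytest.raises(ParsimonyError) as err:
            fitch_hartigan(t, tips)
        assert "c" in str(err.value) and "x" in str(err.value)


class TestOracleEquivalence:
    def test_hard_mode_equals_exhaustive_enumeration(self):
        rng = random.Random(11)
        for rep in range(60):
            n = rng.randint(3, 8)
            labels = [f"t{i}" for i in range(n)]
            nwk = (
                random_binary_newick(rng, labels)
                if rep % 2
                else random_multifurcating_newick(rng, labels)
            )
            t = Phylogeny.from_newick(nwk)
            tips = random_assignment(rng, labels, rng.randint(2, 4), 0.1)
            assert fitch_hartigan(t, tips).min_steps == brute_force_hard(t, tips)

    def test_soft_mode_equals_exhaustive_refinement(self):
        rng = random.Random(13)
        for _ in range(40):
            nwk, labels = random_one_polytomy_newick(
                rng, rng.randint(3, 6), rng.randint(2, 3)
            )
            t = Phylogeny.from_newick(nwk)
            tips = random_assignment(rng, labels, rng.randint(2, 4))
            assert (
                soft_polytomy_steps(t, tips).min_steps
                == brute_force_soft(t, tips)
            )

    def test_soft_mode_exact_on_nested_polytomies(self):
        rng = random.Random(17)
        cases = [
            "((a,b,c),(d,e,f));",
            "(a,(b,c,d),e);",
            "((a,b,c,d),e,f);",
            "(a,b,(c,d,(e,f,g)));",
            "(a,b,c,d,e);",
        ]
        for _ in range(40):
            nwk = rng.choice(cases)
            labels = sorted({x for x in nwk if x.isalpha()})
            t = Phylogeny.from_newick(nwk)
            tips = random_assignment(rng, labels, rng.randint(2, 4))
            assert (
                soft_polytomy_steps(t, tips).min_steps
                == brute_force_soft(t, tips)
            )

    def test_hard_mode_matches_phangorn_sankoff(self, tmp_path):
        """Cross-check against an independent implementation (R/phangorn)."""
        rng = random.Random(23)
        cases = []
        for _ in range(4):
            labels = [f"t{i}" for i in range(rng.randint(4, 7))]
            nwk = random_multifurcating_newick(rng, labels)
            tips = random_assignment(rng, labels, 3)
            cases.append((nwk, tips))
        script_lines = ["suppressMessages(library(phangorn))"]
        for i, (nwk, tips) in enumerate(cases):
            states = ",".join(
                f'{lab}="{tips.states[lab]}"' for lab in sorted(tips.states)
            )
            levels = ",".join(f'"{a}"' for a in tips.alphabet)
            script_lines.append(textwrap.dedent(f"""
                tree <- read.tree(text="{nwk}")
                states <- c({states})
                dat <- phyDat(matrix(states, ncol=1,
                              dimnames=list(names(states), NULL)),
                              type="USER", levels=c({levels}))
                cat(sankoff(tree, dat, cost=NULL), "\\n")
            """))
        script = tmp_path / "check.R"
        script.write_text("\n".join(script_lines))
        out = subprocess.run(
            ["Rscript", str(script)], capture_output=True, text=True, check=True
        )
        r_scores = [int(float(x)) for x in out.stdout.split()]
        ours = [
            fitch_hartigan(Phylogeny.from_newick(nwk), tips).min_steps
            for nwk, tips in cases
        ]
        assert ours == r_scores


class TestInvariants:
    def test_soft_never_exceeds_hard(self):
        rng = random.Random(29)
        for _ in range(80):
            labels = [f"t{i}" for i in range(rng.randint(3, 10))]
            t = Phylogeny.from_newick(random_multifurcating_newick(rng, labels))
            tips = random_assignment(rng, labels, rng.randint(2, 4), 0.1)
            assert (
                soft_polytomy_steps(t, tips).min_steps
                <= fitch_hartigan(t, tips).min_steps
            )

    def test_soft_steps_never_drop_on_refinement(self):
        # collapsing structure can only help the soft score; equivalently a
        # refinement T' of T has soft steps >= those of T
        rng = random.Random(31)
        for _ in range(40):
            labels = [f"t{i}" for i in range(rng.randint(4, 8))]
            refined_nwk = random_binary_newick(rng, labels)
            refined = Phylogeny.from_newick(refined_nwk)
            tips = random_assignment(rng, labels, rng.randint(2, 3))
            # collapse a random internal edge to make a less resolved tree
            collapsed = Phylogeny.from_newick(refined_nwk)
            dt = collapsed.dendropy_tree
            internal = [
                nd for nd in dt.postorder_internal_node_iter()
                if nd.parent_node is not None
            ]
            if not internal:
                continue
            victim = rng.choice(internal)
            parent = victim.parent_node
            for child in list(victim.child_nodes()):
                victim.remove_child(child)
                parent.add_child(child)
            parent.remove_child(victim)
            collapsed.normalize()
            assert (
                soft_polytomy_steps(refined, tips).min_steps
                >= soft_polytomy_steps(collapsed, tips).min_steps
            )

    def test_state_label_permutation_leaves_steps_unchanged(self):
        rng = random.Random(37)
        for _ in range(40):
            labels = [f"t{i}" for i in range(rng.randint(3, 8))]
            t = Phylogeny.from_newick(random_multifurcating_newick(rng, labels))
            tips = random_assignment(rng, labels, 3)
            perm = list(tips.alphabet)
            rng.shuffle(perm)
            mapping = dict(zip(tips.alphabet, perm))
            permuted = TipStateAssignment(
                {
                    k: (mapping[v] if v != MISSING else v)
                    for k, v in tips.states.items()
                },
                alphabet=tips.alphabet,
            )
            for mode in ("hard", "soft"):
                assert (
                    reconstruct(t, tips, mode).min_steps
                    == reconstruct(t, permuted, mode).min_steps
                )


class TestTransitions:
    def test_zero_step_result_has_no_transitions(self):
        t = Phylogeny.from_newick("(a,b,c);")
        tips = assignment({x: "A" for x in "abc"}, alphabet=("A", "B"))
        summary = count_transitions(fitch_hartigan(t, tips))
        assert summary.total == 0
        assert summary.by_branch == []

    def test_single_deviant_tip_changes_on_its_own_branch(self):
        t = Phylogeny.from_newick("((a,b),(c,d));")
        tips = assignment(
            {"a": "A", "b": "A", "c": "A", "d": "B"}, alphabet=("A", "B")
        )
        res = fitch_hartigan(t, tips)
        summary = count_transitions(res)
        assert summary.total == 1
        (tr,) = summary.by_branch
        assert tr.branch == "d"
        assert (tr.from_state, tr.to_state) == ("A", "B")
        assert (summary.gains, summary.losses) == (1, 0)

    def test_transition_count_always_equals_min_steps(self):
        rng = random.Random(41)
        for _ in range(250):
            labels = [f"t{i}" for i in range(rng.randint(3, 9))]
            t = Phylogeny.from_newick(random_multifurcating_newick(rng, labels))
            tips = random_assignment(rng, labels, rng.randint(2, 4), 0.1)
            for mode in ("hard", "soft"):
                res = reconstruct(t, tips, mode)
                assert count_transitions(res).total == res.min_steps


class TestDimorphismMapping:
    def test_monomorphic_everywhere_gives_zero_step_dimorphism_map(self):
        t = Phylogeny.from_newick("((a,b),(c,d));")
        states = {"a": "x", "b": "y", "c": "x", "d": "y"}
        tips = assignment(dict(states), alphabet=("x", "y"))
        maps = map_dimorphism(t, tips, assignment(dict(states), ("x", "y")))
        assert maps.dimorphism.min_steps == 0

    def test_female_only_shift_creates_dimorphism_on_same_branch(self):
        t = Phylogeny.from_newick("((a,b),(c,d));")
        male = assignment({x: "long" for x in "abcd"}, ("long", "short"))
        female = assignment(
            {"a": "long", "b": "long", "c": "long", "d": "short"},
            ("long", "short"),
        )
        maps = map_dimorphism(t, male, female)
        assert maps.males.min_steps == 0
        assert maps.females.min_steps == 1
        assert maps.dimorphism.min_steps == 1
        (f_tr,) = maps.females.transitions
        (d_tr,) = maps.dimorphism.transitions
        assert f_tr.branch == d_tr.branch == "d"
        assert (d_tr.from_state, d_tr.to_state) == ("absent", "present")

    def test_species_in_one_sex_only_rejected(self):
        t = Phylogeny.from_newick("(a,b);")
        male = assignment({"a": "x", "b": "x"}, ("x", "y"))
        female = assignment({"a": "x", "b": "x", "c": "y"}, ("x", "y"))
        with pytest.raises(ParsimonyError, match="one sex only"):
            map_dimorphism(t, male, female)

    def test_dimorphism_steps_bounded_by_sum_of_sex_steps(self):
        rng = random.Random(43)
        for _ in range(200):
            labels = [f"t{i}" for i in range(rng.randint(3, 8))]
            t = Phylogeny.from_newick(random_multifurcating_newick(rng, labels))
            male = random_assignment(rng, labels, 3)
            female = random_assignment(rng, labels, 3)
            maps = map_dimorphism(t, male, female)
            assert (
                maps.dimorphism.min_steps
                <= maps.males.min_steps + maps.females.min_steps
            )


class TestAmbiguity:
    def test_multiple_reconstructions_reported_not_hidden(self):
        # a,b = A and c,d = B on a balanced tree: root may be A or B
        t = Phylogeny.from_newick("((a,b),(c,d));")
        tips = assignment(
            {"a": "A", "b": "A", "c": "B", "d": "B"}, alphabet=("A", "B")
        )
        res = fitch_hartigan(t, tips)
        assert res.min_steps == 1
        assert res.n_mprs == 2
        root_label = [
            lbl for lbl in res.node_state_sets if lbl.startswith("mrca")
            and "n=4" in lbl
        ]
        assert res.node_state_sets[root_label[0]] == frozenset({"A", "B"})
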