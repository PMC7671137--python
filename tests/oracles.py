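"""Independent brute-force oracles for parsimony, used only by tests.

These deliberately share no code with the package's dynamic programmes:
hard-mode scores are found by enumerating every ancestral state assignment,
and soft-mode scores by enumerating every joint binary refinement of every
polytomy (children kept intact) and taking the best hard score over them.
"""

from __future__ import annotations

import itertools
import random

from chaenopsid.characters import MISSING
from chaenopsid.parsimony import TipStateAssignment
from chaenopsid.phylo import Phylogeny, node_label


def brute_force_hard(tree: Phylogeny, tips: TipStateAssignment) -> int:
    """Minimum changes by exhaustive enumeration over ancestral states."""
    nodes = list(tree.postorder())
    internal = [n for n in nodes if n.child_nodes()]
    best = None
    for combo in itertools.product(tips.alphabet, repeat=len(internal)):
        assign = {id(n): s for n, s in zip(internal, combo)}
        cost = 0
        for n in nodes:
            if n.parent_node is None:
                continue
            if n.child_nodes():
                s = assign[id(n)]
            else:
                observed = tips.states[node_label(n)]
                # a missing tip copies its parent at zero cost
                s = assign[id(n.parent_node)] if observed == MISSING else observed
            if s != assign[id(n.parent_node)]:
                cost += 1
        best = cost if best is None else min(best, cost)
    return best


def _binary_shapes(tokens: list):
    """All rooted binary tree shapes over opaque tokens."""
    if len(tokens) == 1:
        yield tokens[0]
        return
    if len(tokens) == 2:
        yield (tokens[0], tokens[1])
        return
    first, rest = tokens[0], list(tokens[1:])
    for shape in _binary_shapes(rest):
        yield from _insert_everywhere(shape, first)


def _insert_everywhere(shape, frag):
    yield (shape, frag)
    if isinstance(shape, tuple):
        a, b = shape
        for t in _insert_everywhere(a, frag):
            yield (t, b)
        for t in _insert_everywhere(b, frag):
            yield (a, t)


def all_refinements(tree: Phylogeny) -> list[str]:
    """Newick strings of every joint binary refinement of the tree.

    Each polytomy is refined over its children as opaque units, so clades
    are never broken apart.
    """

    def refine(node) -> list[str]:
        children = node.child_nodes()
        if not children:
            return [node_label(node).replace(" ", "_")]
        child_opts = [refine(ch) for ch in children]
        out = set()
        for combo in itertools.product(*child_opts):
            tokens = [f"@{i}" for i in range(len(combo))]

            def render(shape):
                if isinstance(shape, tuple):
                    return "(" + render(shape[0]) + "," + render(shape[1]) + ")"
                return combo[int(shape[1:])]

            for shape in _binary_shapes(tokens):
                out.add(render(shape))
        return sorted(out)

    return [nwk + ";" for nwk in refine(tree.root)]


def fitch_binary_score(tree: Phylogeny, tips: TipStateAssignment) -> int:
    """Classic Fitch set-intersection count; exact on binary trees only.

    Missing tips carry the full alphabet and never force a count.
    """
    full = frozenset(tips.alphabet)
    count = 0
    sets: dict[int, frozenset[str]] = {}
    for node in tree.postorder():
        children = node.child_nodes()
        if not children:
            observed = tips.states[node_label(node)]
            sets[id(node)] = full if observed == MISSING else frozenset({observed})
            continue
        assert len(children) == 2, "Fitch oracle needs a binary tree"
        a, b = (sets[id(ch)] for ch in children)
        inter = a & b
        if inter:
            sets[id(node)] = inter
        else:
            sets[id(node)] = a | b
            count += 1
    return count


def brute_force_soft(tree: Phylogeny, tips: TipStateAssignment) -> int:
    """Best score over all binary refinements, each scored by Fitch."""
    best = None
    for nwk in all_refinements(tree):
        refined = Phylogeny.from_newick(nwk)
        score = fitch_binary_score(refined, tips)
        best = score if best is None else min(best, score)
    return best


# ---------------------------------------------------------------------------
# Random instance generators (seeded by the caller)
# ---------------------------------------------------------------------------

def random_binary_newick(rng: random.Random, labels: list[str]) -> str:
    frags = list(labels)
    while len(frags) > 2:
        i, j = sorted(rng.sample(range(len(frags)), 2))
        frags = [f for k, f in enumerate(frags) if k not in (i, j)] + [
            f"({frags[i]},{frags[j]})"
        ]
    return "(" + ",".join(frags) + ");"


def random_multifurcating_newick(rng: random.Random, labels: list[str]) -> str:
    """Random tree built by joining 2-4 fragments at a time."""
    frags = list(labels)
    while len(frags) > 1:
        k = min(len(frags), rng.randint(2, 4))
        picked = sorted(rng.sample(range(len(frags)), k))
        merged = "(" + ",".join(frags[i] for i in picked) + ")"
        frags = [f for i, f in enumerate(frags) if i not in picked] + [merged]
    inner = frags[0]
    return inner + ";" if inner.startswith("(") else f"({inner});"


def random_one_polytomy_newick(
    rng: random.Random, n_poly: int, n_extra: int
) -> tuple[str, list[str]]:
    """Binary tree with a single grafted polytomy of ``n_poly`` children."""
    poly_labels = [f"p{i}" for i in range(n_poly)]
    extra = [f"b{i}" for i in range(n_extra)]
    poly = "(" + ",".join(poly_labels) + ")"
    nwk = random_binary_newick(rng, [poly] + extra)
    return nwk, poly_labels + extra


def random_assignment(
    rng: random.Random,
    labels: list[str],
    n_states: int,
    missing_rate: float = 0.0,
) -> TipStateAssignment:
    alphabet = tuple(f"S{j}" for j in range(n_states))
    states = {
        lab: (MISSING if rng.random() < missing_rate else rng.choice(alphabet))
        for lab in labels
    }
    if all(v == MISSING for v in states.values()):
        states[labels[0]] = alphabet[0]
    return TipStateAssignment(states, alphabet=alphabet)
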