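"""Simulate per-sex discrete characters on trees with known histories.

The survey's raw per-species scores live in its (unpackaged) supplement, so
the pipeline is exercised on simulated data of the same shape: a rooted
tree, and for each character a male and a female state per tip.  Characters
start monomorphic at the root and change along branches in two ways:

shared changes (probability ``p_shared`` per branch per character)
    both sexes jump together to a common new state — monomorphism-preserving
    when the sexes agreed;

sex-limited changes (probability ``p_sex`` per branch per character)
    one sex (fair coin) jumps alone — these create dimorphism, and can
    equally destroy it when the moving sex lands on the other's state.

The per-branch Bernoulli change model is deliberately transparent (the
survey fits no evolutionary model); it is a stand-in for a continuous-time
Mk process, not an estimate of real rates.  Every replicate carries its
full event history so parsimony output can be checked against the truth:
the inferred minimum steps can never exceed the number of events that
actually occurred.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal

import numpy as np

from .characters import (
    CATEGORIES,
    MISSING,
    CharacterCatalog,
    CharacterDefinition,
    SexScoreMatrix,
)
from .parsimony import ParsimonyResult, TipStateAssignment, reconstruct
from .phylo import Phylogeny, node_label


class SimulationError(ValueError):
    """Raised for invalid simulation configurations."""


#: Characters per category, defaulting to the survey catalogue's sizes.
DEFAULT_CATEGORY_SIZES = {
    "M-I": 5, "M-II": 4, "M-III": 7, "M-IV": 6, "C-I": 3, "C-II": 3, "C-III": 11,
}


@dataclass(frozen=True)
class SimulationConfig:
    """Knobs of the generator.

    ``tree_shape`` is ``"random-binary"`` or ``"with-polytomies"``; in the
    latter case internal edges are collapsed with probability
    ``collapse_prob`` (bounded by ``max_degree``).  ``alphabet_size`` states
    per character (labels ``s0``, ``s1``, ...).
    """

    n_species: int = 16
    tree_shape: Literal["random-binary", "with-polytomies"] = "random-binary"
    category_sizes: dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_CATEGORY_SIZES)
    )
    alphabet_size: int = 3
    p_shared: float = 0.05
    p_sex: float = 0.05
    collapse_prob: float = 0.3
    max_degree: int = 6
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_species < 2:
            raise SimulationError("n_species must be >= 2")
        for p in (self.p_shared, self.p_sex, self.collapse_prob):
            if not 0.0 <= p <= 1.0:
                raise SimulationError(f"probability {p} outside [0, 1]")
        if self.alphabet_size < 2:
            raise SimulationError("alphabet_size must be >= 2")
        bad = set(self.category_sizes) - set(CATEGORIES)
        if bad:
            raise SimulationError(f"unknown categories {sorted(bad)}")

    @property
    def n_characters(self) -> int:
        return sum(self.category_sizes.values())


@dataclass(frozen=True)
class ChangeEvent:
    """One state change on one branch of the true history."""

    branch: str  # label of the child end of the branch
    char_id: str
    sex_scope: Literal["both", "male-only", "female-only"]
    from_male: str
    to_male: str
    from_female: str
    to_female: str


@dataclass
class SimulationTruth:
    """Full event history plus true per-tip dimorphism flags."""

    events: list[ChangeEvent]
    dimorphic: dict[tuple[str, str], bool]  # (species, char_id) -> bool
    root_states: dict[str, str]  # char_id -> shared root state

    def events_for(self, char_id: str, sex: str) -> list[ChangeEvent]:
        """Events that moved the given sex for one character."""
        scope = {"male": ("both", "male-only"), "female": ("both", "female-only")}
        return [
            e for e in self.events
            if e.char_id == char_id and e.sex_scope in scope[sex]
        ]


# ---------------------------------------------------------------------------
# Tree generation
# ---------------------------------------------------------------------------

def random_tree(config: SimulationConfig, rng: np.random.Generator) -> Phylogeny:
    """Random rooted tree over ``sp_0001``-style tips.

    Built by random sequential joins (uniform over join order); optionally
    polytomised by collapsing internal edges.
    """
    labels = [f"sp_{i:04d}" for i in range(1, config.n_species + 1)]
    fragments = list(labels)
    while len(fragments) > 2:
        i, j = sorted(rng.choice(len(fragments), size=2, replace=False))
        merged = f"({fragments[i]},{fragments[j]})"
        fragments = [
            f for k, f in enumerate(fragments) if k not in (i, j)
        ] + [merged]
    tree = Phylogeny.from_newick("(" + ",".join(fragments) + ");")
    if config.tree_shape == "with-polytomies":
        _collapse_edges(tree, config, rng)
    return tree


def _collapse_edges(
    tree: Phylogeny, config: SimulationConfig, rng: np.random.Generator
) -> None:
    dt = tree.dendropy_tree
    internal = [
        nd for nd in dt.postorder_internal_node_iter()
        if nd.parent_node is not None
    ]
    for node in internal:
        parent = node.parent_node
        if parent is None:
            continue
        room = config.max_degree - len(parent.child_nodes()) + 1
        if room < len(node.child_nodes()):
            continue
        if rng.random() < config.collapse_prob:
            for child in list(node.child_nodes()):
                node.remove_child(child)
                parent.add_child(child)
            parent.remove_child(node)
    tree.normalize()


# ---------------------------------------------------------------------------
# Character evolution
# ---------------------------------------------------------------------------

def _synthetic_catalog(config: SimulationConfig) -> CharacterCatalog:
    states = tuple(f"s{i}" for i in range(config.alphabet_size))
    chars = []
    for cat in CATEGORIES:
        for i in range(config.category_sizes.get(cat, 0)):
            chars.append(
                CharacterDefinition(
                    char_id=f"{cat}.sim{i:02d}",
                    category=cat,
                    description=f"simulated character {i} in {cat}",
                    state_labels=states,
                )
            )
    return CharacterCatalog(chars)


def simulate(
    config: SimulationConfig,
    tree: Phylogeny | None = None,
) -> tuple[Phylogeny, SexScoreMatrix, SimulationTruth]:
    """Generate a tree, a per-sex score matrix, and the true history.

    Seeded runs are bit-reproducible: all randomness flows from
    ``config.seed`` through one ``numpy`` generator.
    """
    rng = np.random.default_rng(config.seed)
    if tree is None:
        tree = random_tree(config, rng)
    catalogue = _synthetic_catalog(config)
    alphabet = catalogue.characters[0].state_labels
    events: list[ChangeEvent] = []
    dimorphic: dict[tuple[str, str], bool] = {}
    root_states: dict[str, str] = {}
    scores: dict[tuple[str, str, str], str] = {}
    tips = tree.tip_labels()

    for ch in catalogue:
        root = str(rng.choice(alphabet))
        root_states[ch.char_id] = root
        # states carried down the tree: node -> (male_state, female_state)
        carry: dict[int, tuple[str, str]] = {id(tree.root): (root, root)}
        for node in tree.preorder():
            if node is tree.root:
                continue
            male, female = carry[id(node.parent_node)]
            if rng.random() < config.p_shared:
                # Jump to a state new to both sexes where possible (a binary
                # alphabet with dimorphic sexes leaves only the male's state).
                candidates = [a for a in alphabet if a not in (male, female)]
                if not candidates:
                    candidates = [a for a in alphabet if a != male]
                new = str(rng.choice(candidates))
                events.append(
                    ChangeEvent(
                        branch=node_label(node),
                        char_id=ch.char_id,
                        sex_scope="both",
                        from_male=male,
                        to_male=new,
                        from_female=female,
                        to_female=new,
                    )
                )
                male = female = new
            if rng.random() < config.p_sex:
                which = "male-only" if rng.random() < 0.5 else "female-only"
                if which == "male-only":
                    new = str(rng.choice([a for a in alphabet if a != male]))
                    events.append(
                        ChangeEvent(
                            branch=node_label(node),
                            char_id=ch.char_id,
                            sex_scope=which,
                            from_male=male,
                            to_male=new,
                            from_female=female,
                            to_female=female,
                        )
                    )
                    male = new
                else:
                    new = str(rng.choice([a for a in alphabet if a != female]))
                    events.append(
                        ChangeEvent(
                            branch=node_label(node),
                            char_id=ch.char_id,
                            sex_scope=which,
                            from_male=male,
                            to_male=male,
                            from_female=female,
                            to_female=new,
                        )
                    )
                    female = new
            carry[id(node)] = (male, female)
            if not node.child_nodes():
                label = node_label(node)
                scores[(label, "male", ch.char_id)] = male
                scores[(label, "female", ch.char_id)] = female
                dimorphic[(label, ch.char_id)] = male != female

    matrix = SexScoreMatrix(catalogue, scores, species=tips)
    truth = SimulationTruth(
        events=events, dimorphic=dimorphic, root_states=root_states
    )
    return tree, matrix, truth


# ---------------------------------------------------------------------------
# Recovery checking
# ---------------------------------------------------------------------------

@dataclass
class RecoveryReport:
    """Parsimony-vs-truth comparison for one character and sex."""

    char_id: str
    sex: str
    true_events: int
    min_steps: int

    @property
    def bound_holds(self) -> bool:
        return self.min_steps <= self.true_events

    @property
    def exact(self) -> bool:
        return self.min_steps == self.true_events


def recovery_check(
    tree: Phylogeny,
    matrix: SexScoreMatrix,
    truth: SimulationTruth,
    mode: str = "soft",
) -> list[RecoveryReport]:
    """Check min-steps <= true change count for every character and sex.

    Parsimony is a lower bound on the true number of changes; the report
    records, per character and sex, the true event count and the inferred
    minimum so equality rates can be measured.  Raises if any tip of the
    tree has no scores (mismatched tree).
    """
    tip_set = set(tree.tip_labels())
    if tip_set != set(matrix.species):
        raise SimulationError(
            "tree/matrix mismatch: "
            f"{sorted(tip_set ^ set(matrix.species))}"
        )
    alphabet = matrix.catalogue.characters[0].state_labels
    reports = []
    for ch in matrix.catalogue:
        for sex in ("male", "female"):
            tips = TipStateAssignment(
                matrix.sex_assignment(sex, ch.char_id), alphabet=alphabet
            )
            result: ParsimonyResult = reconstruct(tree, tips, mode)
            reports.append(
                RecoveryReport(
                    char_id=ch.char_id,
                    sex=sex,
                    true_events=len(truth.events_for(ch.char_id, sex)),
                    min_steps=result.min_steps,
                )
            )
    return reports
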