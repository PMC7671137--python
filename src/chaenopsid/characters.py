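"""Character catalogue, sex-specific score matrices, and dimorphism scoring.

The survey scores each species twice — once per sex — on a catalogue of 39
discrete characters grouped into seven categories: osteology (M-I),
morphometrics (M-II), soft anatomy (M-III), fins (M-IV), head coloration
(C-I), body coloration (C-II), and fin coloration (C-III). A character is
dimorphic in a species when the male and female scores differ; characters
unscorable in either sex contribute nothing, so per-species counts are
minima.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

import dendropy
import pandas as pd

logger = logging.getLogger(__name__)

#: Sentinel score for a cell that could not be assessed in a sex.
MISSING = "?"

#: Valid sexes, in canonical order.
SEXES = ("male", "female")

#: Category codes in catalogue order.  M-* are morphology, C-* coloration.
CATEGORIES = ("M-I", "M-II", "M-III", "M-IV", "C-I", "C-II", "C-III")
MORPHOLOGY_CATEGORIES = ("M-I", "M-II", "M-III", "M-IV")
COLORATION_CATEGORIES = ("C-I", "C-II", "C-III")


class CatalogError(ValueError):
    """Raised when a character catalogue fails validation."""


class MatrixError(ValueError):
    """Raised when a score matrix fails validation."""


@dataclass(frozen=True)
class CharacterDefinition:
    """One discrete character of the dimorphism survey.

    Parameters
    ----------
    char_id:
        Short code such as ``"M-IIb"`` (jaw length) or ``"C-IIIa"``
        (anterior dorsal-fin coloration).
    category:
        One of :data:`CATEGORIES`.
    description:
        Free-text description of what is scored.
    state_labels:
        Ordered tuple of allowed state labels (at least two).  The order is
        cosmetic: all mapping downstream treats states as unordered.
    ordered_flag:
        Retained for extensibility; always ``False`` here because every
        character is mapped as unordered.
    """

    char_id: str
    category: str
    description: str
    state_labels: tuple[str, ...]
    ordered_flag: bool = False

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise CatalogError(
                f"character {self.char_id!r}: unknown category {self.category!r}"
            )
        if len(self.state_labels) < 2:
            raise CatalogError(
                f"character {self.char_id!r}: needs >= 2 state labels"
            )
        if len(set(self.state_labels)) != len(self.state_labels):
            raise CatalogError(
                f"character {self.char_id!r}: duplicate state labels"
            )


class CharacterCatalog:
    """An ordered, validated collection of :class:`CharacterDefinition`."""

    def __init__(self, characters: Iterable[CharacterDefinition]):
        self.characters: tuple[CharacterDefinition, ...] = tuple(characters)
        if not self.characters:
            raise CatalogError("no characters in catalogue")
        seen: set[str] = set()
        for ch in self.characters:
            if ch.char_id in seen:
                raise CatalogError(f"duplicate char_id {ch.char_id!r}")
            seen.add(ch.char_id)
        self._by_id = {ch.char_id: ch for ch in self.characters}

    def __len__(self) -> int:
        return len(self.characters)

    def __iter__(self):
        return iter(self.characters)

    def __contains__(self, char_id: str) -> bool:
        return char_id in self._by_id

    def __getitem__(self, char_id: str) -> CharacterDefinition:
        try:
            return self._by_id[char_id]
        except KeyError:
            raise KeyError(f"unknown character {char_id!r}") from None

    @property
    def char_ids(self) -> tuple[str, ...]:
        return tuple(ch.char_id for ch in self.characters)

    def category_sizes(self) -> dict[str, int]:
        """Number of characters per category, all categories present."""
        sizes = {cat: 0 for cat in CATEGORIES}
        for ch in self.characters:
            sizes[ch.category] += 1
        return sizes

    def ids_in_category(self, category: str) -> tuple[str, ...]:
        return tuple(c.char_id for c in self.characters if c.category == category)

    @property
    def n_morphology(self) -> int:
        sizes = self.category_sizes()
        return sum(sizes[c] for c in MORPHOLOGY_CATEGORIES)

    @property
    def n_coloration(self) -> int:
        sizes = self.category_sizes()
        return sum(sizes[c] for c in COLORATION_CATEGORIES)


@dataclass
class DimorphismProfile:
    """Per-species dimorphism counts, one Table-2-style row.

    ``category_counts`` maps each category code to the number of characters
    in that category whose male and female scores differ; ``m_total``,
    ``c_total`` and ``grand_total`` are the morphology, coloration and
    combined sums.
    """

    species: str
    category_counts: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for cat in CATEGORIES:
            self.category_counts.setdefault(cat, 0)
        bad = set(self.category_counts) - set(CATEGORIES)
        if bad:
            raise MatrixError(f"{self.species}: unknown categories {sorted(bad)}")
        if any(v < 0 for v in self.category_counts.values()):
            raise MatrixError(f"{self.species}: negative category count")

    @property
    def m_total(self) -> int:
        return sum(self.category_counts[c] for c in MORPHOLOGY_CATEGORIES)

    @property
    def c_total(self) -> int:
        return sum(self.category_counts[c] for c in COLORATION_CATEGORIES)

    @property
    def grand_total(self) -> int:
        return self.m_total + self.c_total

    def validate_against(self, catalogue: CharacterCatalog) -> None:
        """Check category caps against a catalogue's category sizes."""
        sizes = catalogue.category_sizes()
        for cat, count in self.category_counts.items():
            if count > sizes[cat]:
                raise MatrixError(
                    f"{self.species}: {cat} count {count} exceeds "
                    f"category size {sizes[cat]}"
                )


class SexScoreMatrix:
    """Discrete scores for every (species, sex, character) cell.

    Cells never present in the input default to :data:`MISSING`.
    """

    def __init__(
        self,
        catalogue: CharacterCatalog,
        scores: Mapping[tuple[str, str, str], str],
        species: Iterable[str] | None = None,
    ):
        self.catalogue = catalogue
        if species is None:
            ordered: list[str] = []
            for sp, _sex, _cid in scores:
                if sp not in ordered:
                    ordered.append(sp)
            species = ordered
        self.species: tuple[str, ...] = tuple(species)
        self._scores: dict[tuple[str, str, str], str] = {}
        for sp in self.species:
            for sex in SEXES:
                for cid in catalogue.char_ids:
                    self._scores[(sp, sex, cid)] = MISSING
        for (sp, sex, cid), state in scores.items():
            self._set(sp, sex, cid, state)

    def _set(self, species: str, sex: str, char_id: str, state: str) -> None:
        if sex not in SEXES:
            raise MatrixError(
                f"{species}/{char_id}: sex must be one of {SEXES}, got {sex!r}"
            )
        if species not in self.species:
            raise MatrixError(f"unknown species {species!r}")
        definition = self.catalogue[char_id]
        if state != MISSING and state not in definition.state_labels:
            raise MatrixError(
                f"{species}/{sex}/{char_id}: state {state!r} not among "
                f"allowed states {definition.state_labels}"
            )
        self._scores[(species, sex, char_id)] = state

    def get(self, species: str, sex: str, char_id: str) -> str:
        key = (species, sex, char_id)
        if key not in self._scores:
            raise KeyError(f"no cell for {key}")
        return self._scores[key]

    def __len__(self) -> int:
        return len(self._scores)

    def to_frame(self) -> pd.DataFrame:
        """Long-format view: columns species, sex, char_id, state."""
        rows = [
            {"species": sp, "sex": sex, "char_id": cid, "state": st}
            for (sp, sex, cid), st in sorted(self._scores.items())
        ]
        return pd.DataFrame(rows, columns=["species", "sex", "char_id", "state"])

    def sex_assignment(self, sex: str, char_id: str) -> dict[str, str]:
        """Tip → state map for one sex and character (MISSING kept as-is)."""
        if sex not in SEXES:
            raise MatrixError(f"unknown sex {sex!r}")
        return {sp: self.get(sp, sex, char_id) for sp in self.species}

    def dimorphism_assignment(self, char_id: str) -> dict[str, str]:
        """Tip → present/absent dimorphism for one character.

        A species with a MISSING score in either sex is scored MISSING.
        """
        out: dict[str, str] = {}
        for sp in self.species:
            m = self.get(sp, "male", char_id)
            f = self.get(sp, "female", char_id)
            if MISSING in (m, f):
                out[sp] = MISSING
            else:
                out[sp] = "present" if m != f else "absent"
        return out


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def fixture_path(name: str) -> Path:
    """Path to a packaged fixture file."""
    ref = resources.files("chaenopsid") / "fixtures" / name
    return Path(str(ref))


def load_catalog(path: str | Path | None = None) -> CharacterCatalog:
    """Load a character catalogue from a tab-separated file.

    Expected columns: ``char_id``, ``category``, ``description``, ``states``
    (states pipe-separated).  With no argument the packaged 39-character
    catalogue is loaded.
    """
    if path is None:
        path = fixture_path("table1_catalog.tsv")
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    required = {"char_id", "category", "description", "states"}
    missing_cols = required - set(df.columns)
    if missing_cols:
        raise CatalogError(f"missing columns: {sorted(missing_cols)}")
    if df.empty:
        raise CatalogError("no characters")
    chars = []
    for _, row in df.iterrows():
        states = tuple(s.strip() for s in str(row["states"]).split("|"))
        chars.append(
            CharacterDefinition(
                char_id=row["char_id"],
                category=row["category"],
                description=row["description"],
                state_labels=states,
            )
        )
    return CharacterCatalog(chars)


def read_matrix(path: str | Path, catalogue: CharacterCatalog) -> SexScoreMatrix:
    """Read a long-format score table (species, sex, char_id, state).

    Cells absent from the file become MISSING, with a logged warning; this is
    how unscorable characters enter the survey as non-dimorphic.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    required = {"species", "sex", "char_id", "state"}
    missing_cols = required - set(df.columns)
    if missing_cols:
        raise MatrixError(f"missing columns: {sorted(missing_cols)}")
    scores: dict[tuple[str, str, str], str] = {}
    species_order: list[str] = []
    for _, row in df.iterrows():
        sp = row["species"]
        if sp not in species_order:
            species_order.append(sp)
        scores[(sp, row["sex"], row["char_id"])] = row["state"]
    matrix = SexScoreMatrix(catalogue, scores, species=species_order)
    n_missing = sum(1 for v in matrix._scores.values() if v == MISSING)
    if n_missing:
        logger.warning(
            "%s: %d of %d cells missing (scored as non-dimorphic)",
            path, n_missing, len(matrix),
        )
    return matrix


def write_matrix(matrix: SexScoreMatrix, path: str | Path) -> None:
    """Write the long-format TSV that :func:`read_matrix` reads."""
    matrix.to_frame().to_csv(path, sep="\t", index=False)


def write_matrix_nexus(matrix: SexScoreMatrix, path: str | Path) -> None:
    """Write a NEXUS CHARACTERS block with one species×sex composite taxon.

    States are encoded as the 0-based index of the label within each
    character's state list (alphabet sizes here are all <= 10); MISSING
    becomes ``?``.  Emitted through dendropy, which quotes reserved
    punctuation in taxon labels.
    """
    taxa = dendropy.TaxonNamespace()
    char_matrix = dendropy.StandardCharacterMatrix(taxon_namespace=taxa)
    for sp in matrix.species:
        for sex in SEXES:
            taxon = taxa.new_taxon(label=f"{sp} {sex}")
            symbols = []
            for ch in matrix.catalogue:
                state = matrix.get(sp, sex, ch.char_id)
                if state == MISSING:
                    symbols.append("?")
                else:
                    symbols.append(str(ch.state_labels.index(state)))
            char_matrix.new_sequence(taxon=taxon, values=symbols)
    char_matrix.write(path=str(path), schema="nexus")


def read_matrix_nexus(
    path: str | Path, catalogue: CharacterCatalog
) -> SexScoreMatrix:
    """Reparse a NEXUS file written by :func:`write_matrix_nexus`."""
    char_matrix = dendropy.StandardCharacterMatrix.get(
        path=str(path), schema="nexus"
    )
    scores: dict[tuple[str, str, str], str] = {}
    species_order: list[str] = []
    for taxon in char_matrix.taxon_namespace:
        label = taxon.label
        sp, _, sex = label.rpartition(" ")
        if sex not in SEXES:
            raise MatrixError(f"taxon label {label!r} does not end in a sex")
        if sp not in species_order:
            species_order.append(sp)
        seq = char_matrix[taxon]
        for ch, cell in zip(catalogue, seq):
            symbol = str(cell)
            if symbol in ("?", "-"):
                continue
            scores[(sp, sex, ch.char_id)] = ch.state_labels[int(symbol)]
    return SexScoreMatrix(catalogue, scores, species=species_order)


# ---------------------------------------------------------------------------
# Dimorphism scoring
# ---------------------------------------------------------------------------

def score_dimorphism(matrix: SexScoreMatrix, species: str) -> DimorphismProfile:
    """Count dimorphic characters for one species, aggregated by category.

    A character counts as dimorphic iff the male and female scores are both
    present and differ.  MISSING in either sex contributes zero (the survey's
    counts are minima) and is logged.
    """
    if species not in matrix.species:
        raise MatrixError(f"species {species!r} not in matrix")
    counts = {cat: 0 for cat in CATEGORIES}
    for ch in matrix.catalogue:
        m = matrix.get(species, "male", ch.char_id)
        f = matrix.get(species, "female", ch.char_id)
        if MISSING in (m, f):
            logger.debug(
                "%s/%s: missing in at least one sex, scored non-dimorphic",
                species, ch.char_id,
            )
            continue
        if m != f:
            counts[ch.category] += 1
    profile = DimorphismProfile(species=species, category_counts=counts)
    profile.validate_against(matrix.catalogue)
    return profile


def score_all(matrix: SexScoreMatrix) -> list[DimorphismProfile]:
    """Dimorphism profiles for every species in the matrix."""
    return [score_dimorphism(matrix, sp) for sp in matrix.species]


def read_count_table(path: str | Path | None = None) -> pd.DataFrame:
    """Read a per-species category-count table (Table-2 layout).

    Columns: species, then one column per category code, then the printed
    totals ``M-Total``, ``C-Total``, ``Total``.  With no argument the
    packaged survey transcription (66 species) is loaded.
    """
    if path is None:
        path = fixture_path("table2_counts.tsv")
    df = pd.read_csv(path, sep="\t", comment="#")
    if "species" not in df.columns:
        raise MatrixError("count table needs a 'species' column")
    for cat in CATEGORIES:
        if cat not in df.columns:
            raise MatrixError(f"count table missing category column {cat!r}")
    return df


def profiles_from_counts(df: pd.DataFrame) -> list[DimorphismProfile]:
    """Turn a count table into :class:`DimorphismProfile` objects."""
    profiles = []
    for _, row in df.iterrows():
        counts = {cat: int(row[cat]) for cat in CATEGORIES}
        profiles.append(
            DimorphismProfile(species=row["species"], category_counts=counts)
        )
    return profiles
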