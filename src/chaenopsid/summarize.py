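"""Genus summaries of dimorphism counts and ordinal binning for mapping.

Per-species counts of dimorphic characters are summarised per genus
(arithmetic mean, sample standard deviation, range) and binned into five
ordinal map scores (0–4) before being traced on the phylogeny.  The bin
edges follow the survey's scheme and differ between the morphology,
coloration, and total counts because the categories hold different numbers
of characters (22, 17 and 39).
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .characters import CATEGORIES, DimorphismProfile


class SummaryError(ValueError):
    """Raised for unmapped species or out-of-domain counts."""


# ---------------------------------------------------------------------------
# Binning
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BinningScheme:
    """Inclusive integer ranges mapped onto ordinal scores 0-4.

    Score 0 is reserved for a count of exactly zero; counts above the top
    edge are an error because each scheme is tied to the size of its
    character set.
    """

    name: str
    bin_edges: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        prev_hi = -1
        for lo, hi in self.bin_edges:
            if lo != prev_hi + 1 or hi < lo:
                raise SummaryError(
                    f"scheme {self.name!r}: ranges must be disjoint, "
                    f"exhaustive and increasing"
                )
            prev_hi = hi
        if self.bin_edges[0] != (0, 0):
            raise SummaryError(
                f"scheme {self.name!r}: score 0 must be reserved for count 0"
            )

    @property
    def top(self) -> int:
        return self.bin_edges[-1][1]


#: Map-score schemes: five ordinal classes per data set.
SCHEMES: dict[str, BinningScheme] = {
    "morphology": BinningScheme(
        "morphology", ((0, 0), (1, 4), (5, 8), (9, 11), (12, 17))
    ),
    "coloration": BinningScheme(
        "coloration", ((0, 0), (1, 4), (5, 8), (9, 11), (12, 14))
    ),
    "total": BinningScheme(
        "total", ((0, 0), (1, 6), (7, 13), (14, 19), (20, 31))
    ),
}


def bin_count(count: int, scheme: BinningScheme) -> int:
    """Ordinal map score (0-4) for a dimorphic-character count."""
    if count < 0:
        raise SummaryError(f"negative count {count}")
    for score, (lo, hi) in enumerate(scheme.bin_edges):
        if lo <= count <= hi:
            return score
    raise SummaryError(
        f"count {count} above top edge {scheme.top} of scheme {scheme.name!r}"
    )


def binned_scores(profile: DimorphismProfile) -> dict[str, int]:
    """Morphology/coloration/total map scores for one species."""
    return {
        "morphology": bin_count(profile.m_total, SCHEMES["morphology"]),
        "coloration": bin_count(profile.c_total, SCHEMES["coloration"]),
        "total": bin_count(profile.grand_total, SCHEMES["total"]),
    }


# ---------------------------------------------------------------------------
# Genus summaries
# ---------------------------------------------------------------------------

@dataclass
class GenusSummary:
    """Mean / sample SD / range of dimorphism counts for one genus.

    ``sd`` entries are ``None`` when only one species is included, matching
    the dash the survey prints.  ``n_total_in_genus`` is the number of
    recognised species; it defaults to the number included when unknown.
    """

    genus: str
    n_included: int
    n_total_in_genus: int
    morphology: tuple[float, float | None, int, int]
    coloration: tuple[float, float | None, int, int]
    total: tuple[float, float | None, int, int]


def _stats(values: Sequence[int]) -> tuple[float, float | None, int, int]:
    n = len(values)
    mean = sum(values) / n
    if n > 1:
        var = sum((v - mean) ** 2 for v in values) / (n - 1)
        sd: float | None = math.sqrt(var)
    else:
        sd = None
    return mean, sd, min(values), max(values)


#: Recognised species per genus in the family (sampled/total in the survey).
GENUS_TOTALS: dict[str, int] = {
    "Acanthemblemaria": 21,
    "Chaenopsis": 11,
    "Cirriemblemaria": 1,
    "Coralliozetus": 6,
    "Ekemblemaria": 3,
    "Emblemaria": 16,
    "Emblemariopsis": 14,
    "Hemiemblemaria": 1,
    "Lucayablennius": 1,
    "Mccoskerichthys": 1,
    "Neoclinus": 11,
    "Protemblemaria": 3,
}
FAMILY_TOTAL_SPECIES = 89


def summarize_genus(
    profiles: Iterable[DimorphismProfile],
    genus_map: Mapping[str, str] | None = None,
    genus_totals: Mapping[str, int] | None = None,
    include_pooled: bool = True,
) -> list[GenusSummary]:
    """Per-genus summary rows, plus a pooled all-genera row.

    ``genus_map`` assigns each species to a genus; by default the genus is
    the first token of the species name.  Every species must be assigned.
    """
    profiles = list(profiles)
    if genus_totals is None:
        genus_totals = GENUS_TOTALS
    by_genus: dict[str, list[DimorphismProfile]] = {}
    for p in profiles:
        if genus_map is not None:
            if p.species not in genus_map:
                raise SummaryError(f"species without genus: {p.species!r}")
            genus = genus_map[p.species]
        else:
            genus = p.species.split()[0]
        by_genus.setdefault(genus, []).append(p)
    out = []
    for genus in sorted(by_genus):
        members = by_genus[genus]
        out.append(
            GenusSummary(
                genus=genus,
                n_included=len(members),
                n_total_in_genus=genus_totals.get(genus, len(members)),
                morphology=_stats([p.m_total for p in members]),
                coloration=_stats([p.c_total for p in members]),
                total=_stats([p.grand_total for p in members]),
            )
        )
    if include_pooled:
        out.append(
            GenusSummary(
                genus="All genera",
                n_included=len(profiles),
                n_total_in_genus=FAMILY_TOTAL_SPECIES,
                morphology=_stats([p.m_total for p in profiles]),
                coloration=_stats([p.c_total for p in profiles]),
                total=_stats([p.grand_total for p in profiles]),
            )
        )
    return out


def summaries_to_frame(summaries: Iterable[GenusSummary]) -> pd.DataFrame:
    rows = []
    for s in summaries:
        row: dict[str, object] = {
            "genus": s.genus,
            "n_included": s.n_included,
            "n_total_in_genus": s.n_total_in_genus,
        }
        for prefix, stats in (
            ("morph", s.morphology),
            ("color", s.coloration),
            ("total", s.total),
        ):
            mean, sd, lo, hi = stats
            row[f"{prefix}_mean"] = mean
            row[f"{prefix}_sd"] = sd
            row[f"{prefix}_min"] = lo
            row[f"{prefix}_max"] = hi
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Table-2-style report
# ---------------------------------------------------------------------------

_TABLE2_COLUMNS = [
    "species", *CATEGORIES[:4], "M-Total", *CATEGORIES[4:], "C-Total", "Total"
]


def table2_frame(profiles: Iterable[DimorphismProfile]) -> pd.DataFrame:
    """Count table in survey column order, rows sorted genus then species."""
    rows = []
    for p in sorted(profiles, key=lambda p: (p.species.split()[0], p.species)):
        row: dict[str, object] = {"species": p.species}
        for cat in CATEGORIES:
            row[cat] = p.category_counts[cat]
        row["M-Total"] = p.m_total
        row["C-Total"] = p.c_total
        row["Total"] = p.grand_total
        rows.append(row)
    return pd.DataFrame(rows, columns=_TABLE2_COLUMNS)


def table2_report(profiles: Iterable[DimorphismProfile]) -> str:
    """Render the per-species count table as TSV text."""
    buf = io.StringIO()
    table2_frame(profiles).to_csv(buf, sep="\t", index=False)
    return buf.getvalue()


def parse_table2_report(text: str) -> list[DimorphismProfile]:
    """Inverse of :func:`table2_report` (round-trip identity)."""
    df = pd.read_csv(io.StringIO(text), sep="\t")
    from .characters import profiles_from_counts

    return profiles_from_counts(df)
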