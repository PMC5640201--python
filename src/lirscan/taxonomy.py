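"""Baltimore <-> ICTV taxonomy reconciliation by approximate name matching.

UniProt lineage strings carry the Baltimore genome-type grouping (dsDNA,
dsRNA, ssDNA, ssRNA, reverse-transcribing), while the ICTV master species
list provides order/family/genus/species.  Species names rarely agree
character-for-character between the two sources, so reconciliation uses the
Levenshtein edit distance — the minimal number of single-character
replacements, insertions and deletions transforming one string into the
other — computed with the classic O(m*n) dynamic programme.  Names are
case-folded, whitespace-collapsed and stripped of parenthesised strain
qualifiers before comparison.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Sequence

import pandas as pd

from .errors import TaxonomyError

logger = logging.getLogger(__name__)

BALTIMORE_GROUPS = (
    "dsDNA",
    "dsRNA",
    "ssDNA",
    "ssRNA",
    "reverse-transcribing",
    "unclassified",
)
BaltimoreGroup = Literal[
    "dsDNA", "dsRNA", "ssDNA", "ssRNA", "reverse-transcribing", "unclassified"
]

# Token -> group; matched case-insensitively with no letter immediately
# before the token (so "dsrna" never fires inside another word).
_BALTIMORE_TOKENS = (
    (re.compile(r"(?<![a-z])(retro|reverse)[ -]?transcribing", re.I), "reverse-transcribing"),
    (re.compile(r"(?<![a-z])dsdna", re.I), "dsDNA"),
    (re.compile(r"(?<![a-z])dsrna", re.I), "dsRNA"),
    (re.compile(r"(?<![a-z])ssdna", re.I), "ssDNA"),
    (re.compile(r"(?<![a-z])ssrna", re.I), "ssRNA"),
)


@dataclass(frozen=True)
class IctvRecord:
    """One row of the ICTV master species list."""

    species: str
    genus: str = ""
    family: str = ""
    subfamily: str = ""
    order: str = ""

    def __post_init__(self) -> None:
        if not self.species:
            raise TaxonomyError("ICTV record with empty species name")


@dataclass(frozen=True)
class TaxonAssignment:
    """Result of reconciling one query name against the ICTV list."""

    query: str
    matched: IctvRecord | None
    edit_distance: int | None
    baltimore: BaltimoreGroup
    method: Literal["exact", "approximate", "unmatched"]


def levenshtein(a: str, b: str) -> int:
    """Edit distance between two strings (symmetric; d('', b) = len(b)).

    Two-row dynamic programme, O(len(a) * len(b)) time, O(min) memory.
    """
    if len(a) < len(b):
        a, b = b, a
    if not b:
        return len(a)
    previous = list(range(len(b) + 1))
    for i, ca in enumerate(a, start=1):
        current = [i]
        for j, cb in enumerate(b, start=1):
            current.append(
                min(
                    previous[j] + 1,        # deletion
                    current[j - 1] + 1,     # insertion
                    previous[j - 1] + (ca != cb),  # substitution
                )
            )
        previous = current
    return previous[-1]


_WS = re.compile(r"\s+")
_PARENS = re.compile(r"\s*\([^)]*\)")


def normalize_name(name: str) -> str:
    """Case-fold, collapse whitespace, drop parenthesised strain qualifiers."""
    name = _PARENS.sub("", name)
    return _WS.sub(" ", name).strip().casefold()


def match_species(
    query: str,
    ictv_list: Sequence[IctvRecord],
    max_distance: int = 2,
) -> TaxonAssignment:
    """Best ICTV record for a species name.

    Exact match (after normalisation) wins; otherwise the minimal-distance
    candidate within ``max_distance``, ties broken by lexicographic species
    name; otherwise unmatched.  Deterministic and idempotent.
    """
    if not query or not query.strip():
        raise TaxonomyError("empty query name")
    if not ictv_list:
        raise TaxonomyError("empty ICTV list")
    if max_distance < 0:
        raise TaxonomyError(f"max_distance must be >= 0, got {max_distance}")

    q = normalize_name(query)
    best: IctvRecord | None = None
    best_d = None
    for rec in ictv_list:
        d = levenshtein(q, normalize_name(rec.species))
        if d == 0:
            return TaxonAssignment(
                query=query, matched=rec, edit_distance=0,
                baltimore="unclassified", method="exact",
            )
        if d <= max_distance and (
            best_d is None
            or d < best_d
            or (d == best_d and best is not None and rec.species < best.species)
        ):
            best, best_d = rec, d
    if best is None:
        return TaxonAssignment(
            query=query, matched=None, edit_distance=None,
            baltimore="unclassified", method="unmatched",
        )
    return TaxonAssignment(
        query=query, matched=best, edit_distance=int(best_d),
        baltimore="unclassified", method="approximate",
    )


def assign_baltimore(lineage: str) -> BaltimoreGroup:
    """Baltimore group from a semicolon-delimited lineage string.

    Keyword-based: the first genome-type token found wins (reverse-
    transcribing checked first so 'Retro-transcribing viruses' never falls
    through to an RNA group); no token -> 'unclassified'.
    """
    if not lineage:
        return "unclassified"
    for pattern, group in _BALTIMORE_TOKENS:
        if pattern.search(lineage):
            return group
    logger.info("no Baltimore token in lineage %r", lineage)
    return "unclassified"


def load_ictv(path: str | Path) -> list[IctvRecord]:
    """Read an ICTV species list from CSV/TSV.

    Expects headers (any case) among: order, family, subfamily, genus,
    species; only species is mandatory.  The delimiter is sniffed.
    """
    df = pd.read_csv(path, sep=None, engine="python", dtype=str).fillna("")
    df.columns = [c.strip().lower() for c in df.columns]
    if "species" not in df.columns:
        raise TaxonomyError(f"no 'species' column in {path}")
    records = []
    for _, row in df.iterrows():
        if not str(row["species"]).strip():
            continue
        records.append(
            IctvRecord(
                species=str(row["species"]).strip(),
                genus=str(row.get("genus", "")).strip(),
                family=str(row.get("family", "")).strip(),
                subfamily=str(row.get("subfamily", "")).strip(),
                order=str(row.get("order", "")).strip(),
            )
        )
    if not records:
        raise TaxonomyError(f"no species rows in {path}")
    return records


def reconcile(
    names: Sequence[str],
    ictv_list: Sequence[IctvRecord],
    lineages: Sequence[str] | None = None,
    max_distance: int = 2,
) -> pd.DataFrame:
    """Assign every query name; returns the assignment table.

    Columns: query, matched_species, distance, method, family, genus,
    baltimore.  ``lineages`` (parallel to ``names``) feeds the Baltimore
    column; otherwise every row is 'unclassified'.
    """
    if lineages is not None and len(lineages) != len(names):
        raise TaxonomyError("lineages must parallel names")
    rows = []
    for i, name in enumerate(names):
        a = match_species(name, ictv_list, max_distance=max_distance)
        baltimore = assign_baltimore(lineages[i]) if lineages is not None else a.baltimore
        rows.append(
            {
                "query": name,
                "matched_species": a.matched.species if a.matched else "",
                "distance": a.edit_distance,
                "method": a.method,
                "family": a.matched.family if a.matched else "",
                "genus": a.matched.genus if a.matched else "",
                "baltimore": baltimore,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "query", "matched_species", "distance", "method",
            "family", "genus", "baltimore",
        ],
    )
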