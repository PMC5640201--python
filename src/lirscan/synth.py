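"""Deterministic synthetic fixtures with known ground truth.

Three generators cover the package's test surface without any downloads:

* :func:`generate_proteome` — proteins with planted LIR windows.  In
  *inert* background mode the sequence alphabet excludes the aromatic
  residues W, F and Y, so no core motif can arise outside the planted
  windows and the truth table is exact by construction; *full* mode samples
  all 20 residues and the truth table is computed by an exhaustive window
  scan of the generated sequences.
* :func:`generate_enrichment_cohort` — binary LIRCP labels for a subset
  enriched by a chosen fold over a baseline rate.
* :func:`generate_taxa` — an ICTV-style species table plus query names with
  typos introduced at a controlled edit distance.

All generators draw from ``numpy.random.default_rng`` (the PCG64 stream,
stable across platforms), so identical spec + seed gives byte-identical
output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .enrichment import EnrichmentResult, hypergeometric_enrichment
from .errors import FixtureError
from .patterns import AMINO_ACIDS, classify_window
from .taxonomy import levenshtein

#: 17 standard residues: the 20 minus the aromatics W, F, Y.
INERT_ALPHABET = "".join(sorted(set(AMINO_ACIDS) - set("WFY")))


@dataclass(frozen=True)
class PlantedMotif:
    """One window to embed: protein index, 1-based position, sequence."""

    protein_index: int
    position: int
    window: str


@dataclass(frozen=True)
class FixtureSpec:
    """Recipe for a synthetic proteome."""

    n_proteins: int
    min_length: int = 80
    max_length: int = 200
    planted: tuple[PlantedMotif, ...] = ()
    background: str = "inert"  # "inert" | "full"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_proteins < 0:
            raise FixtureError("n_proteins must be >= 0")
        if self.min_length < 6 or self.max_length < self.min_length:
            raise FixtureError("need 6 <= min_length <= max_length")
        if self.background not in ("inert", "full"):
            raise FixtureError(f"unknown background mode {self.background!r}")


def _truth_scan(pid: str, seq: str) -> list[dict]:
    """Exhaustive per-window oracle: every core occurrence, classified."""
    rows = []
    n = len(seq)
    for i in range(n - 3):
        if seq[i] not in "WFY" or seq[i + 3] not in "ILV":
            continue
        w_start = max(0, i - 2)
        window = seq[w_start : i + 4]
        truncated = i < 2
        pclass = "WxxL" if truncated else classify_window(window)
        rows.append(
            {
                "protein_id": pid,
                "start": w_start + 1,
                "end": i + 4,
                "window": window,
                "pattern_class": pclass,
                "subtype": seq[i],
                "truncated": truncated,
            }
        )
    return rows


def generate_proteome(spec: FixtureSpec) -> tuple[str, pd.DataFrame]:
    """Build FASTA text and the exact truth table for a fixture spec.

    Planted windows are written at their 1-based positions over a random
    background.  Overlapping planted windows raise
    :class:`~lirscan.errors.FixtureError`, as does an inert-mode plant
    whose own residues would create a core outside the intended one (an
    extra aromatic that pairs with a downstream I/L/V, say): the inert
    guarantee is that the truth table equals the planted list exactly.
    """
    rng = np.random.default_rng(spec.seed)
    alphabet = INERT_ALPHABET if spec.background == "inert" else AMINO_ACIDS
    letters = np.array(list(alphabet))

    by_protein: dict[int, list[PlantedMotif]] = {}
    for pm in spec.planted:
        if not (0 <= pm.protein_index < spec.n_proteins):
            raise FixtureError(f"planted motif on missing protein {pm.protein_index}")
        by_protein.setdefault(pm.protein_index, []).append(pm)

    fasta_lines: list[str] = []
    truth_rows: list[dict] = []
    for idx in range(spec.n_proteins):
        length = int(rng.integers(spec.min_length, spec.max_length + 1))
        seq = list("".join(rng.choice(letters, size=length)))
        occupied: set[int] = set()
        for pm in sorted(by_protein.get(idx, []), key=lambda p: p.position):
            start0 = pm.position - 1
            end0 = start0 + len(pm.window)
            if start0 < 0 or end0 > length:
                raise FixtureError(
                    f"planted window {pm.window!r} at {pm.position} exceeds "
                    f"protein {idx} of length {length}"
                )
            span = set(range(start0, end0))
            if span & occupied:
                raise FixtureError(
                    f"planted windows overlap at protein {idx}, position {pm.position}"
                )
            occupied |= span
            seq[start0:end0] = list(pm.window.upper())
        pid = f"SYN{idx:05d}"
        sequence = "".join(seq)
        fasta_lines.append(f">{pid} synthetic fixture protein {idx}")
        fasta_lines.append(sequence)
        scan_rows = _truth_scan(pid, sequence)
        if spec.background == "inert":
            expected = {
                (pm.position, pm.position + len(pm.window) - 1)
                for pm in by_protein.get(idx, [])
            }
            found = {(r["start"], r["end"]) for r in scan_rows}
            if found != expected:
                raise FixtureError(
                    f"inert-mode fixture for protein {idx} yields cores "
                    f"{sorted(found)} but planted spans are {sorted(expected)}; "
                    "a planted window must not contain stray aromatics"
                )
        truth_rows.extend(scan_rows)

    fasta = "\n".join(fasta_lines) + ("\n" if fasta_lines else "")
    truth = pd.DataFrame(
        truth_rows,
        columns=[
            "protein_id", "start", "end", "window",
            "pattern_class", "subtype", "truncated",
        ],
    )
    return fasta, truth


def generate_enrichment_cohort(
    n_universe: int,
    n_subset: int,
    baseline_rate: float,
    fold: float,
    seed: int = 0,
) -> tuple[pd.DataFrame, EnrichmentResult]:
    """Binary LIRCP labels with the subset enriched ``fold``-times.

    ``fold`` is the *measured* quantity ``(k/n) / (K/N)`` — the subset's
    LIRCP rate against the whole universe, subset included.  Proteins
    outside the subset carry probability ``baseline_rate``; the subset rate
    ``s`` is solved from the expected-fold identity::

        s / [ (n s + (N - n) b) / N ] = fold
        =>  s = fold * b * (N - n) / (N - fold * n)

    Returns the per-protein table (protein_id, group in {subset, rest},
    is_lircp) and the realised :class:`EnrichmentResult` of the subset
    against the universe.
    """
    if not (0 <= n_subset <= n_universe):
        raise FixtureError("need 0 <= n_subset <= n_universe")
    if not (0.0 <= baseline_rate <= 1.0):
        raise FixtureError("baseline_rate must be in [0, 1]")
    if fold < 0:
        raise FixtureError(f"fold must be >= 0, got {fold}")
    if n_subset == n_universe or fold == 1.0:
        subset_rate = baseline_rate  # subset == universe forces fold 1
        if fold != 1.0 and n_subset == n_universe and n_universe > 0:
            raise FixtureError("subset equal to the universe pins the fold at 1")
    else:
        denom = n_universe - fold * n_subset
        if denom <= 0:
            raise FixtureError(
                f"infeasible fold {fold}: subset of {n_subset} cannot be "
                f"{fold}-fold enriched within a universe of {n_universe}"
            )
        subset_rate = fold * baseline_rate * (n_universe - n_subset) / denom
        if subset_rate > 1.0:
            raise FixtureError(
                f"infeasible fold {fold} at baseline {baseline_rate}: "
                f"implied subset rate {subset_rate:.3f} exceeds 1"
            )
    rng = np.random.default_rng(seed)
    group = np.array(["subset"] * n_subset + ["rest"] * (n_universe - n_subset))
    rate = np.where(group == "subset", subset_rate, baseline_rate)
    labels = rng.random(n_universe) < rate
    table = pd.DataFrame(
        {
            "protein_id": [f"P{i:06d}" for i in range(n_universe)],
            "group": group,
            "is_lircp": labels,
        }
    )
    realised = hypergeometric_enrichment(
        k=int(labels[:n_subset].sum()),
        n=n_subset,
        K=int(labels.sum()),
        N=n_universe,
    )
    return table, realised


_SYLLABLES = [
    "ba", "ce", "di", "fo", "gu", "ha", "ki", "lo", "mu", "ne",
    "pa", "qui", "ro", "su", "ta", "ve", "xo", "za", "thi", "bre",
]


def _random_name(rng: np.random.Generator) -> str:
    genus = "".join(rng.choice(_SYLLABLES, size=int(rng.integers(3, 5)))).capitalize()
    epithet = "".join(rng.choice(_SYLLABLES, size=int(rng.integers(3, 5))))
    return f"{genus} {epithet} virus"


def _make_typo(name: str, distance: int, rng: np.random.Generator) -> str:
    """Apply exactly ``distance`` substitutions at distinct positions."""
    chars = list(name)
    positions = [i for i, c in enumerate(chars) if c.isalpha()]
    picks = rng.choice(len(positions), size=distance, replace=False)
    lowers = "abcdefghijklmnopqrstuvwxyz"
    for p in picks:
        i = positions[int(p)]
        old = chars[i].lower()
        choices = [c for c in lowers if c != old]
        chars[i] = choices[int(rng.integers(len(choices)))]
    return "".join(chars)


def generate_taxa(
    n_species: int,
    typo_rate: float = 0.3,
    max_typo_distance: int = 1,
    seed: int = 0,
) -> tuple[pd.DataFrame, list[str], dict[str, str]]:
    """ICTV-style species table, query names, and the query -> species truth.

    Species names are drawn pairwise far apart (normalised edit distance
    > 2 * max_typo_distance) so that a typo of up to ``max_typo_distance``
    edits keeps its source as the unique nearest neighbour.  A fraction
    ``typo_rate`` of queries receive exactly ``max_typo_distance``
    substitutions (verified against :func:`~lirscan.taxonomy.levenshtein`,
    redrawn if an edit shortcut exists).
    """
    if max_typo_distance < 1:
        raise FixtureError("max_typo_distance must be >= 1")
    if not (0.0 <= typo_rate <= 1.0):
        raise FixtureError("typo_rate must be in [0, 1]")
    rng = np.random.default_rng(seed)
    names: list[str] = []
    guard = 2 * max_typo_distance
    attempts = 0
    while len(names) < n_species:
        attempts += 1
        if attempts > 100 * max(n_species, 1):
            raise FixtureError("could not draw well-separated species names")
        cand = _random_name(rng)
        if all(levenshtein(cand.casefold(), o.casefold()) > guard for o in names):
            names.append(cand)

    families = [f"{n.split()[0]}idae" for n in names]
    ictv = pd.DataFrame(
        {
            "order": ["Synthvirales"] * n_species,
            "family": families,
            "subfamily": [""] * n_species,
            "genus": [n.split()[0] for n in names],
            "species": names,
        }
    )
    queries: list[str] = []
    truth: dict[str, str] = {}
    for name in names:
        if rng.random() < typo_rate:
            while True:
                q = _make_typo(name, max_typo_distance, rng)
                if levenshtein(q.casefold(), name.casefold()) == max_typo_distance:
                    break
        else:
            q = name
        queries.append(q)
        truth[q] = name
    return ictv, queries, truth
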