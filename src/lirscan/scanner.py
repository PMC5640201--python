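"""Proteome scanning: coordinate-resolved LIR motif hits and summaries.

Every occurrence of the 4-residue core (aromatic residue with I/L/V three
positions downstream) yields one hit.  The reported window is the 6-mer with
the aromatic at position 3, i.e. two residues of upstream context plus the
core; when the core sits within the first two residues of the sequence the
window is truncated to 4 or 5 residues and flagged.  Coordinates are 1-based
inclusive throughout, matching the convention of published motif spans.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Literal, Sequence

import pandas as pd
from Bio import SeqIO

from .errors import (
    DuplicateIdError,
    EmptySequenceError,
    FileFormatError,
    IntervalError,
    LirScanError,
)
from .patterns import (
    _AA_SET,
    ConsensusPattern,
    PatternClass,
    Subtype,
    classify_window,
    default_pattern,
)
from .pssm import Pssm, score_window

logger = logging.getLogger(__name__)

DisorderState = Literal[True, False, "unknown"]

#: Column order of the exported hit table.
HIT_COLUMNS = [
    "accession",
    "start",
    "end",
    "motif",
    "pssm_score",
    "pattern_class",
    "subtype",
    "anchor_flag",
    "protein_name",
    "species",
]


@dataclass(frozen=True)
class ProteinRecord:
    """One protein to scan: accession, description, sequence, taxonomy."""

    id: str
    sequence: str
    description: str = ""
    organism: str = ""
    lineage: str = ""

    def __post_init__(self) -> None:
        if not self.sequence:
            raise EmptySequenceError(f"protein {self.id!r} has an empty sequence")


@dataclass(frozen=True)
class MotifHit:
    """One detected LIR window on one protein (1-based inclusive span)."""

    protein_id: str
    start: int
    end: int
    window: str
    pattern_class: PatternClass
    subtype: Subtype
    pssm_score: float
    in_disorder: DisorderState = "unknown"
    truncated: bool = False


@dataclass(frozen=True)
class ProteinSummary:
    """Per-protein motif counts and the four-way category."""

    protein_id: str
    n_xlir: int
    n_wxxl: int
    category: Literal["both", "xlir_only", "wxxl_only", "none"]

    @property
    def motifs_total(self) -> int:
        return self.n_xlir + self.n_wxxl


def _validate_intervals(
    intervals: Sequence[tuple[int, int]], seq_len: int | None = None
) -> None:
    prev_end = 0
    for start, end in intervals:
        if start < 1 or end < start:
            raise IntervalError(f"bad interval [{start}, {end}]")
        if start <= prev_end:
            raise IntervalError(
                f"intervals must be sorted and non-overlapping near [{start}, {end}]"
            )
        if seq_len is not None and end > seq_len:
            raise IntervalError(
                f"interval [{start}, {end}] exceeds sequence length {seq_len}"
            )
        prev_end = end


def annotate_disorder(
    hit: MotifHit, intervals: Sequence[tuple[int, int]] | None
) -> MotifHit:
    """Set ``in_disorder``: True iff the whole window lies inside one interval.

    Intervals are 1-based inclusive, sorted, non-overlapping.  With no
    intervals the flag is ``"unknown"``.
    """
    if intervals is None:
        return replace(hit, in_disorder="unknown")
    _validate_intervals(intervals)
    contained = any(s <= hit.start and hit.end <= e for s, e in intervals)
    return replace(hit, in_disorder=contained)


def scan_sequence(
    record: ProteinRecord,
    pattern: ConsensusPattern | None = None,
    pssm: Pssm | None = None,
    disorder: Sequence[tuple[int, int]] | None = None,
) -> list[MotifHit]:
    """All LIR hits in one protein, sorted by start (xLIR before WxxL on ties).

    One hit per core occurrence: index ``i`` (0-based) with an aromatic
    residue and I/L/V at ``i + 3``.  Windows containing non-standard
    residues (X, B, Z, U, O, J ...) are skipped with a logged warning rather
    than aborting the scan.  ``pssm_score`` is NaN when no matrix is given
    or the window is truncated.
    """
    pattern = pattern or default_pattern()
    seq = record.sequence.upper()
    n = len(seq)
    if disorder is not None:
        _validate_intervals(disorder, seq_len=n)
    aromatic = pattern.core_positions[0]
    aliphatic = pattern.core_positions[3]

    hits: list[MotifHit] = []
    for i in range(n - 3):
        if seq[i] not in aromatic or seq[i + 3] not in aliphatic:
            continue
        w_start = max(0, i - 2)
        window = seq[w_start : i + 4]
        if any(ch not in _AA_SET for ch in window):
            logger.warning(
                "skipping window %s at %d-%d of %s: non-standard residue",
                window, w_start + 1, i + 4, record.id,
            )
            continue
        truncated = i < 2
        if truncated:
            pclass: PatternClass = "WxxL"
        else:
            pclass = classify_window(window, pattern)  # core matched => not None
        score = math.nan
        if pssm is not None and not truncated:
            score = score_window(pssm, window)
        hit = MotifHit(
            protein_id=record.id,
            start=w_start + 1,
            end=i + 4,
            window=window,
            pattern_class=pclass,
            subtype=seq[i],  # type: ignore[arg-type]
            pssm_score=score,
            truncated=truncated,
        )
        hits.append(annotate_disorder(hit, disorder))
    hits.sort(key=lambda h: (h.start, 0 if h.pattern_class == "xLIR" else 1))
    return hits


def summarize_protein(
    protein_id: str, hits: Iterable[MotifHit]
) -> ProteinSummary:
    """Count hits by class and assign the four-way category."""
    n_xlir = n_wxxl = 0
    for h in hits:
        if h.protein_id != protein_id:
            raise LirScanError(
                f"hit for {h.protein_id!r} passed to summary of {protein_id!r}"
            )
        if h.pattern_class == "xLIR":
            n_xlir += 1
        else:
            n_wxxl += 1
    if n_xlir and n_wxxl:
        category = "both"
    elif n_xlir:
        category = "xlir_only"
    elif n_wxxl:
        category = "wxxl_only"
    else:
        category = "none"
    return ProteinSummary(protein_id, n_xlir, n_wxxl, category)


def _parse_uniprot_description(description: str) -> tuple[str, str]:
    """Best-effort (protein_name, organism) from a UniProt-style header."""
    name, organism = description, ""
    if " OS=" in description:
        name, _, rest = description.partition(" OS=")
        organism = rest.split(" OX=")[0].split(" GN=")[0].split(" PE=")[0].strip()
    return name.strip(), organism


def read_disorder_tsv(path: str | Path) -> dict[str, list[tuple[int, int]]]:
    """Read disorder intervals: TSV columns protein_id, start, end (1-based
    inclusive), optional header, per protein sorted on return."""
    intervals: dict[str, list[tuple[int, int]]] = {}
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if lineno == 1 and parts[:1] == ["protein_id"]:
            continue
        if len(parts) < 3:
            raise FileFormatError("expected 3 columns (protein_id, start, end)", lineno)
        try:
            start, end = int(parts[1]), int(parts[2])
        except ValueError as exc:
            raise FileFormatError(f"non-integer coordinate: {exc}", lineno) from exc
        intervals.setdefault(parts[0], []).append((start, end))
    for pid, ivals in intervals.items():
        ivals.sort()
        _validate_intervals(ivals)
    return intervals


def hits_to_frame(
    hits: Iterable[MotifHit],
    records: dict[str, ProteinRecord] | None = None,
) -> pd.DataFrame:
    """Tabulate hits with the exported column order (:data:`HIT_COLUMNS`)."""
    rows = []
    for h in hits:
        name = species = ""
        if records and h.protein_id in records:
            rec = records[h.protein_id]
            name, parsed_org = _parse_uniprot_description(rec.description)
            species = rec.organism or parsed_org
        rows.append(
            {
                "accession": h.protein_id,
                "start": h.start,
                "end": h.end,
                "motif": h.window,
                "pssm_score": h.pssm_score,
                "pattern_class": h.pattern_class,
                "subtype": h.subtype,
                "anchor_flag": h.in_disorder,
                "protein_name": name,
                "species": species,
            }
        )
    return pd.DataFrame(rows, columns=HIT_COLUMNS)


def summaries_to_frame(summaries: Iterable[ProteinSummary]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "protein_id": s.protein_id,
                "n_xlir": s.n_xlir,
                "n_wxxl": s.n_wxxl,
                "motifs_total": s.motifs_total,
                "category": s.category,
            }
            for s in summaries
        ],
        columns=["protein_id", "n_xlir", "n_wxxl", "motifs_total", "category"],
    )


def read_fasta(path: str | Path) -> list[ProteinRecord]:
    """Parse a multi-record FASTA into :class:`ProteinRecord` objects."""
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    for seq_record in SeqIO.parse(str(path), "fasta"):
        if seq_record.id in seen:
            raise DuplicateIdError(f"duplicate record id {seq_record.id!r}")
        seen.add(seq_record.id)
        records.append(
            ProteinRecord(
                id=seq_record.id,
                description=seq_record.description,
                sequence=str(seq_record.seq).upper(),
            )
        )
    return records


def scan_fasta(
    path: str | Path,
    pattern: ConsensusPattern | None = None,
    pssm: Pssm | None = None,
    disorder_path: str | Path | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Scan every record of a FASTA file.

    Returns ``(hit_table, summary_table)`` in deterministic order: records
    in file order, hits by coordinate within each record.  An empty FASTA
    yields two empty frames.
    """
    records = read_fasta(path)
    disorder = read_disorder_tsv(disorder_path) if disorder_path else {}
    all_hits: list[MotifHit] = []
    summaries: list[ProteinSummary] = []
    by_id: dict[str, ProteinRecord] = {}
    for rec in records:
        by_id[rec.id] = rec
        hits = scan_sequence(
            rec,
            pattern=pattern,
            pssm=pssm,
            disorder=disorder.get(rec.id) if disorder_path else None,
        )
        all_hits.extend(hits)
        summaries.append(summarize_protein(rec.id, hits))
    return hits_to_frame(all_hits, by_id), summaries_to_frame(summaries)
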