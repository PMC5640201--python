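"""Position-specific scoring matrix (PSSM) for 6-residue LIR windows.

The matrix holds natural-log odds of observing residue *r* at window
position *p* in verified LIR motifs against a background model::

    score[p][r] = ln( (count(p, r) + alpha * bg[r]) / (n + alpha) / bg[r] )

where ``n`` is the number of training windows and ``alpha`` a Laplace-style
pseudocount (default 1, uniform background).  With ``alpha = 0`` an unseen
residue has log-odds of minus infinity; such cells are stored as the finite
sentinel :data:`NEG_SENTINEL` so that window scores remain well defined.

A small curated training set of canonical LIR windows is bundled as a
replaceable TSV resource; see :func:`load_training_set`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Sequence

import numpy as np

from .errors import (
    BackgroundError,
    FileFormatError,
    InvalidResidueError,
    TrainingSetError,
)
from .patterns import AMINO_ACIDS, _check_window

#: Finite stand-in for a -inf log-odds cell (alpha = 0, count = 0).
NEG_SENTINEL = -99.0

_AA_INDEX = {aa: i for i, aa in enumerate(AMINO_ACIDS)}
WINDOW_LENGTH = 6


@dataclass(frozen=True)
class TrainingSet:
    """Verified LIR 6-mers plus a source label per motif."""

    motifs: tuple[str, ...]
    sources: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not self.motifs:
            raise TrainingSetError("training set is empty")
        for m in self.motifs:
            w = _check_window(m, WINDOW_LENGTH)
            if w[2] not in "WFY":
                raise TrainingSetError(
                    f"training window {m!r} lacks an aromatic at position 3"
                )
        if self.sources and len(self.sources) != len(self.motifs):
            raise TrainingSetError("sources and motifs differ in length")

    def __len__(self) -> int:
        return len(self.motifs)


def load_training_set(path: str | Path | None = None) -> TrainingSet:
    """Read a training TSV (columns: window, source_protein, organism).

    ``#`` lines are comments.  With no path, the bundled default set is
    returned.
    """
    if path is None:
        text = (resources.files("lirscan.data") / "lir_training_set.tsv").read_text()
    else:
        text = Path(path).read_text()
    motifs: list[str] = []
    sources: list[str] = []
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if not parts[0]:
            raise FileFormatError("empty window field", line=lineno)
        motifs.append(parts[0].upper())
        sources.append(parts[1] if len(parts) > 1 else "")
    return TrainingSet(motifs=tuple(motifs), sources=tuple(sources))


def uniform_background() -> np.ndarray:
    """Flat frequency 1/20 for each standard residue."""
    return np.full(20, 1.0 / 20.0)


@dataclass(frozen=True)
class Pssm:
    """6x20 log-odds matrix with its background model and pseudocount.

    ``scores[p, r]`` is indexed by window position ``p`` (0-based) and the
    residue order of :data:`~lirscan.patterns.AMINO_ACIDS`.
    """

    scores: np.ndarray
    background: np.ndarray
    pseudocount: float
    training_n: int
    alphabet: str = field(default=AMINO_ACIDS)

    def score_of(self, position: int, residue: str) -> float:
        return float(self.scores[position, _AA_INDEX[residue]])

    @property
    def consensus(self) -> str:
        """Highest-scoring residue at each position (ties: alphabet order)."""
        return "".join(
            self.alphabet[int(np.argmax(self.scores[p]))]
            for p in range(WINDOW_LENGTH)
        )

    def to_tsv(self, path: str | Path) -> None:
        """Write the matrix as TSV: header row of residues, one row per
        position, preceded by ``#`` metadata lines."""
        lines = [
            f"# pseudocount\t{self.pseudocount}",
            f"# training_n\t{self.training_n}",
            "# background\t" + "\t".join(f"{b:.10g}" for b in self.background),
            "position\t" + "\t".join(self.alphabet),
        ]
        for p in range(WINDOW_LENGTH):
            lines.append(
                f"{p + 1}\t" + "\t".join(f"{v:.10g}" for v in self.scores[p])
            )
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "Pssm":
        """Inverse of :meth:`to_tsv`."""
        pseudocount = 1.0
        training_n = 0
        background = uniform_background()
        rows: list[list[float]] = []
        alphabet = AMINO_ACIDS
        for lineno, raw in enumerate(Path(path).read_text().splitlines(), 1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith("# pseudocount"):
                pseudocount = float(line.split("\t")[1])
            elif line.startswith("# training_n"):
                training_n = int(line.split("\t")[1])
            elif line.startswith("# background"):
                background = np.array([float(x) for x in line.split("\t")[1:]])
            elif line.startswith("#"):
                continue
            elif line.startswith("position"):
                alphabet = "".join(line.split("\t")[1:])
            else:
                parts = line.split("\t")
                if len(parts) != 21:
                    raise FileFormatError(
                        f"expected 21 columns, got {len(parts)}", line=lineno
                    )
                rows.append([float(x) for x in parts[1:]])
        if len(rows) != WINDOW_LENGTH:
            raise FileFormatError(f"expected 6 matrix rows, got {len(rows)}")
        return cls(
            scores=np.array(rows),
            background=background,
            pseudocount=pseudocount,
            training_n=training_n,
            alphabet=alphabet,
        )


def build_pssm(
    training: TrainingSet | Sequence[str],
    background: np.ndarray | None = None,
    pseudocount: float = 1.0,
) -> Pssm:
    """Estimate the log-odds matrix from training windows.

    Parameters
    ----------
    training
        A :class:`TrainingSet` or a plain sequence of 6-mers.
    background
        Length-20 strictly positive frequencies summing to 1 (residue order
        of :data:`~lirscan.patterns.AMINO_ACIDS`); uniform by default.
    pseudocount
        Non-negative smoothing weight ``alpha``; each position's counts are
        augmented by ``alpha * background``.
    """
    if not isinstance(training, TrainingSet):
        training = TrainingSet(motifs=tuple(training))
    if pseudocount < 0:
        raise TrainingSetError(f"pseudocount must be >= 0, got {pseudocount}")
    if background is None:
        background = uniform_background()
    background = np.asarray(background, dtype=float)
    if background.shape != (20,):
        raise BackgroundError(f"background must have 20 entries, got {background.shape}")
    if np.any(background <= 0):
        raise BackgroundError("background frequencies must be strictly positive")
    if not math.isclose(float(background.sum()), 1.0, rel_tol=0, abs_tol=1e-9):
        raise BackgroundError("background frequencies must sum to 1")

    n = len(training)
    counts = np.zeros((WINDOW_LENGTH, 20))
    for motif in training.motifs:
        for p, residue in enumerate(motif):
            counts[p, _AA_INDEX[residue]] += 1.0

    freqs = (counts + pseudocount * background[None, :]) / (n + pseudocount)
    with np.errstate(divide="ignore"):
        scores = np.log(freqs / background[None, :])
    scores[np.isneginf(scores)] = NEG_SENTINEL
    return Pssm(
        scores=scores,
        background=background,
        pseudocount=float(pseudocount),
        training_n=n,
    )


def score_window(pssm: Pssm, hexapeptide: str) -> float:
    """Sum of per-position log-odds for a 6-mer.

    Raises :class:`~lirscan.errors.InvalidResidueError` on non-standard
    residues (the score is undefined there; callers scanning whole proteomes
    skip such windows instead).
    """
    window = _check_window(hexapeptide, WINDOW_LENGTH)
    return sum(pssm.score_of(p, r) for p, r in enumerate(window))


def display_score(score: float) -> int:
    """Integer display value: rounded half away from zero."""
    if math.isnan(score):
        raise InvalidResidueError("?", context="cannot display a NaN score")
    return int(math.floor(score + 0.5)) if score >= 0 else int(math.ceil(score - 0.5))
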