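"""Consensus patterns for canonical LC3-interacting region (LIR) motifs.

Two patterns are shipped as plain-text resource files and loaded at import:

* **xLIR** — the extended 6-residue consensus
  ``[ADEFGLPRSK][DEGMSTV][WFY][DEILQTV][ADEFHIKLMPSTV][ILV]``, in which
  positions 3 (aromatic) and 6 (aliphatic) anchor the interaction with
  Atg8-family proteins.
* **WxxL** — the relaxed 4-residue core ``W/F/Y-x-x-I/L/V``.

Windows are classified with the aromatic residue at window position 3, i.e.
a 6-mer is two residues of upstream context followed by the 4-residue core.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Literal

from .errors import InvalidResidueError, InvalidWindowError, NotAMotifError

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
_AA_SET = frozenset(AMINO_ACIDS)

PatternClass = Literal["xLIR", "WxxL"]
Subtype = Literal["W", "F", "Y"]

#: Sentinel classes
XLIR: PatternClass = "xLIR"
WXXL: PatternClass = "WxxL"


def _read_pattern_lines(text: str) -> tuple[frozenset[str], ...]:
    rows = []
    for raw in text.splitlines():
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        residues = line.upper()
        bad = set(residues) - _AA_SET
        if bad:
            raise InvalidResidueError(sorted(bad)[0], context=line)
        rows.append(frozenset(residues))
    return tuple(rows)


@dataclass(frozen=True)
class ConsensusPattern:
    """Allowed-residue sets for the 6-position xLIR window and 4-position core.

    Attributes
    ----------
    positions
        Six sets of residues allowed at xLIR window positions 1-6.
    core_positions
        Four sets for the W/F/Y-x-x-I/L/V core (core position 1 = window
        position 3).
    """

    positions: tuple[frozenset[str], ...]
    core_positions: tuple[frozenset[str], ...]

    def __post_init__(self) -> None:
        if len(self.positions) != 6:
            raise InvalidWindowError(
                f"xLIR pattern needs 6 position sets, got {len(self.positions)}"
            )
        if len(self.core_positions) != 4:
            raise InvalidWindowError(
                f"core pattern needs 4 position sets, got {len(self.core_positions)}"
            )

    @classmethod
    def default(cls) -> "ConsensusPattern":
        """The bundled xLIR/WxxL pair."""
        pkg = resources.files("lirscan.data")
        return cls(
            positions=_read_pattern_lines(
                (pkg / "xlir_pattern.txt").read_text()
            ),
            core_positions=_read_pattern_lines(
                (pkg / "wxxl_core_pattern.txt").read_text()
            ),
        )

    @classmethod
    def from_files(
        cls, xlir_path: str | Path, core_path: str | Path | None = None
    ) -> "ConsensusPattern":
        """Load an alternative consensus from plain-text pattern files.

        Each file holds one line per position, the allowed residues as a
        contiguous string; ``#`` lines are comments.  When ``core_path`` is
        omitted the bundled WxxL core is used.
        """
        positions = _read_pattern_lines(Path(xlir_path).read_text())
        if core_path is None:
            core = cls.default().core_positions
        else:
            core = _read_pattern_lines(Path(core_path).read_text())
        return cls(positions=positions, core_positions=core)


_DEFAULT: ConsensusPattern | None = None


def default_pattern() -> ConsensusPattern:
    """Singleton accessor for the bundled consensus pair."""
    global _DEFAULT
    if _DEFAULT is None:
        _DEFAULT = ConsensusPattern.default()
    return _DEFAULT


def _check_window(window: str, length: int) -> str:
    if not isinstance(window, str) or len(window) != length:
        raise InvalidWindowError(
            f"expected a {length}-residue window, got {window!r}"
        )
    window = window.upper()
    for ch in window:
        if ch not in _AA_SET:
            raise InvalidResidueError(ch, context=window)
    return window


def matches_xlir(hexapeptide: str, pattern: ConsensusPattern | None = None) -> bool:
    """True iff every residue of the 6-mer lies in its xLIR position set."""
    pattern = pattern or default_pattern()
    window = _check_window(hexapeptide, 6)
    return all(r in allowed for r, allowed in zip(window, pattern.positions))


def matches_wxxl_core(
    tetrapeptide: str, pattern: ConsensusPattern | None = None
) -> bool:
    """True iff the 4-mer matches the W/F/Y-x-x-I/L/V core."""
    pattern = pattern or default_pattern()
    core = _check_window(tetrapeptide, 4)
    return all(r in allowed for r, allowed in zip(core, pattern.core_positions))


def classify_window(
    hexapeptide: str, pattern: ConsensusPattern | None = None
) -> PatternClass | None:
    """Classify a 6-mer as ``"xLIR"``, ``"WxxL"``, or ``None``.

    xLIR takes precedence; a window is never labelled both.  WxxL requires
    window positions 3-6 to match the 4-residue core.
    """
    pattern = pattern or default_pattern()
    window = _check_window(hexapeptide, 6)
    if matches_xlir(window, pattern):
        return XLIR
    if matches_wxxl_core(window[2:6], pattern):
        return WXXL
    return None


def classify_subtype(
    hexapeptide: str, pattern: ConsensusPattern | None = None
) -> Subtype:
    """W-, F- or Y-type: the aromatic residue at window position 3.

    Raises :class:`~lirscan.errors.NotAMotifError` when the window matches
    neither consensus.
    """
    pattern = pattern or default_pattern()
    window = _check_window(hexapeptide, 6)
    if classify_window(window, pattern) is None:
        raise NotAMotifError(f"{window!r} matches neither xLIR nor WxxL")
    return window[2]  # type: ignore[return-value]
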