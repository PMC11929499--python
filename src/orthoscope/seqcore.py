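"""Sequence primitives shared by every pipeline stage.

Nucleotide and protein sequence containers with strict alphabets, IUPAC
degenerate-pattern matching and scanning, and FASTA/FASTQ I/O.  Internal
coordinates are 0-based half-open throughout the package; user-facing
reports convert to 1-based inclusive at the formatting layer.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

logger = logging.getLogger(__name__)

NUC_ALPHABET = frozenset("ACGTN")
PROTEIN_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWYX")

#: IUPAC degenerate nucleotide code -> set of concrete bases.
IUPAC_CODES: dict[str, frozenset[str]] = {
    "A": frozenset("A"), "C": frozenset("C"), "G": frozenset("G"), "T": frozenset("T"),
    "R": frozenset("AG"), "Y": frozenset("CT"), "S": frozenset("CG"), "W": frozenset("AT"),
    "K": frozenset("GT"), "M": frozenset("AC"),
    "B": frozenset("CGT"), "D": frozenset("AGT"), "H": frozenset("ACT"), "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

#: Concrete base set -> IUPAC letter (inverse of IUPAC_CODES).
BASES_TO_IUPAC: dict[frozenset[str], str] = {v: k for k, v in IUPAC_CODES.items()}

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


class AlphabetError(ValueError):
    """Raised when a sequence contains characters outside its alphabet."""


@dataclass(frozen=True)
class NucSequence:
    """A named DNA sequence over {A,C,G,T,N}.

    Lowercase input is uppercased with a logged warning; anything outside
    the alphabet raises :class:`AlphabetError`.
    """

    id: str
    residues: str

    def __post_init__(self) -> None:
        res = self.residues
        if not res:
            raise AlphabetError(f"{self.id!r}: empty sequence")
        if not res.isupper() or not set(res) <= NUC_ALPHABET:
            up = res.upper()
            if set(up) <= NUC_ALPHABET:
                logger.warning("sequence %r: lowercase residues uppercased", self.id)
                object.__setattr__(self, "residues", up)
            else:
                bad = sorted(set(up) - NUC_ALPHABET)
                raise AlphabetError(f"{self.id!r}: invalid nucleotide characters {bad}")

    def __len__(self) -> int:
        return len(self.residues)

    def __getitem__(self, key) -> str:
        return self.residues[key]


@dataclass(frozen=True)
class ProteinSequence:
    """A named amino-acid sequence over the 20 standard residues plus X."""

    id: str
    residues: str

    def __post_init__(self) -> None:
        res = self.residues
        if not res:
            raise AlphabetError(f"{self.id!r}: empty sequence")
        if not res.isupper():
            logger.warning("sequence %r: lowercase residues uppercased", self.id)
            res = res.upper()
            object.__setattr__(self, "residues", res)
        if not set(res) <= PROTEIN_ALPHABET:
            bad = sorted(set(res) - PROTEIN_ALPHABET)
            raise AlphabetError(f"{self.id!r}: invalid amino-acid characters {bad}")

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class IupacPattern:
    """A degenerate nucleotide pattern over the 15-letter IUPAC alphabet."""

    letters: str

    def __post_init__(self) -> None:
        if not self.letters:
            raise AlphabetError("empty IUPAC pattern")
        up = self.letters.upper()
        if set(up) - set(IUPAC_CODES):
            bad = sorted(set(up) - set(IUPAC_CODES))
            raise AlphabetError(f"invalid IUPAC letters {bad}")
        object.__setattr__(self, "letters", up)

    def __len__(self) -> int:
        return len(self.letters)

    def base_sets(self) -> list[frozenset[str]]:
        return [IUPAC_CODES[c] for c in self.letters]


def revcomp(seq: NucSequence | str) -> NucSequence | str:
    """Reverse complement; N maps to N. Accepts and returns plain strings too."""
    if isinstance(seq, str):
        if set(seq.upper()) - NUC_ALPHABET:
            raise AlphabetError(f"invalid nucleotide characters in {seq[:20]!r}")
        return seq.upper().translate(_COMPLEMENT)[::-1]
    return NucSequence(seq.id, seq.residues.translate(_COMPLEMENT)[::-1])


def iupac_matches(
    pattern: IupacPattern | str,
    window: str,
    *,
    n_matches_nothing: bool = True,
) -> bool:
    """True iff every base of *window* lies in the corresponding pattern set.

    An ``N`` in the *data* (the window) matches nothing by default so that
    ambiguous reads never inflate PAM hit counts; pass
    ``n_matches_nothing=False`` to let data-N match any pattern letter.
    """
    if isinstance(pattern, str):
        pattern = IupacPattern(pattern)
    if len(pattern) != len(window):
        raise ValueError(
            f"pattern length {len(pattern)} != window length {len(window)}"
        )
    for letter, base in zip(pattern.letters, window):
        if base == "N":
            if n_matches_nothing:
                return False
            continue
        if base not in IUPAC_CODES[letter]:
            return False
    return True


@dataclass(frozen=True)
class IupacHit:
    """One pattern occurrence: forward-strand half-open interval + strand."""

    start: int
    end: int
    strand: str  # '+' or '-'


def scan_iupac(
    pattern: IupacPattern | str,
    seq: NucSequence | str,
    strands: str = "both",
    *,
    n_matches_nothing: bool = True,
) -> list[IupacHit]:
    """Exhaustively scan *seq* for *pattern* occurrences.

    Reverse-strand hits are reported as forward-coordinate intervals (the
    interval of sequence whose reverse complement matches the pattern).
    Hits are sorted by start, '+' before '-' at equal start.
    """
    if isinstance(pattern, str):
        pattern = IupacPattern(pattern)
    if strands not in ("both", "fwd", "rev"):
        raise ValueError(f"strands must be both|fwd|rev, got {strands!r}")
    s = seq.residues if isinstance(seq, NucSequence) else seq.upper()
    L = len(pattern)
    hits: list[IupacHit] = []
    if L > len(s):
        return hits
    pats: list[tuple[str, str]] = []
    if strands in ("both", "fwd"):
        pats.append((pattern.letters, "+"))
    if strands in ("both", "rev"):
        # Matching revcomp(pattern) on the forward strand is equivalent to
        # matching pattern on the reverse strand at the mirrored interval.
        rc = "".join(
            BASES_TO_IUPAC[frozenset(revcomp(b) for b in IUPAC_CODES[c])]
            for c in reversed(pattern.letters)
        )
        pats.append((rc, "-"))
    for i in range(len(s) - L + 1):
        window = s[i : i + L]
        for pat, strand in pats:
            if iupac_matches(pat, window, n_matches_nothing=n_matches_nothing):
                hits.append(IupacHit(i, i + L, strand))
    hits.sort(key=lambda h: (h.start, h.strand))
    return hits


# ---------------------------------------------------------------------------
# FASTA / FASTQ I/O (gzip-transparent, Sanger qualities)
# ---------------------------------------------------------------------------

class ParseError(ValueError):
    """Malformed FASTA/FASTQ record; message names the offending line."""


def _open_text(path: str | Path, mode: str = "rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def read_fasta(path: str | Path, *, protein: bool = False) -> list:
    """Read all records of a (possibly gzipped) FASTA file.

    Returns :class:`NucSequence` records, or :class:`ProteinSequence` when
    ``protein=True``.  CRLF line endings are tolerated.
    """
    cls = ProteinSequence if protein else NucSequence
    records = []
    cur_id: str | None = None
    chunks: list[str] = []
    with _open_text(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.rstrip("\r\n")
            if not line:
                continue
            if line.startswith(">"):
                if cur_id is not None:
                    records.append(cls(cur_id, "".join(chunks)))
                cur_id = line[1:].split()[0] if line[1:].split() else ""
                if not cur_id:
                    raise ParseError(f"{path}: empty FASTA header at line {lineno}")
                chunks = []
            else:
                if cur_id is None:
                    raise ParseError(
                        f"{path}: sequence before any '>' header at line {lineno}"
                    )
                chunks.append(line.strip())
        if cur_id is not None:
            records.append(cls(cur_id, "".join(chunks)))
    return records


def write_fasta(records: Iterable, path: str | Path, width: int = 70) -> None:
    """Write records (anything with .id and .residues) as FASTA."""
    with _open_text(path, "wt") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            res = rec.residues
            for i in range(0, len(res), width):
                fh.write(res[i : i + width] + "\n")


@dataclass(frozen=True)
class FastqRecord:
    """A FASTQ read: sequence plus Sanger-encoded qualities (phred+33)."""

    seq: NucSequence
    qualities: tuple[int, ...] = field(default=())


def read_fastq(path: str | Path) -> list[FastqRecord]:
    """Read a (possibly gzipped) 4-line-record FASTQ file."""
    records: list[FastqRecord] = []
    with _open_text(path) as fh:
        lines = [ln.rstrip("\r\n") for ln in fh]
    lines = [ln for ln in lines if ln]
    if len(lines) % 4:
        raise ParseError(f"{path}: truncated FASTQ (line count not divisible by 4)")
    for i in range(0, len(lines), 4):
        head, seq, plus, qual = lines[i : i + 4]
        if not head.startswith("@"):
            raise ParseError(f"{path}: expected '@' header at line {i + 1}")
        if not plus.startswith("+"):
            raise ParseError(f"{path}: expected '+' separator at line {i + 3}")
        if len(seq) != len(qual):
            raise ParseError(f"{path}: quality length mismatch at line {i + 4}")
        rid = head[1:].split()[0]
        records.append(
            FastqRecord(NucSequence(rid, seq), tuple(ord(c) - 33 for c in qual))
        )
    return records


def write_fastq(records: Iterable[FastqRecord], path: str | Path) -> None:
    with _open_text(path, "wt") as fh:
        for rec in records:
            quals = rec.qualities or tuple([40] * len(rec.seq))
            fh.write(f"@{rec.seq.id}\n{rec.seq.residues}\n+\n")
            fh.write("".join(chr(q + 33) for q in quals) + "\n")
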