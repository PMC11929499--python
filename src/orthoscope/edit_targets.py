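"""Base-editing target-space enumeration.

Given an editor definition (PAM, spacer length, editing window, chemistry)
this module scans sequences for guide sites, decides whether a single
nucleotide variant is addressable by the editor, and summarizes how much
target space a set of new editors adds over an established reference set.

Positions follow the standard base-editing convention: protospacer
positions are numbered 1..spacer_len from the 5' (PAM-distal) end and the
PAM sits immediately 3' of position spacer_len.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Literal, Mapping, Sequence

from .seqcore import IupacPattern, NucSequence, iupac_matches, revcomp

logger = logging.getLogger(__name__)

_SNV_BASES = set("ACGT")


class ConfigError(ValueError):
    pass


@dataclass(frozen=True)
class Editor:
    """A Cas9 base editor: PAM 3' of the protospacer, window, chemistry.

    ``window`` is inclusive 1-based protospacer positions (w_lo, w_hi);
    chemistry is ABE (A->G on the protospacer strand) or CBE (C->T).
    """

    name: str
    pam: IupacPattern
    window: tuple[int, int]
    spacer_len: int = 20
    chemistry: Literal["ABE", "CBE"] = "ABE"

    def __post_init__(self) -> None:
        if isinstance(self.pam, str):
            object.__setattr__(self, "pam", IupacPattern(self.pam))
        lo, hi = self.window
        if not 1 <= lo <= hi <= self.spacer_len:
            raise ConfigError(
                f"{self.name}: window {self.window} outside 1..{self.spacer_len}"
            )
        if self.chemistry not in ("ABE", "CBE"):
            raise ConfigError(f"{self.name}: chemistry must be ABE or CBE")

    @property
    def substrate(self) -> str:
        """Base edited on the protospacer strand (A for ABE, C for CBE)."""
        return "A" if self.chemistry == "ABE" else "C"

    @property
    def product(self) -> str:
        return "G" if self.chemistry == "ABE" else "T"


@dataclass(frozen=True)
class Guide:
    """A guide site: protospacer + PAM intervals in forward coordinates."""

    contig: str
    proto_start: int
    proto_end: int
    pam_start: int
    pam_end: int
    strand: str
    protospacer: str

    def protospacer_position(self, pos0: int) -> int | None:
        """1-based protospacer position of forward coordinate *pos0*."""
        if not self.proto_start <= pos0 < self.proto_end:
            return None
        if self.strand == "+":
            return pos0 - self.proto_start + 1
        return self.proto_end - pos0


@dataclass(frozen=True)
class VariantRecord:
    """A single-nucleotide variant (1-based position)."""

    contig: str
    position: int
    ref: str
    alt: str

    def __post_init__(self) -> None:
        if self.ref == self.alt:
            raise ValueError(f"{self.contig}:{self.position}: ref == alt")
        if self.ref not in _SNV_BASES or self.alt not in _SNV_BASES:
            raise ValueError(f"{self.contig}:{self.position}: not a SNV")


@dataclass(frozen=True)
class TargetSpaceSummary:
    per_editor: Mapping[str, int]
    reference_count: int
    union_count: int
    added_count: int
    undeterminable: int
    total: int


def scan_guides(
    seq: NucSequence,
    editor: Editor,
    region: tuple[int, int] | None = None,
) -> list[Guide]:
    """Exhaustively enumerate guide sites for *editor* inside *region*.

    A guide exists at every position on either strand where the PAM
    matches immediately 3' of a full-length protospacer lying inside the
    region.  Deterministic; sorted by protospacer start, '+' first.
    """
    s = seq.residues
    if region is None:
        region = (0, len(s))
    lo, hi = region
    if not 0 <= lo < hi <= len(s):
        raise ValueError(f"region {region} out of bounds for length {len(s)}")
    S, P = editor.spacer_len, len(editor.pam)
    guides: list[Guide] = []
    # forward: protospacer [i, i+S), PAM [i+S, i+S+P)
    for i in range(lo, hi - S - P + 1):
        window = s[i + S : i + S + P]
        if iupac_matches(editor.pam, window):
            guides.append(
                Guide(seq.id, i, i + S, i + S, i + S + P, "+", s[i : i + S])
            )
    # reverse: PAM forward interval [j, j+P), protospacer [j+P, j+P+S)
    for j in range(lo, hi - S - P + 1):
        window = revcomp(s[j : j + P])
        if iupac_matches(editor.pam, window):
            guides.append(
                Guide(
                    seq.id, j + P, j + P + S, j, j + P, "-",
                    revcomp(s[j + P : j + P + S]),
                )
            )
    guides.sort(key=lambda g: (g.proto_start, g.strand))
    return guides


def variant_targetable(
    variant: VariantRecord,
    context: NucSequence,
    editor: Editor,
    variant_offset: int | None = None,
    orientation: Literal["revert", "install"] = "revert",
) -> tuple[bool | str, list[Guide]]:
    """Decide whether *editor* can address *variant* inside *context*.

    Under the default ``revert`` orientation the pathogenic alt allele is
    present in the genome and editing must restore ref: the alt base must
    present the editor's substrate on some strand (genomic alt->ref equal
    to A->G or T->C for ABE; C->T or G->A for CBE) and sit at a protospacer
    window position of a PAM-validated guide.  ``install`` evaluates the
    opposite direction (ref present, editing installs alt).

    Returns (decision, supporting_guides); decision is True/False or the
    string ``"undeterminable"`` when the context lacks a full
    spacer+PAM-length flank on either side.
    """
    pos0 = (variant.position - 1) if variant_offset is None else variant_offset
    if not 0 <= pos0 < len(context):
        raise ValueError("variant position outside context")
    if context.residues[pos0] not in _SNV_BASES:
        raise ValueError("context base at variant position is ambiguous")
    need = editor.spacer_len + len(editor.pam)
    if pos0 < need or len(context) - pos0 - 1 < need:
        return "undeterminable", []

    if orientation == "revert":
        present, restored = variant.alt, variant.ref
    else:
        present, restored = variant.ref, variant.alt
    sub, prod = editor.substrate, editor.product
    fwd_ok = present == sub and restored == prod
    rev_ok = present == revcomp(sub) and restored == revcomp(prod)
    if not (fwd_ok or rev_ok):
        return False, []

    edited = (
        context.residues[:pos0] + present + context.residues[pos0 + 1 :]
    )
    eseq = NucSequence(context.id, edited)
    w_lo, w_hi = editor.window
    supporting = []
    for g in scan_guides(eseq, editor):
        if g.strand == "+" and not fwd_ok:
            continue
        if g.strand == "-" and not rev_ok:
            continue
        p = g.protospacer_position(pos0)
        if p is not None and w_lo <= p <= w_hi:
            supporting.append(g)
    return (len(supporting) > 0), supporting


def summarize_target_space(
    variants: Sequence[VariantRecord],
    contexts: Mapping[str, NucSequence],
    editors: Sequence[Editor],
    reference_set: Iterable[str],
    query_set: Iterable[str],
    orientation: Literal["revert", "install"] = "revert",
) -> TargetSpaceSummary:
    """Per-editor / union / added targetable counts over a variant table.

    ``added`` is the number of variants targetable by the query editors
    beyond those already targetable by the reference set.  Variants with
    insufficient flank for any editor are tallied as undeterminable and
    excluded from per-editor counts (never silently false).
    """
    names = [e.name for e in editors]
    if len(set(names)) != len(names):
        raise ConfigError("duplicate editor names")
    by_name = {e.name: e for e in editors}
    reference_set, query_set = list(reference_set), list(query_set)
    for n in reference_set + query_set:
        if n not in by_name:
            raise ConfigError(f"unknown editor name {n!r}")

    decisions: dict[str, set[int]] = {n: set() for n in names}
    undet: set[int] = set()
    for i, v in enumerate(variants):
        ctx = contexts[v.contig]
        for e in editors:
            d, _ = variant_targetable(v, ctx, e, orientation=orientation)
            if d == "undeterminable":
                undet.add(i)
            elif d:
                decisions[e.name].add(i)

    ref_hits = set().union(*(decisions[n] for n in reference_set)) if reference_set else set()
    qry_hits = set().union(*(decisions[n] for n in query_set)) if query_set else set()
    union = ref_hits | qry_hits
    return TargetSpaceSummary(
        per_editor={n: len(decisions[n]) for n in names},
        reference_count=len(ref_hits),
        union_count=len(union),
        added_count=len(union) - len(ref_hits),
        undeterminable=len(undet),
        total=len(variants),
    )


# ---------------------------------------------------------------------------
# Minimal VCF subset I/O (SNVs only) and a TSV alternative
# ---------------------------------------------------------------------------

def read_vcf(path: str | Path) -> list[VariantRecord]:
    """Read CHROM/POS/REF/ALT single-nucleotide records from a plain VCF.

    Non-SNV records (indels, multiallelic, symbolic) are skipped; the skip
    count is logged.
    """
    records: list[VariantRecord] = []
    skipped = 0
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 5:
                raise ValueError(f"{path}: malformed VCF line: {line[:60]!r}")
            chrom, pos, _id, ref, alt = fields[:5]
            if (
                len(ref) == 1 and len(alt) == 1
                and ref in _SNV_BASES and alt in _SNV_BASES and ref != alt
            ):
                records.append(VariantRecord(chrom, int(pos), ref, alt))
            else:
                skipped += 1
    if skipped:
        logger.info("%s: skipped %d non-SNV records", path, skipped)
    return records


def write_vcf(records: Iterable[VariantRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for v in records:
            fh.write(f"{v.contig}\t{v.position}\t.\t{v.ref}\t{v.alt}\t.\t.\t.\n")


def read_variants_tsv(path: str | Path) -> list[VariantRecord]:
    """TSV alternative: columns contig, position, ref, alt (with header)."""
    records = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        idx = {c: i for i, c in enumerate(header)}
        for line in fh:
            f = line.rstrip("\n").split("\t")
            records.append(
                VariantRecord(
                    f[idx["contig"]], int(f[idx["position"]]),
                    f[idx["ref"]], f[idx["alt"]],
                )
            )
    return records
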