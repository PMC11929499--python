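"""Seeded synthetic-data generators with machine-readable planted truth.

Every generator draws from a single ``numpy.random.default_rng(seed)``
stream, returns a :class:`TruthRecord` describing exactly what was
planted, and regenerates byte-identically for the same seed and
parameters.  Recovery tests read truth only from these records.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping, Sequence

import numpy as np

from .amplicon_quant import AmpliconRef
from .edit_targets import Editor, VariantRecord
from .pam_depletion import PamLibrary, all_kmers
from .seqcore import (
    IUPAC_CODES,
    FastqRecord,
    IupacPattern,
    NucSequence,
    ProteinSequence,
    iupac_matches,
    revcomp,
)

_BASES = "ACGT"
_AA = "ACDEFGHIKLMNPQRSTVWY"


class ConfigError(ValueError):
    pass


@dataclass(frozen=True)
class TruthRecord:
    """What a generator planted, serialized alongside its dataset."""

    generator: str
    seed: int
    params: Mapping[str, Any] = field(default_factory=dict)

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text

    @classmethod
    def from_json(cls, text: str) -> "TruthRecord":
        d = json.loads(text)
        return cls(d["generator"], d["seed"], d["params"])


def _random_dna(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list(_BASES), size=n))


def _random_protein(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list(_AA), size=n))


# ---------------------------------------------------------------------------
# Genomes with planted repeat-spacer arrays and an anti-repeat
# ---------------------------------------------------------------------------

def _sharpen_boundary(rng: np.random.Generator, genome: list[str],
                      columns: list[int]) -> None:
    """Redraw a flanking column so no base dominates it.

    The bases one position outside each planted repeat boundary are forced
    to have multiplicity <= max(1, n_copies - 2), so the planted array has
    a well-defined (unambiguous) boundary: a column that happened to agree
    across all copies would itself be part of the repeat under any
    consistent definition.
    """
    m = len(columns)
    if m < 3:
        return
    cap = max(1, m - 2)
    while True:
        bases = [genome[c] for c in columns]
        counts = {b: bases.count(b) for b in set(bases)}
        if max(counts.values()) <= cap:
            return
        worst = max(counts, key=lambda b: counts[b])
        i = bases.index(worst)
        genome[columns[i]] = str(rng.choice([b for b in _BASES if b != worst]))


def make_genome_with_array(
    seed: int,
    repeat: NucSequence | None = None,
    n_repeats: int = 4,
    repeat_len: int = 36,
    spacer_len: int = 30,
    genome_len: int = 3000,
    anti_repeat_identity: float = 100.0,
    anti_repeat_offset: int = 400,
) -> tuple[NucSequence, TruthRecord]:
    """Random genome with a planted array and a degraded anti-repeat.

    The anti-repeat (reverse complement of the repeat, degraded to the
    requested percent identity by substitutions) is planted
    *anti_repeat_offset* nt downstream of the array end, emulating the
    tracrRNA locus adjacent to a CRISPR array.
    """
    if n_repeats < 2:
        raise ConfigError("n_repeats must be >= 2")
    rng = np.random.default_rng(seed)
    rep = repeat.residues if repeat is not None else _random_dna(rng, repeat_len)
    L = len(rep)
    array_parts = [rep]
    spacers = []
    for _ in range(n_repeats - 1):
        sp = _random_dna(rng, spacer_len)
        spacers.append(sp)
        array_parts += [sp, rep]
    array = "".join(array_parts)

    anti = list(revcomp(rep))
    n_sub = round(L * (1.0 - anti_repeat_identity / 100.0))
    if n_sub:
        for i in rng.choice(L, size=n_sub, replace=False):
            anti[i] = str(rng.choice([b for b in _BASES if b != anti[i]]))
    anti = "".join(anti)

    needed = len(array) + anti_repeat_offset + L + 200
    if genome_len < needed:
        raise ConfigError(f"genome_len {genome_len} < required {needed}")
    hi = genome_len - needed + 100
    array_start = int(rng.integers(100, hi)) if hi > 100 else 100
    g = list(_random_dna(rng, genome_len))
    g[array_start : array_start + len(array)] = list(array)
    anti_start = array_start + len(array) + anti_repeat_offset
    g[anti_start : anti_start + L] = list(anti)

    period = L + spacer_len
    starts = [array_start + i * period for i in range(n_repeats)]
    for d in (1, 2):
        _sharpen_boundary(rng, g, [s - d for s in starts])
        _sharpen_boundary(rng, g, [s + L + d - 1 for s in starts])
    # boundary sharpening may touch spacer-terminal bases: record spacers
    # from the final genome so the truth matches what is actually planted
    spacers = ["".join(g[a + L : b]) for a, b in zip(starts, starts[1:])]

    genome = NucSequence(f"synthetic_contig_seed{seed}", "".join(g))
    truth = TruthRecord(
        generator="make_genome_with_array",
        seed=seed,
        params={
            "repeat": rep,
            "repeat_intervals": [[s, s + L] for s in starts],
            "spacers": spacers,
            "anti_repeat_interval": [anti_start, anti_start + L],
            "anti_repeat_identity": anti_repeat_identity,
            "genome_len": genome_len,
        },
    )
    return genome, truth


# ---------------------------------------------------------------------------
# Randomized-PAM depletion libraries
# ---------------------------------------------------------------------------

def simulate_pam_library(
    seed: int,
    true_pam: str | IupacPattern = "NNARTA",
    p_cleave_match: float = 0.95,
    p_cleave_nonmatch: float = 0.01,
    mean_depth: float = 100.0,
    k: int = 7,
) -> tuple[PamLibrary, PamLibrary, TruthRecord]:
    """Control/cleaved k-mer counts for a cleaver with a planted PAM.

    Control counts are multinomial over all 4^k k-mers at *mean_depth*
    average coverage; each control molecule survives cleavage with
    probability 1 - p_cleave, where p_cleave depends on whether the k-mer
    matches the planted PAM (padded with trailing N to length k).
    """
    if not (0 <= p_cleave_nonmatch <= p_cleave_match <= 1):
        raise ConfigError("need 0 <= p_cleave_nonmatch <= p_cleave_match <= 1")
    if mean_depth <= 0:
        raise ConfigError("mean_depth must be positive")
    pat = IupacPattern(
        (true_pam.letters if isinstance(true_pam, IupacPattern) else true_pam)
        .ljust(k, "N")
    )
    if len(pat) != k:
        raise ConfigError(f"PAM longer than k={k}")
    rng = np.random.default_rng(seed)
    kmers = all_kmers(k)
    total = int(round(mean_depth * len(kmers)))
    ctrl = rng.multinomial(total, np.full(len(kmers), 1.0 / len(kmers)))
    match = np.array([iupac_matches(pat, w) for w in kmers])
    p_surv = np.where(match, 1.0 - p_cleave_match, 1.0 - p_cleave_nonmatch)
    clv = rng.binomial(ctrl, p_surv)
    control = PamLibrary(k, dict(zip(kmers, ctrl.tolist())), "control")
    cleaved = PamLibrary(k, dict(zip(kmers, clv.tolist())), "cleaved")
    truth = TruthRecord(
        "simulate_pam_library", seed,
        {
            "true_pam": pat.letters.rstrip("N"),
            "p_cleave_match": p_cleave_match,
            "p_cleave_nonmatch": p_cleave_nonmatch,
            "mean_depth": mean_depth,
            "k": k,
        },
    )
    return control, cleaved, truth


# ---------------------------------------------------------------------------
# Amplicon reads with planted indels and base conversions
# ---------------------------------------------------------------------------

def make_amplicon_ref(
    seed: int,
    amplicon_len: int = 240,
    spacer_len: int = 20,
    pam: str = "NGG",
    substrate_positions: Sequence[int] = (),
) -> AmpliconRef:
    """Random amplicon with a forward protospacer + concrete PAM planted.

    *substrate_positions* (1-based protospacer positions) are forced to
    'A' so an adenine-editor conversion profile is observable there.
    """
    rng = np.random.default_rng(seed)
    s = list(_random_dna(rng, amplicon_len))
    proto_start = amplicon_len // 2 - spacer_len
    proto_end = proto_start + spacer_len
    pam_concrete = [str(rng.choice(sorted(IUPAC_CODES[c]))) for c in pam]
    s[proto_end : proto_end + len(pam)] = pam_concrete
    for p in substrate_positions:
        if not 1 <= p <= spacer_len:
            raise ConfigError(f"profile position {p} outside protospacer")
        s[proto_start + p - 1] = "A"
    return AmpliconRef(
        sequence=NucSequence(f"synthetic_amplicon_seed{seed}", "".join(s)),
        proto_start=proto_start,
        proto_end=proto_end,
        pam_len=len(pam),
        strand="+",
    )


def simulate_amplicon_reads(
    seed: int,
    ref: AmpliconRef,
    indel_rate: float = 0.3,
    conversion_profile: Mapping[int, float] | None = None,
    n_reads: int = 1000,
    subst_error: float = 0.001,
    indel_geom_p: float = 0.5,
    max_indel: int = 10,
) -> tuple[list[FastqRecord], TruthRecord]:
    """Amplicon reads with planted indels and per-position conversions.

    Each read independently carries an indel with probability
    *indel_rate*: size geometric (truncated to 1..max_indel), deletion or
    insertion with equal odds, placed uniformly within +/-3 nt of the cut
    site (so the default +/-8 nt classification window always captures
    it).  Non-indel reads receive A->G conversions at the profiled
    protospacer positions (which must hold 'A' in the reference); uniform
    substitution noise is applied to every read.
    """
    if not 0 <= indel_rate <= 1:
        raise ConfigError("indel_rate must be in [0, 1]")
    profile = dict(conversion_profile or {})
    t = ref.sequence.residues
    for p, rate in profile.items():
        if not 1 <= p <= ref.spacer_len:
            raise ConfigError(f"profile position {p} outside protospacer")
        if not 0 <= rate <= 1:
            raise ConfigError(f"conversion rate {rate} outside [0, 1]")
        base = t[ref.proto_position_to_ref(p)]
        if (base if ref.strand == "+" else revcomp(base)) != "A":
            raise ConfigError(f"protospacer position {p} is {base}, need 'A'")
    rng = np.random.default_rng(seed)
    cut = ref.cut_site
    reads: list[FastqRecord] = []
    for i in range(n_reads):
        if rng.random() < indel_rate:
            size = min(int(rng.geometric(indel_geom_p)), max_indel)
            pos = cut + int(rng.integers(-3, 4))
            if rng.random() < 0.5:  # deletion
                pos = min(max(pos, 0), len(t) - size)
                seq = t[:pos] + t[pos + size :]
            else:  # insertion
                pos = min(max(pos, 0), len(t))
                seq = t[:pos] + _random_dna(rng, size) + t[pos:]
        else:
            s = list(t)
            for p, rate in profile.items():
                if rng.random() < rate:
                    rp = ref.proto_position_to_ref(p)
                    s[rp] = "G" if ref.strand == "+" else "C"
            seq = "".join(s)
        if subst_error > 0:
            s = list(seq)
            n_err = rng.binomial(len(s), subst_error)
            for j in rng.choice(len(s), size=n_err, replace=False):
                s[j] = str(rng.choice([b for b in _BASES if b != s[j]]))
            seq = "".join(s)
        reads.append(FastqRecord(NucSequence(f"read{i}", seq), tuple([40] * len(seq))))
    truth = TruthRecord(
        "simulate_amplicon_reads", seed,
        {
            "indel_rate": indel_rate,
            "conversion_profile": {str(k): v for k, v in profile.items()},
            "n_reads": n_reads,
            "subst_error": subst_error,
        },
    )
    return reads, truth


# ---------------------------------------------------------------------------
# Variant tables with planted per-editor targetability
# ---------------------------------------------------------------------------

DEFAULT_REF_EDITOR = Editor("SpyABE", IupacPattern("NGG"), (4, 8))
DEFAULT_QUERY_EDITOR = Editor("SubABE", IupacPattern("NNAATA"), (3, 11))


def make_variant_table(
    seed: int,
    n_variants: int = 200,
    mix: Mapping[str, float] | None = None,
    context_len: int = 121,
) -> tuple[list[VariantRecord], dict[str, NucSequence], TruthRecord]:
    """Variants + contexts whose per-editor ABE targetability is planted.

    Each context is an ablated all-C backbone carrying a G>A variant at
    its center; with an all-C backbone and alt allele A, only
    forward-strand adenine-editor guides can ever qualify (the alt base on
    the reverse strand is T, never the ABE substrate), so targetability is
    controlled entirely by planting or withholding PAM bases:

    - ``reference_only``: 'GG' planted so an NGG guide holds the variant at
      protospacer position 6 (inside window 4-8); no A/T planted, so the
      A/T-rich query PAM cannot occur.
    - ``query_only``: 'AATA' planted completing an NNAATA PAM with the
      variant at position 6 (inside window 3-11); no G anywhere.
    - ``both``: both motifs planted at non-conflicting offsets (variant at
      position 6 of the NGG guide and position 4 of the NNAATA guide).
    - ``none``: bare backbone.

    Category fractions *mix* must sum to <= 1 (remainder goes to
    ``none``).  Truth (category and per-editor decision per variant) is by
    construction; the checker never participates.
    """
    mix = dict(mix or {"reference_only": 0.3, "query_only": 0.2, "both": 0.1, "none": 0.4})
    known = {"reference_only", "query_only", "both", "none"}
    if set(mix) - known:
        raise ConfigError(f"unknown mix categories {set(mix) - known}")
    if sum(mix.values()) > 1 + 1e-9:
        raise ConfigError("mix fractions must sum to <= 1")
    if context_len < 55 or context_len % 2 == 0:
        raise ConfigError("context_len must be odd and >= 55")
    rng = np.random.default_rng(seed)
    v0 = context_len // 2  # 0-based variant index; >= 26 nt flank either side

    counts = {c: int(round(mix.get(c, 0.0) * n_variants)) for c in known}
    counts["none"] += n_variants - sum(counts.values())
    categories = [c for c in ("reference_only", "query_only", "both", "none")
                  for _ in range(counts[c])]
    rng.shuffle(categories)

    variants: list[VariantRecord] = []
    contexts: dict[str, NucSequence] = {}
    truth_rows = []
    for i, cat in enumerate(categories):
        name = f"synthvar{i:04d}"
        ctx = ["C"] * context_len
        ctx[v0] = "G"  # ref allele; alt is A
        if cat in ("reference_only", "both"):
            ctx[v0 + 16] = "G"
            ctx[v0 + 17] = "G"
        if cat == "query_only":
            ctx[v0 + 17] = "A"
            ctx[v0 + 18] = "A"
            ctx[v0 + 19] = "T"
            ctx[v0 + 20] = "A"
        if cat == "both":
            ctx[v0 + 19] = "A"
            ctx[v0 + 20] = "A"
            ctx[v0 + 21] = "T"
            ctx[v0 + 22] = "A"
        variants.append(VariantRecord(name, v0 + 1, "G", "A"))
        contexts[name] = NucSequence(name, "".join(ctx))
        truth_rows.append(
            {
                "contig": name,
                "category": cat,
                "targetable": {
                    DEFAULT_REF_EDITOR.name: cat in ("reference_only", "both"),
                    DEFAULT_QUERY_EDITOR.name: cat in ("query_only", "both"),
                },
            }
        )
    truth = TruthRecord(
        "make_variant_table", seed,
        {
            "n_variants": n_variants,
            "mix": mix,
            "counts": counts,
            "editors": {
                DEFAULT_REF_EDITOR.name: "NGG window 4-8 ABE",
                DEFAULT_QUERY_EDITOR.name: "NNAATA window 3-11 ABE",
            },
            "variants": truth_rows,
        },
    )
    return variants, contexts, truth


# ---------------------------------------------------------------------------
# Synthetic ortholog panel (stand-in for the study's protein supplement)
# ---------------------------------------------------------------------------

ORTHOLOG_LENGTHS = {
    "SpyCas9_synthetic": 1368,
    "SinCas9_synthetic": 1368,
    "SauCas9_synthetic": 1053,
    "SubCas9_synthetic": 1122,
    "SgaCas9_synthetic": 1130,
    "SpaCas9_synthetic": 1140,
}


def make_ortholog_panel(
    seed: int, sin_spy_identity: float = 70.0
) -> tuple[dict[str, ProteinSequence], TruthRecord]:
    """SYNTHETIC Cas9-ortholog stand-ins with planted lengths and identity.

    These are random proteins, not real Cas9 sequences: the panel plants
    the documented ortholog lengths (1,122 / 1,130 / 1,140 / 1,053 /
    1,368 aa) and a Sin/Spy pair whose percent identity is planted at
    *sin_spy_identity* by substituting the complementary fraction of
    positions of a shared template — so alignment-based identity recovery
    can be tested without the real sequences.
    """
    rng = np.random.default_rng(seed)
    spy = _random_protein(rng, ORTHOLOG_LENGTHS["SpyCas9_synthetic"])
    n = len(spy)
    n_sub = round(n * (1.0 - sin_spy_identity / 100.0))
    sin = list(spy)
    for i in rng.choice(n, size=n_sub, replace=False):
        sin[i] = str(rng.choice([a for a in _AA if a != sin[i]]))
    sin = "".join(sin)

    sau_family_template = _random_protein(rng, 1140)

    def family_member(length: int, sub_frac: float = 0.6) -> str:
        s = list(sau_family_template)
        for i in rng.choice(len(s), size=round(len(s) * sub_frac), replace=False):
            s[i] = str(rng.choice([a for a in _AA if a != s[i]]))
        if length < len(s):
            drop = rng.choice(len(s), size=len(s) - length, replace=False)
            s = [c for i, c in enumerate(s) if i not in set(drop.tolist())]
        return "".join(s)

    panel = {
        "SpyCas9_synthetic": spy,
        "SinCas9_synthetic": sin,
        "SauCas9_synthetic": family_member(1053),
        "SubCas9_synthetic": family_member(1122),
        "SgaCas9_synthetic": family_member(1130),
        "SpaCas9_synthetic": family_member(1140),
    }
    records = {k: ProteinSequence(k, v) for k, v in panel.items()}
    truth = TruthRecord(
        "make_ortholog_panel", seed,
        {
            "lengths": {k: len(v) for k, v in panel.items()},
            "sin_spy_identity": sin_spy_identity,
            "note": "synthetic stand-ins; random proteins with planted parameters",
        },
    )
    return records, truth
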