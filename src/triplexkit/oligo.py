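"""Mixmer oligonucleotide model.

Parses the mixmer notation used for LNA/DNA triplex-forming oligonucleotides
(TFOs): lowercase letters are DNA nucleotides, uppercase letters are LNA
(locked nucleic acid) nucleotides, ``**P**`` (or bare ``P``) is a TINA
intercalating monomer, ``Cy3``/``Cy5`` are terminal fluorophore labels and
``-`` separates segments (e.g. the arm/linker/arm layout of a bisLNA clamp).
Strings may carry ``5'-``/``-3'`` direction decorations (unicode primes
accepted) and may be written 3'→5', in which case they are normalised to
5'→3' on parsing.  ``**...**`` spans longer than a single P are kept as
emphasis (binding-site) annotations.

Also provides Watson-Crick and parallel Hoogsteen complement operations,
TFO binding-site search on duplex targets, hybridization-ratio arithmetic,
the shipped sequence catalog and FASTA import/export.
"""

from __future__ import annotations

import csv
import math
import re
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import NamedTuple, Optional, Sequence

__all__ = [
    "NotationError",
    "AmbiguousSiteError",
    "Monomer",
    "Oligo",
    "DuplexTarget",
    "HgComplement",
    "parse_mixmer",
    "to_notation",
    "count_lna",
    "count_tina",
    "wc_complement",
    "hoogsteen_parallel_complement",
    "find_tfo_binding_site",
    "hybridization_ratio",
    "protonate_tfo_cytosines",
    "load_catalog",
    "get_oligo",
    "get_duplex",
    "write_fasta",
    "read_fasta",
]

PURINES = frozenset("AG")
PYRIMIDINES = frozenset("CT")
WC_RULE = {"A": "T", "T": "A", "G": "C", "C": "G"}
# Parallel Hoogsteen third-strand rule: position-wise, no reversal.
HG_RULE = {"A": "T", "G": "C"}

DNA = "DNA"
LNA = "LNA"
TINA = "TINA"


class NotationError(ValueError):
    """Raised for malformed mixmer notation or invalid base sequences."""


class AmbiguousSiteError(ValueError):
    """Raised when a TFO matches a duplex target at more than one site."""


@dataclass(frozen=True)
class Monomer:
    """One monomer of an oligonucleotide.

    ``base`` is ``None`` for base-free monomers (TINA); ``position`` is the
    1-based nucleotide index from the 5' end and is ``None`` for TINA.
    """

    base: Optional[str]
    chemistry: str
    protonated: bool = False
    position: Optional[int] = None

    def __post_init__(self) -> None:
        if self.chemistry == TINA and self.base is not None:
            raise NotationError("TINA monomers are base-free")
        if self.protonated and self.base != "C":
            raise NotationError("only cytosines can be protonated")


@dataclass(frozen=True)
class Oligo:
    """A parsed oligonucleotide (ordered monomers, labels, segment spans).

    ``segments`` are 1-based closed intervals in monomer-list coordinates;
    ``highlight`` is the bold (binding-site) span of the printed notation in
    nucleotide coordinates, when present.
    """

    monomers: tuple[Monomer, ...]
    name: str = ""
    label5: Optional[str] = None
    label3: Optional[str] = None
    segments: tuple[tuple[int, int], ...] = ()
    highlight: Optional[tuple[int, int]] = None

    @property
    def sequence(self) -> str:
        """Base letters (uppercase), 5'→3', TINA monomers skipped."""
        return "".join(m.base for m in self.monomers if m.base is not None)

    @property
    def nucleotides(self) -> tuple[Monomer, ...]:
        return tuple(m for m in self.monomers if m.base is not None)

    def __len__(self) -> int:
        """Nucleotide length (TINA monomers are not nucleotides)."""
        return sum(1 for m in self.monomers if m.base is not None)

    @property
    def chemistries(self) -> tuple[str, ...]:
        """Per-nucleotide chemistry, 5'→3'."""
        return tuple(m.chemistry for m in self.monomers if m.base is not None)

    @property
    def is_pyrimidine(self) -> bool:
        return all(b in PYRIMIDINES for b in self.sequence)


def count_lna(oligo: Oligo) -> int:
    """Number of LNA monomers in the oligonucleotide."""
    return sum(1 for m in oligo.monomers if m.chemistry == LNA)


def count_tina(oligo: Oligo) -> int:
    return sum(1 for m in oligo.monomers if m.chemistry == TINA)


# ---------------------------------------------------------------------------
# Notation parsing
# ---------------------------------------------------------------------------

_PRIME_CHARS = {"′": "'", "’": "'", "ʹ": "'"}


def _normalise(notation: str) -> str:
    s = notation.strip()
    for uni, ascii_ in _PRIME_CHARS.items():
        s = s.replace(uni, ascii_)
    return s


def parse_mixmer(
    notation: str, name: str = "", strict_tina: bool = False
) -> Oligo:
    """Parse mixmer notation into an :class:`Oligo`.

    Lowercase acgt → DNA, uppercase ACGT → LNA, ``**P**`` → TINA (bare ``P``
    also accepted unless ``strict_tina``), ``-`` separates segments and
    ``Cy3``/``Cy5`` at an end is a fluorophore label.  Strings written 3'→5'
    (leading ``3'-`` or trailing ``-5'``) are reversed to 5'→3'.
    """
    s = _normalise(notation)
    if not s:
        raise NotationError("empty notation")

    reversed_print = False
    if s.startswith("5'-"):
        s = s[3:]
    elif s.startswith("3'-"):
        s = s[3:]
        reversed_print = True
    if s.endswith("-3'"):
        if reversed_print:
            raise NotationError(f"conflicting direction decorations in {notation!r}")
        s = s[:-3]
    elif s.endswith("-5'"):
        if not reversed_print and notation.lstrip().startswith(("5'", "5′")):
            raise NotationError(f"conflicting direction decorations in {notation!r}")
        s = s[:-3]
        reversed_print = True

    label_lead = label_trail = None
    m = re.match(r"^(Cy3|Cy5)-", s)
    if m:
        label_lead = m.group(1)
        s = s[len(m.group(0)):]
    m = re.search(r"-(Cy3|Cy5)$", s)
    if m:
        label_trail = m.group(1)
        s = s[: -len(m.group(0))]

    # Tokenize.  tokens: (kind, base, chemistry, emphasized)
    tokens: list[tuple[str, Optional[str], Optional[str]]] = []  # kind in {nt, tina, break}
    emphasis_flags: list[bool] = []
    bold_open = False
    i = 0
    monomer_pos = 0  # position in printed monomer stream (for error messages)
    while i < len(s):
        ch = s[i]
        if s.startswith("**", i):
            # "**P**" is always a TINA token; other bold spans are emphasis.
            if not bold_open and s.startswith("**P**", i):
                tokens.append(("tina", None, TINA))
                emphasis_flags.append(False)
                i += 5
                monomer_pos += 1
                continue
            bold_open = not bold_open
            i += 2
            continue
        monomer_pos += 1
        if ch == "-":
            tokens.append(("break", None, None))
            emphasis_flags.append(False)
        elif ch == "P":
            if strict_tina:
                raise NotationError(
                    f"bare 'P' at monomer position {monomer_pos} "
                    "(strict mode requires **P**)"
                )
            tokens.append(("tina", None, TINA))
            emphasis_flags.append(bold_open)
        elif ch in "acgt":
            tokens.append(("nt", ch.upper(), DNA))
            emphasis_flags.append(bold_open)
        elif ch in "ACGT":
            tokens.append(("nt", ch, LNA))
            emphasis_flags.append(bold_open)
        else:
            raise NotationError(
                f"unknown character {ch!r} at monomer position {monomer_pos} "
                f"in {notation!r}"
            )
        i += 1
    if bold_open:
        raise NotationError(f"unbalanced '**' emphasis markers in {notation!r}")

    if reversed_print:
        tokens.reverse()
        emphasis_flags.reverse()
        label_lead, label_trail = label_trail, label_lead

    label5, label3 = label_lead, label_trail

    monomers: list[Monomer] = []
    segments: list[tuple[int, int]] = []
    emphasized_nt: list[int] = []
    seg_start = 1
    nt_pos = 0
    for tok, emph in zip(tokens, emphasis_flags):
        kind, base, chem = tok
        if kind == "break":
            if len(monomers) + 1 == seg_start:
                raise NotationError(f"empty segment in {notation!r}")
            segments.append((seg_start, len(monomers)))
            seg_start = len(monomers) + 1
            continue
        if kind == "tina":
            monomers.append(Monomer(None, TINA))
        else:
            nt_pos += 1
            monomers.append(Monomer(base, chem, position=nt_pos))
            if emph:
                emphasized_nt.append(nt_pos)
    if not monomers:
        raise NotationError(f"no monomers in {notation!r}")
    if len(monomers) + 1 == seg_start:
        raise NotationError(f"empty trailing segment in {notation!r}")
    segments.append((seg_start, len(monomers)))

    highlight = None
    if emphasized_nt:
        lo, hi = min(emphasized_nt), max(emphasized_nt)
        if emphasized_nt != list(range(lo, hi + 1)):
            raise NotationError(f"non-contiguous emphasis span in {notation!r}")
        highlight = (lo, hi)

    return Oligo(
        monomers=tuple(monomers),
        name=name,
        label5=label5,
        label3=label3,
        segments=tuple(segments),
        highlight=highlight,
    )


def to_notation(oligo: Oligo, decorate: bool = True) -> str:
    """Serialize an :class:`Oligo` back to mixmer notation (5'→3')."""
    parts: list[str] = []
    for start, end in oligo.segments:
        chars: list[str] = []
        for m in oligo.monomers[start - 1 : end]:
            if m.chemistry == TINA:
                chars.append("**P**")
            elif m.chemistry == LNA:
                chars.append(m.base)
            else:
                chars.append(m.base.lower())
        parts.append("".join(chars))
    body = "-".join(parts)
    if oligo.label5:
        body = f"{oligo.label5}-{body}"
    if oligo.label3:
        body = f"{body}-{oligo.label3}"
    if decorate:
        body = f"5'-{body}-3'"
    return body


def protonate_tfo_cytosines(oligo: Oligo) -> Oligo:
    """Return a copy with every cytosine flagged protonated (N3-H+), as in a
    parallel pyrimidine-motif TFO at triplex-forming pH."""
    monos = tuple(
        replace(m, protonated=True) if m.base == "C" else m for m in oligo.monomers
    )
    return replace(oligo, monomers=monos)


# ---------------------------------------------------------------------------
# Complements
# ---------------------------------------------------------------------------


def wc_complement(sequence: str) -> str:
    """Antiparallel Watson-Crick complement, returned 5'→3'.

    Case is preserved per character (so chemistry annotations in mixmer
    strings survive a double complement).
    """
    out = []
    for pos, ch in enumerate(sequence, start=1):
        up = ch.upper()
        if up not in WC_RULE:
            raise NotationError(f"non-ACGT character {ch!r} at position {pos}")
        comp = WC_RULE[up]
        out.append(comp if ch.isupper() else comp.lower())
    return "".join(reversed(out))


class HgComplement(NamedTuple):
    """Parallel Hoogsteen complement: pyrimidine sequence plus per-position
    cytosine protonation flags."""

    sequence: str
    protonated: tuple[bool, ...]


def hoogsteen_parallel_complement(purine_tract: str) -> HgComplement:
    """Position-wise parallel Hoogsteen complement of a purine tract.

    A→T and G→C+ (protonated cytosine); no reversal, because a pyrimidine
    TFO binds parallel to the purine strand in the major groove.
    """
    seq = []
    prot = []
    for pos, ch in enumerate(purine_tract, start=1):
        up = ch.upper()
        if up not in HG_RULE:
            raise NotationError(
                f"pyrimidine/non-purine character {ch!r} at position {pos} "
                "in purine tract"
            )
        seq.append(HG_RULE[up].lower())
        prot.append(up == "G")
    return HgComplement("".join(seq), tuple(prot))


# ---------------------------------------------------------------------------
# Duplex targets and binding sites
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DuplexTarget:
    """A double-stranded target: purine-rich strand plus its full-length
    antiparallel Watson-Crick complement, both stored 5'→3'."""

    purine_strand: Oligo
    pyrimidine_strand: Oligo
    binding_site: Optional[tuple[int, int]] = None
    name: str = ""

    def __post_init__(self) -> None:
        a = self.purine_strand.sequence
        b = self.pyrimidine_strand.sequence
        if len(a) != len(b):
            raise NotationError(
                f"duplex strands differ in length ({len(a)} vs {len(b)})"
            )
        comp = wc_complement(b).upper()
        for i, (x, y) in enumerate(zip(a, comp), start=1):
            if x != y:
                raise NotationError(
                    f"strands are not Watson-Crick complementary: first "
                    f"mismatch at purine-strand position {i} ({x} vs {y})"
                )

    @property
    def is_hetero(self) -> bool:
        """True when either strand contains LNA (hetero-duplex target)."""
        return bool(count_lna(self.purine_strand) or count_lna(self.pyrimidine_strand))

    def __len__(self) -> int:
        return len(self.purine_strand)


def find_tfo_binding_site(
    duplex: DuplexTarget, tfo: Oligo
) -> Optional[tuple[int, int]]:
    """Locate the unique purine-strand interval whose parallel Hoogsteen
    complement equals the TFO base sequence (1-based closed interval)."""
    tfo_seq = tfo.sequence
    bad = [b for b in tfo_seq if b not in PYRIMIDINES]
    if bad:
        raise NotationError(
            f"TFO contains purine base(s) {sorted(set(bad))}; a parallel "
            "pyrimidine-motif TFO must contain only C/T"
        )
    pur = duplex.purine_strand.sequence
    k = len(tfo_seq)
    want = tfo_seq.lower()
    hits = []
    for i in range(len(pur) - k + 1):
        window = pur[i : i + k]
        if not all(b in PURINES for b in window):
            continue
        if hoogsteen_parallel_complement(window).sequence == want:
            hits.append((i + 1, i + k))
    if not hits:
        return None
    if len(hits) > 1:
        raise AmbiguousSiteError(
            f"TFO matches multiple purine-strand intervals: {hits}"
        )
    return hits[0]


def hybridization_ratio(target_concentration: float, on_concentration: float):
    """dsDNA-target : oligonucleotide molar ratio (the '1:N' of a binding
    series).  Rounded to the nearest integer when within 1%."""
    if target_concentration <= 0 or on_concentration <= 0:
        raise ValueError("concentrations must be positive")
    ratio = on_concentration / target_concentration
    nearest = round(ratio)
    if nearest > 0 and abs(ratio - nearest) <= 0.01 * ratio:
        return int(nearest)
    return ratio


# ---------------------------------------------------------------------------
# Catalog of the studied sequences
# ---------------------------------------------------------------------------


def _norm_name(name: str) -> str:
    s = _normalise(name).lower()
    return re.sub(r"[\s'\-_•⦁>ʹ.]", "", s)


def _catalog_rows() -> list[dict]:
    with resources.files("triplexkit.data").joinpath("sequences.tsv").open(
        encoding="utf-8"
    ) as fh:
        return list(csv.DictReader(fh, delimiter="\t"))


_CATALOG_CACHE: Optional[dict] = None


def load_catalog() -> dict:
    """Load the shipped sequence catalog: name → record dict with keys
    ``kind`` (oligo/duplex), ``length_nt`` and ``notation``."""
    global _CATALOG_CACHE
    if _CATALOG_CACHE is None:
        _CATALOG_CACHE = {
            row["name"]: {
                "kind": row["kind"],
                "length_nt": int(row["length_nt"]),
                "notation": row["notation"],
            }
            for row in _catalog_rows()
        }
    return _CATALOG_CACHE


def _lookup(name: str) -> tuple[str, dict]:
    cat = load_catalog()
    if name in cat:
        return name, cat[name]
    want = _norm_name(name)
    for key, rec in cat.items():
        if _norm_name(key) == want:
            return key, rec
    raise KeyError(f"unknown sequence name {name!r}; see load_catalog() keys")


def get_oligo(name: str) -> Oligo:
    """Fetch a catalog oligonucleotide by (fuzzy-normalised) name."""
    key, rec = _lookup(name)
    if rec["kind"] != "oligo":
        raise KeyError(f"{key!r} is a duplex target, not an oligonucleotide")
    return parse_mixmer(rec["notation"], name=key)


def get_duplex(name: str) -> DuplexTarget:
    """Fetch a catalog duplex target by name.  The first printed strand is
    the purine (TFO-binding) strand; its bold span becomes the recorded
    binding site."""
    key, rec = _lookup(name)
    if rec["kind"] != "duplex":
        raise KeyError(f"{key!r} is an oligonucleotide, not a duplex target")
    pur_s, pyr_s = rec["notation"].split("/")
    pur = parse_mixmer(pur_s, name=f"{key}:purine")
    pyr = parse_mixmer(pyr_s, name=f"{key}:pyrimidine")
    return DuplexTarget(
        purine_strand=pur,
        pyrimidine_strand=pyr,
        binding_site=pur.highlight,
        name=key,
    )


def duplex_from_notations(
    purine: str, pyrimidine: str, name: str = ""
) -> DuplexTarget:
    pur = parse_mixmer(purine, name=f"{name}:purine")
    pyr = parse_mixmer(pyrimidine, name=f"{name}:pyrimidine")
    return DuplexTarget(pur, pyr, binding_site=pur.highlight, name=name)


# ---------------------------------------------------------------------------
# FASTA import/export (chemistry goes to a sidecar TSV; FASTA keeps bases)
# ---------------------------------------------------------------------------


def write_fasta(
    oligos: Sequence[Oligo], path, sidecar: Optional[object] = None
) -> None:
    """Write plain base sequences as FASTA; per-position chemistry and
    protonation go to an optional sidecar TSV (FASTA cannot carry them)."""
    from Bio import SeqIO
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord

    records = [
        SeqRecord(Seq(o.sequence), id=o.name or f"oligo{i+1}", description="")
        for i, o in enumerate(oligos)
    ]
    SeqIO.write(records, str(path), "fasta")
    if sidecar is not None:
        with open(sidecar, "w", encoding="utf-8") as fh:
            fh.write("name\tposition\tbase\tchemistry\tprotonated\n")
            for i, o in enumerate(oligos):
                oname = o.name or f"oligo{i+1}"
                for m in o.nucleotides:
                    fh.write(
                        f"{oname}\t{m.position}\t{m.base}\t{m.chemistry}\t"
                        f"{int(m.protonated)}\n"
                    )


def read_fasta(path, sidecar: Optional[object] = None) -> list[Oligo]:
    """Read FASTA base sequences (DNA chemistry by default); a sidecar TSV
    written by :func:`write_fasta` restores per-position chemistry."""
    from Bio import SeqIO

    chem: dict[tuple[str, int], tuple[str, bool]] = {}
    if sidecar is not None and Path(sidecar).exists():
        with open(sidecar, encoding="utf-8") as fh:
            for row in csv.DictReader(fh, delimiter="\t"):
                chem[(row["name"], int(row["position"]))] = (
                    row["chemistry"],
                    bool(int(row["protonated"])),
                )
    out = []
    for rec in SeqIO.parse(str(path), "fasta"):
        monos = []
        for pos, ch in enumerate(str(rec.seq).upper(), start=1):
            if ch not in WC_RULE:
                raise NotationError(
                    f"non-ACGT character {ch!r} at position {pos} in {rec.id}"
                )
            chemistry, prot = chem.get((rec.id, pos), (DNA, False))
            monos.append(Monomer(ch, chemistry, protonated=prot, position=pos))
        out.append(
            Oligo(tuple(monos), name=rec.id, segments=((1, len(monos)),))
        )
    return out
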