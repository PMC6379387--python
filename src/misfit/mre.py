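"""Sequence-level domain model for synthetic miRNA response elements (MREs).

An MRE is a short stretch of mRNA that base-pairs with a miRNA and recruits
the RNA-induced silencing complex; the degree of complementarity sets the
magnitude of repression. This module represents miRNAs and substitution-only
MRE variant libraries: reverse complementation, per-position pairing
classification (Watson-Crick / G:U wobble / mismatch), and exhaustive
enumeration of all variants with exactly ``k`` substituted positions.

Coordinate convention
---------------------
Positions are 1-based from the miRNA 5' end (position 1 = miRNA 5'
nucleotide). The MRE is stored as DNA, 5'->3' in mRNA orientation, so miRNA
position ``i`` pairs with MRE string index ``L - i`` (0-based). The seed is
miRNA nt 2-8 and the supplementary region nt 13-16 unless overridden.
"""

from __future__ import annotations

import itertools
import re
from dataclasses import dataclass, field
from math import comb
from typing import Iterable, Iterator

__all__ = [
    "AlphabetError",
    "MiRNA",
    "MREVariant",
    "PairingProfile",
    "MIR17",
    "reverse_complement",
    "perfect_mre",
    "count_combinations",
    "enumerate_variants",
    "classify_pair",
    "pairing_profile",
    "make_variant",
    "parse_variant_id",
    "variant_id_for",
]

DNA_BASES = "ACGT"
RNA_BASES = "ACGU"

# base pairing partner, emitted in the requested output alphabet
_COMPLEMENT = {
    "DNA": {"A": "T", "C": "G", "G": "C", "T": "A", "U": "A"},
    "RNA": {"A": "U", "C": "G", "G": "C", "T": "A", "U": "A"},
}

# miRNA base (RNA) : MRE base (DNA) -> pairing class
_WATSON_CRICK = {("A", "T"), ("U", "A"), ("G", "C"), ("C", "G")}
# miRNA G pairs with MRE T (transcribed to U... the transcript base pairs G:U),
# miRNA U pairs with MRE G
_WOBBLE = {("G", "T"), ("U", "G")}


class AlphabetError(ValueError):
    """A sequence contains characters outside the expected nucleotide alphabet."""


def reverse_complement(seq: str, out_alphabet: str = "DNA") -> str:
    """Reverse complement of ``seq`` emitted in ``out_alphabet`` ('DNA' or 'RNA').

    Accepts mixed DNA/RNA input (A, C, G, T, U); an involution when input and
    output alphabets match.
    """
    if out_alphabet not in _COMPLEMENT:
        raise ValueError(f"unknown alphabet {out_alphabet!r}")
    table = _COMPLEMENT[out_alphabet]
    try:
        return "".join(table[b] for b in reversed(seq.upper()))
    except KeyError as exc:
        raise AlphabetError(f"non-nucleotide character {exc.args[0]!r} in sequence") from exc


def count_combinations(n: int, r: int) -> int:
    """Number of ways to choose ``r`` mismatch positions among ``n``: n!/(r!(n-r)!)."""
    if n < 0 or r < 0 or r > n:
        raise ValueError(f"require 0 <= r <= n, got n={n}, r={r}")
    return comb(n, r)


@dataclass(frozen=True)
class MiRNA:
    """A miRNA: name, 5'->3' RNA sequence and its functional regions.

    ``seed_range`` and ``supplementary_range`` are inclusive 1-based position
    ranges counted from the miRNA 5' end.
    """

    name: str
    sequence: str
    seed_range: tuple[int, int] = (2, 8)
    supplementary_range: tuple[int, int] = (13, 16)

    def __post_init__(self) -> None:
        seq = self.sequence.upper()
        if not seq or any(b not in RNA_BASES for b in seq):
            raise AlphabetError(f"miRNA sequence must be non-empty RNA (ACGU): {self.sequence!r}")
        object.__setattr__(self, "sequence", seq)
        for lo, hi in (self.seed_range, self.supplementary_range):
            if not (1 <= lo <= hi <= len(seq)):
                # a short miRNA may simply not reach the canonical ranges;
                # clip rather than reject so toy sequences stay usable
                pass

    @property
    def length(self) -> int:
        return len(self.sequence)

    def base(self, position: int) -> str:
        """miRNA base at 1-based ``position``."""
        if not 1 <= position <= self.length:
            raise IndexError(f"miRNA position {position} outside 1..{self.length}")
        return self.sequence[position - 1]

    def complement_dna(self, position: int) -> str:
        """The perfectly complementary MRE (DNA) base opposite ``position``."""
        return _COMPLEMENT["DNA"][self.base(position)]

    def region(self, position: int) -> str:
        """Region label of ``position``: 'seed', 'supplementary' or 'other'."""
        if self.seed_range[0] <= position <= self.seed_range[1]:
            return "seed"
        if self.supplementary_range[0] <= position <= self.supplementary_range[1]:
            return "supplementary"
        return "other"

    def mre_index(self, position: int) -> int:
        """0-based index into the MRE string opposite miRNA ``position``."""
        return self.length - position


#: hsa-miR-17-5p (miRBase); configuration default, not hard-wired anywhere.
MIR17 = MiRNA(name="hsa-miR-17-5p", sequence="CAAAGUGCUUACAGUGCAGGUAG")


@dataclass(frozen=True)
class MREVariant:
    """One candidate target site: sequence plus its substitution set.

    ``substitutions`` holds ``(mirna_position, alt_mre_base)`` pairs; the alt
    base always differs from the perfect-complement base at that position.
    """

    variant_id: str
    mre_sequence: str
    substitutions: frozenset[tuple[int, str]] = frozenset()
    tag: str = "perfect"

    @property
    def n_mismatches(self) -> int:
        return len(self.substitutions)

    def positions(self) -> tuple[int, ...]:
        return tuple(sorted(p for p, _ in self.substitutions))


def variant_id_for(substitutions: Iterable[tuple[int, str]]) -> str:
    """Canonical id: 'p<pos><base>' per substitution, '+'-joined, sorted by (pos, base)."""
    subs = sorted(substitutions)
    if not subs:
        return "perfect"
    return "+".join(f"p{pos}{base}" for pos, base in subs)


_SUB_RE = re.compile(r"^p(\d+)([ACGT])$")


def parse_variant_id(variant_id: str) -> frozenset[tuple[int, str]]:
    """Invert :func:`variant_id_for`; raises ValueError for non-canonical ids."""
    if variant_id == "perfect":
        return frozenset()
    subs = set()
    for token in variant_id.split("+"):
        m = _SUB_RE.match(token)
        if not m:
            raise ValueError(f"not a canonical variant id: {variant_id!r}")
        subs.add((int(m.group(1)), m.group(2)))
    return frozenset(subs)


def perfect_mre(mirna: MiRNA) -> MREVariant:
    """The fully complementary MRE: DNA reverse complement of the miRNA."""
    return MREVariant(
        variant_id="perfect",
        mre_sequence=reverse_complement(mirna.sequence, "DNA"),
        substitutions=frozenset(),
        tag="perfect",
    )


_TAG_BY_K = {0: "perfect", 1: "single", 2: "double"}


def make_variant(mirna: MiRNA, substitutions: Iterable[tuple[int, str]]) -> MREVariant:
    """Build the variant carrying exactly the given substitutions.

    Each substitution replaces the MRE base opposite the stated miRNA position
    with ``alt_mre_base``; the alt base must differ from the perfect
    complement there (otherwise it would not be a substitution).
    """
    subs = frozenset(substitutions)
    seq = list(reverse_complement(mirna.sequence, "DNA"))
    seen: set[int] = set()
    for pos, alt in sorted(subs):
        if not 1 <= pos <= mirna.length:
            raise ValueError(f"position {pos} outside 1..{mirna.length}")
        if alt not in DNA_BASES:
            raise AlphabetError(f"alt base {alt!r} is not a DNA base")
        if pos in seen:
            raise ValueError(f"duplicate substitution position {pos}")
        if alt == mirna.complement_dna(pos):
            raise ValueError(
                f"p{pos}{alt} equals the perfect-complement base; not a substitution"
            )
        seen.add(pos)
        seq[mirna.mre_index(pos)] = alt
    return MREVariant(
        variant_id=variant_id_for(subs),
        mre_sequence="".join(seq),
        substitutions=subs,
        tag=_TAG_BY_K.get(len(subs), "multi"),
    )


def enumerate_variants(mirna: MiRNA, k: int) -> list[MREVariant]:
    """All distinct variants with exactly ``k`` substituted MRE positions.

    Size is C(L, k) * 3**k. Ordering is canonical and deterministic:
    lexicographic on the position tuple, then on the alt bases.
    """
    if k < 0:
        raise ValueError("k must be >= 0")
    variants: list[MREVariant] = []
    for positions in itertools.combinations(range(1, mirna.length + 1), k):
        alt_sets = [
            [b for b in DNA_BASES if b != mirna.complement_dna(pos)] for pos in positions
        ]
        for alts in itertools.product(*alt_sets):
            variants.append(make_variant(mirna, zip(positions, alts)))
    return variants


def classify_pair(mirna_base: str, mre_base: str) -> str:
    """Pairing class of a miRNA (RNA) base against an MRE (DNA) base.

    'watson_crick' for the four canonical pairs, 'wobble' for miRNA G : MRE T
    and miRNA U : MRE G (G:U pairs in the transcript), 'mismatch' otherwise.
    """
    mirna_base = mirna_base.upper()
    mre_base = mre_base.upper()
    if mirna_base not in RNA_BASES:
        raise AlphabetError(f"miRNA base {mirna_base!r} is not RNA")
    if mre_base not in DNA_BASES:
        raise AlphabetError(f"MRE base {mre_base!r} is not DNA")
    pair = (mirna_base, mre_base)
    if pair in _WATSON_CRICK:
        return "watson_crick"
    if pair in _WOBBLE:
        return "wobble"
    return "mismatch"


@dataclass(frozen=True)
class PairingProfile:
    """Per-miRNA-position pairing classes and region labels (index 0 = position 1)."""

    classes: tuple[str, ...]
    regions: tuple[str, ...]

    def __len__(self) -> int:
        return len(self.classes)

    def pairing_class(self, position: int) -> str:
        return self.classes[position - 1]

    def region(self, position: int) -> str:
        return self.regions[position - 1]

    def non_watson_crick_positions(self) -> tuple[int, ...]:
        return tuple(
            i + 1 for i, cls in enumerate(self.classes) if cls != "watson_crick"
        )


def pairing_profile(mirna: MiRNA, variant: MREVariant) -> PairingProfile:
    """Classify every miRNA position against the aligned MRE base."""
    if len(variant.mre_sequence) != mirna.length:
        raise ValueError(
            f"MRE length {len(variant.mre_sequence)} != miRNA length {mirna.length}"
        )
    classes = []
    regions = []
    for pos in range(1, mirna.length + 1):
        mre_base = variant.mre_sequence[mirna.mre_index(pos)]
        classes.append(classify_pair(mirna.base(pos), mre_base))
        regions.append(mirna.region(pos))
    return PairingProfile(classes=tuple(classes), regions=tuple(regions))
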