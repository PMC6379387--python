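"""Synthetic pooled-screen data with a known ground truth.

Every downstream stage (counting, frequency normalisation, cDNA/pDNA
abundance, translational efficiency, dictionary building, knock-in
quantification) is validated against libraries generated here, where the
per-variant repression is known exactly.

The generator emulates the screen's study conditions: a 23-nt degenerate
oligo pool carrying the perfectly complementary base at 91% and each of the
three alternatives at 3% per position; plasmid (pDNA), mRNA (cDNA), monosome
and heavy-polysome amplicon libraries whose variant frequencies follow a
configurable ground-truth repression model; and pooled knock-in gDNA/cDNA
amplicons with wild-type contamination carrying an intact restriction site.

The ground-truth model is the simulator's own stand-in (no generative model
is implied by the biology): expression of a variant is

    min(1, perfect_level * prod_i (1 + g_i)),

one relief factor per substitution, with g_i = weight[pos] * base_modifier *
seed_boost (seed positions) * wobble_relief (G:U wobbles). Seed mismatches
therefore derepress most, wobbles derepress least, and expression is
monotone non-decreasing as substitutions are added.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from types import MappingProxyType
from typing import Mapping, Sequence

import numpy as np

from .mre import (
    DNA_BASES,
    MiRNA,
    MREVariant,
    classify_pair,
    enumerate_variants,
    perfect_mre,
    reverse_complement,
)
from .quantify import CountTable

__all__ = [
    "CONTROL_NONTARGETED_ID",
    "CONTROL_NONTARGETED_SITE",
    "LibraryComposition",
    "GroundTruthModel",
    "ScreenSimConfig",
    "SimulatedScreen",
    "SimulatedKnockin",
    "degenerate_composition",
    "expected_frequency",
    "ground_truth_expression",
    "simulate_screen",
    "reads_from_counts",
    "simulate_knockin",
]

#: Non-targeted spike-in control: a site complementary to C. elegans
#: cel-miR-67-3p, which has no mammalian counterpart. Truncated to 23 nt so
#: control amplicons share the variable-region length of the library.
CONTROL_NONTARGETED_ID = "cel-miR-67"
CONTROL_NONTARGETED_SITE = reverse_complement("UCACAACCUCCUAGAAAGAGUAGA", "DNA")[:23]

#: key used for the unenumerated (k >= 3) remainder of the degenerate pool
OTHER_ID = "__other__"

_BASE_INDEX = {b: i for i, b in enumerate(DNA_BASES)}


@dataclass(frozen=True)
class LibraryComposition:
    """Per-position base probabilities of the degenerate pool.

    ``probs`` has shape (L, 4) over bases A, C, G, T; row j is the MRE
    position with 0-based 5'->3' index j (i.e. miRNA position L - j).
    """

    probs: np.ndarray

    def __post_init__(self) -> None:
        p = np.asarray(self.probs, dtype=float)
        if p.ndim != 2 or p.shape[1] != 4:
            raise ValueError("composition must have shape (L, 4)")
        if (p < 0).any() or not np.allclose(p.sum(axis=1), 1.0, atol=1e-12):
            raise ValueError("each position's probabilities must be >= 0 and sum to 1")
        object.__setattr__(self, "probs", p)

    @property
    def length(self) -> int:
        return self.probs.shape[0]


def degenerate_composition(mirna: MiRNA, match_frac: float = 0.91) -> LibraryComposition:
    """Composition of a hand-mixed degenerate pool.

    Each position carries the perfectly complementary base at ``match_frac``
    and each of the three alternatives at (1 - match_frac)/3 (0.91 / 0.03
    per the library design).
    """
    if not 0 < match_frac <= 1:
        raise ValueError("match_frac must be in (0, 1]")
    perfect = perfect_mre(mirna).mre_sequence
    off = (1.0 - match_frac) / 3.0
    probs = np.full((mirna.length, 4), off)
    for j, base in enumerate(perfect):
        probs[j, _BASE_INDEX[base]] = match_frac
    return LibraryComposition(probs=probs)


def expected_frequency(comp: LibraryComposition, variant: MREVariant | str) -> float:
    """Design frequency of one exact sequence in the degenerate pool."""
    seq = variant if isinstance(variant, str) else variant.mre_sequence
    if len(seq) != comp.length:
        raise ValueError(f"sequence length {len(seq)} != composition length {comp.length}")
    freq = 1.0
    for j, base in enumerate(seq):
        freq *= comp.probs[j, _BASE_INDEX[base]]
    return freq


def _default_weights(mirna: MiRNA) -> tuple[float, ...]:
    # Region-level relief weights with a fixed per-position jitter so that
    # ground-truth single-variant expressions are distinct (real per-position
    # effect maps are idiosyncratic; exact ties would make rank recovery
    # ill-posed). The jitter stream is a constant of the default model.
    base = {"seed": 2.0, "supplementary": 2.0, "other": 0.5}
    rng = np.random.default_rng(170817)
    jitter = 0.75 + 0.5 * rng.random(mirna.length)
    return tuple(base[mirna.region(pos)] * jitter[pos - 1] for pos in range(1, mirna.length + 1))


@dataclass(frozen=True)
class GroundTruthModel:
    """Simulator ground truth: expression retained by each MRE variant.

    Expression is a fraction of the non-targeted control (= 1.0); the
    perfect MRE sits at ``perfect_level`` and each substitution multiplies
    in a relief factor (1 + g_i) >= 1, capped at 1.0 overall.
    """

    weights: tuple[float, ...]
    perfect_level: float = 0.1
    seed_boost: float = 2.5
    wobble_relief: float = 0.5
    base_modifiers: Mapping[str, float] = field(
        default_factory=lambda: MappingProxyType({"A": 1.0, "C": 0.9, "G": 1.15, "T": 1.05})
    )
    te_gamma: float = 1.0
    other_expression: float = 0.7
    multisite_levels: Mapping[str, float] = field(
        default_factory=lambda: MappingProxyType({"perfect_2x": 0.05, "perfect_4x": 0.03})
    )

    def __post_init__(self) -> None:
        if not 0 < self.perfect_level < 1:
            raise ValueError("perfect_level must be in (0, 1)")
        if self.seed_boost < 1:
            raise ValueError("seed_boost must be >= 1")
        if not 0 < self.wobble_relief <= 1:
            raise ValueError("wobble_relief must be in (0, 1]")
        if any(w < 0 for w in self.weights):
            raise ValueError("weights must be >= 0")

    @classmethod
    def default(cls, mirna: MiRNA, **overrides) -> "GroundTruthModel":
        return cls(weights=_default_weights(mirna), **overrides)


def ground_truth_expression(
    model: GroundTruthModel, variant: MREVariant, mirna: MiRNA
) -> float:
    """True expression fraction of ``variant`` under the simulator model."""
    if variant.tag in ("control_nontargeted", "scrambled"):
        return 1.0
    if variant.tag == "control_multisite":
        raise ValueError(
            "multi-site controls are measured, never predicted by the single-site model"
        )
    if variant.tag not in ("perfect", "single", "double", "multi"):
        raise ValueError(f"unknown variant tag {variant.tag!r}")
    if len(model.weights) != mirna.length:
        raise ValueError("model weights length != miRNA length")
    relief = 1.0
    for pos, alt in variant.substitutions:
        g = model.weights[pos - 1] * model.base_modifiers.get(alt, 1.0)
        if mirna.region(pos) == "seed":
            g *= model.seed_boost
        if classify_pair(mirna.base(pos), alt) == "wobble":
            g *= model.wobble_relief
        relief *= 1.0 + g
    return min(1.0, model.perfect_level * relief)


#: default read depths per amplicon library; pDNA/cDNA sized so every
#: single-nt variant is expected well above the screen's observed minimum
#: coverage of 6000 reads (0.91^22 * 0.03 * depth ~ 7500 at 2e6).
_DEFAULT_DEPTHS = MappingProxyType(
    {"pDNA": 2_000_000, "cDNA": 2_000_000, "monosome": 1_000_000, "heavy": 1_000_000}
)


@dataclass(frozen=True)
class ScreenSimConfig:
    """Configuration of one simulated pooled screen (seed is mandatory)."""

    mirna: MiRNA
    model: GroundTruthModel
    seed: int
    match_frac: float = 0.91
    replicates: int = 3
    depths: Mapping[str, int] = field(default_factory=lambda: dict(_DEFAULT_DEPTHS))
    control_spike: float = 0.01
    max_enumerated_mismatches: int = 2
    flank5: str = "GCCTCGACTGTGCCTTCTAGT"
    flank3: str = "TGGCCGCAATAAAATATCTTT"
    read_len: int = 150
    error_rate: float = 1e-3

    def __post_init__(self) -> None:
        if not 0 < self.match_frac <= 1:
            raise ValueError("match_frac must be in (0, 1]")
        if any(d <= 0 for d in self.depths.values()):
            raise ValueError("depths must be > 0")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if not 0 <= self.error_rate <= 0.1:
            raise ValueError("error_rate must be in [0, 0.1]")
        if not 0 <= self.control_spike < 1:
            raise ValueError("control_spike must be in [0, 1)")
        if self.seed is None:
            raise ValueError("an explicit rng seed is required")
        for fl in (self.flank5, self.flank3):
            if any(b not in DNA_BASES for b in fl):
                raise ValueError("flanks must be ACGT only")


@dataclass(frozen=True)
class SimulatedScreen:
    """Output of :func:`simulate_screen`: count tables plus the ground truth."""

    config: ScreenSimConfig
    variants: tuple[MREVariant, ...]
    truth: Mapping[str, float]
    design_frequency: Mapping[str, float]
    tables: Mapping[str, tuple[CountTable, ...]]

    def sequences(self) -> dict[str, str]:
        """variant_id -> MRE sequence map for every countable amplicon."""
        seqs = {v.variant_id: v.mre_sequence for v in self.variants}
        seqs[CONTROL_NONTARGETED_ID] = CONTROL_NONTARGETED_SITE[: self.config.mirna.length]
        return seqs


def simulate_screen(cfg: ScreenSimConfig) -> SimulatedScreen:
    """Draw pDNA / cDNA / monosome / heavy count tables for each replicate.

    pDNA counts are multinomial over the enumerated k <= 2 variants, the
    non-targeted spike-in and an "other" bucket holding the k >= 3 design
    mass. cDNA frequencies are proportional to design frequency x true
    expression; monosome and heavy-polysome frequencies additionally encode
    a per-variant heavy/monosome ratio of expression**te_gamma. Only
    libraries named in ``cfg.depths`` are drawn.
    """
    mirna = cfg.mirna
    comp = degenerate_composition(mirna, cfg.match_frac)
    variants: list[MREVariant] = []
    for k in range(cfg.max_enumerated_mismatches + 1):
        variants.extend(enumerate_variants(mirna, k))
    ids = [v.variant_id for v in variants]

    design = np.array([expected_frequency(comp, v) for v in variants])
    truth = np.array([ground_truth_expression(cfg.model, v, mirna) for v in variants])

    # categories: enumerated variants, spike-in control, then "other"
    spike = cfg.control_spike
    p_pdna = np.empty(len(variants) + 2)
    p_pdna[:-2] = design * (1.0 - spike)
    p_pdna[-2] = spike
    p_pdna[-1] = (1.0 - spike) * (1.0 - design.sum())
    expr = np.concatenate([truth, [1.0, cfg.model.other_expression]])

    weights = {
        "pDNA": p_pdna,
        "cDNA": p_pdna * expr,
        "monosome": p_pdna * expr,
        "heavy": p_pdna * expr * expr**cfg.model.te_gamma,
    }

    rng = np.random.default_rng(cfg.seed)
    all_ids = ids + [CONTROL_NONTARGETED_ID]
    tables: dict[str, list[CountTable]] = {lib: [] for lib in cfg.depths}
    for rep in range(1, cfg.replicates + 1):
        for lib, depth in cfg.depths.items():
            if lib not in weights:
                raise ValueError(f"unknown library {lib!r}")
            p = weights[lib] / weights[lib].sum()
            counts = rng.multinomial(int(depth), p)
            tables[lib].append(
                CountTable(
                    library_id=lib,
                    replicate=rep,
                    counts=dict(zip(all_ids, counts[:-1].tolist())),
                    other_count=int(counts[-1]),
                )
            )

    truth_map = dict(zip(ids, truth.tolist()))
    truth_map[CONTROL_NONTARGETED_ID] = 1.0
    design_map = dict(zip(ids, design.tolist()))
    return SimulatedScreen(
        config=cfg,
        variants=tuple(variants),
        truth=truth_map,
        design_frequency=design_map,
        tables={lib: tuple(ts) for lib, ts in tables.items()},
    )


def reads_from_counts(
    counts: CountTable,
    sequences: Mapping[str, str],
    flank5: str,
    flank3: str,
    read_len: int = 150,
    err_rate: float = 0.0,
    seed: int = 0,
) -> list[tuple[str, str, str]]:
    """Expand a count table into single-end amplicon reads.

    Each read is flank5 + variant + flank3, padded with downstream vector
    sequence ('A') or truncated to ``read_len``; independent per-base
    substitution errors at ``err_rate``; Phred+33 qualities (constant Q40).
    Reads for the "other" bucket are drawn uniformly at random (they carry
    no enumerated variant). Returns (read_id, sequence, quality) triples in
    shuffled order.
    """
    for fl in (flank5, flank3):
        if any(b not in DNA_BASES for b in fl):
            raise ValueError("flanks must be ACGT only")
    lengths = {len(s) for s in sequences.values()}
    if lengths and read_len < len(flank5) + max(lengths):
        raise ValueError("read_len must cover flank5 plus the variable region")
    rng = np.random.default_rng(seed)
    base_arr = np.frombuffer(DNA_BASES.encode(), dtype=np.uint8)

    templates: list[tuple[str, str]] = []
    for vid, n in counts.counts.items():
        if n < 0:
            raise ValueError("negative count")
        if n == 0:
            continue
        if vid not in sequences:
            raise KeyError(f"no sequence for variant {vid!r}")
        t = (flank5 + sequences[vid] + flank3).ljust(read_len, "A")[:read_len]
        templates.extend([(vid, t)] * n)

    reads: list[tuple[str, str, str]] = []
    qual = "I" * read_len  # Phred+33 Q40
    for i, (vid, t) in enumerate(templates):
        seq = t
        if err_rate > 0:
            arr = np.frombuffer(t.encode(), dtype=np.uint8).copy()
            hits = np.nonzero(rng.random(read_len) < err_rate)[0]
            if hits.size:
                # substitute with one of the three other bases
                for j in hits:
                    choices = base_arr[base_arr != arr[j]]
                    arr[j] = rng.choice(choices)
                seq = arr.tobytes().decode()
        reads.append((f"read_{i}:{vid}", seq, qual))

    for j in range(counts.other_count):
        seq = "".join(rng.choice(list(DNA_BASES), size=read_len))
        reads.append((f"read_other_{j}", seq, qual))

    rng.shuffle(reads)  # type: ignore[arg-type]
    return reads


@dataclass(frozen=True)
class SimulatedKnockin:
    """Output of :func:`simulate_knockin`: tables, truth and expected frequencies."""

    truth: Mapping[str, float]
    gdna_probs: Mapping[str, float]
    cdna_probs: Mapping[str, float]
    tables: Mapping[str, tuple[CountTable, ...]]


def simulate_knockin(
    donor_expression: Mapping[str, float],
    hdr_freqs: Mapping[str, float],
    wt_frac: float,
    depths: Mapping[str, int],
    seed: int,
    replicates: int = 3,
    digest_efficiency: float = 1.0,
) -> SimulatedKnockin:
    """Draw pooled knock-in gDNA / cDNA count tables.

    gDNA allele frequencies are the HDR donor frequencies plus a wild-type
    fraction; cDNA frequencies are allele frequency x true expression
    (scrambled and wild type = 1.0), renormalised. ``digest_efficiency`` is
    the fraction of wild-type amplicons removed by restriction digestion of
    the intact site before sequencing (applied to both libraries).
    """
    ids = list(donor_expression)
    f = np.array([hdr_freqs[d] for d in ids], dtype=float)
    if (f < 0).any() or wt_frac < 0:
        raise ValueError("allele fractions must be >= 0")
    if not np.isclose(f.sum() + wt_frac, 1.0, atol=1e-9):
        raise ValueError("hdr_freqs + wt_frac must sum to 1")
    if not 0 <= digest_efficiency <= 1:
        raise ValueError("digest_efficiency must be in [0, 1]")

    expr = np.array([donor_expression[d] for d in ids], dtype=float)
    keep_wt = wt_frac * (1.0 - digest_efficiency)
    g = np.concatenate([f, [keep_wt]])
    g = g / g.sum()
    c = np.concatenate([f * expr, [keep_wt * 1.0]])
    c = c / c.sum()

    all_ids = ids + ["WT"]
    rng = np.random.default_rng(seed)
    tables: dict[str, list[CountTable]] = {"gDNA": [], "cDNA": []}
    probs = {"gDNA": g, "cDNA": c}
    for rep in range(1, replicates + 1):
        for lib in ("gDNA", "cDNA"):
            if lib not in depths:
                raise ValueError(f"depth for {lib!r} required")
            counts = rng.multinomial(int(depths[lib]), probs[lib])
            tables[lib].append(
                CountTable(
                    library_id=lib,
                    replicate=rep,
                    counts=dict(zip(all_ids, counts.tolist())),
                    other_count=0,
                )
            )
    return SimulatedKnockin(
        truth=dict(zip(ids, expr.tolist())),
        gdna_probs=dict(zip(all_ids, g.tolist())),
        cdna_probs=dict(zip(all_ids, c.tolist())),
        tables={lib: tuple(ts) for lib, ts in tables.items()},
    )
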