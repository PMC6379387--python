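"""Per-variant expression estimates from amplicon reads or count tables.

The estimator chain mirrors the screen's read-out: trim each read down to
the variable region by exact 5'-flank location, count exact matches against
the enumerated variant set, normalise counts to library totals, divide cDNA
frequency by pDNA frequency (transcript abundance), divide heavy-polysome
frequency by monosome frequency (translational efficiency), normalise to a
non-targeted control, and aggregate replicates as mean +/- sample s.d.

No error-tolerant read assignment is attempted: a sequencing error inside
the variable region either lands on another enumerated variant or falls in
the "other" bucket, matching the exact-trim approach of the assay.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .mre import MiRNA, parse_variant_id

__all__ = [
    "CountTable",
    "trim_and_count",
    "frequencies",
    "transcript_abundance",
    "normalize_to_control",
    "translational_efficiency",
    "aggregate_replicates",
    "quantify_screen",
    "mean_fold_derepression",
    "position_effect_matrix",
    "ddct",
    "aggregate_pcr_error",
]


@dataclass
class CountTable:
    """Per-library, per-replicate read counts over an enumerated variant set.

    ``other_count`` absorbs every read that did not match an enumerated
    variant exactly; ``total`` is always counts + other.
    """

    library_id: str
    replicate: int
    counts: dict[str, int]
    other_count: int = 0

    def __post_init__(self) -> None:
        if self.other_count < 0 or any(c < 0 for c in self.counts.values()):
            raise ValueError("counts must be non-negative")

    @property
    def total(self) -> int:
        return sum(self.counts.values()) + self.other_count


def trim_and_count(
    reads: Iterable,
    variant_sequences: Mapping[str, str],
    flank5: str,
    flank3: str = "",
    library_id: str = "reads",
    replicate: int = 1,
) -> CountTable:
    """Count exact variant occurrences in amplicon reads.

    For each read the 5' flank is located exactly; the following L bases
    (L = variant length) are looked up in ``variant_sequences``. Reads with
    no flank match, a truncated variable region, or an unenumerated variable
    region increment ``other_count``. ``reads`` may yield Bio.SeqRecord
    objects, (id, sequence, quality) triples, or plain sequence strings.
    """
    if not variant_sequences:
        raise ValueError("variant set must not be empty")
    lengths = {len(s) for s in variant_sequences.values()}
    if len(lengths) != 1:
        raise ValueError("all variant sequences must share one length")
    L = lengths.pop()
    lookup = {seq: vid for vid, seq in variant_sequences.items()}
    if len(lookup) != len(variant_sequences):
        raise ValueError("variant sequences must be unique")

    counts = {vid: 0 for vid in variant_sequences}
    other = 0
    for read in reads:
        if isinstance(read, str):
            seq = read
        elif isinstance(read, tuple):
            seq = read[1]
        else:  # Bio.SeqRecord
            seq = str(read.seq)
        seq = seq.upper()
        i = seq.find(flank5)
        if i < 0:
            other += 1
            continue
        mre = seq[i + len(flank5) : i + len(flank5) + L]
        vid = lookup.get(mre)
        if vid is None:
            other += 1
        else:
            counts[vid] += 1
    return CountTable(
        library_id=library_id, replicate=replicate, counts=counts, other_count=other
    )


def frequencies(table: CountTable, pseudocount: float = 0.0) -> dict[str, float]:
    """Per-variant read frequency, normalised to total library reads.

    The denominator includes ``other_count`` (total retained reads); with a
    pseudocount, each of the V variant categories plus the other bucket
    receives it, keeping frequencies summing to 1.
    """
    if table.total == 0:
        raise ValueError(f"count table {table.library_id}/{table.replicate} is empty")
    denom = table.total + pseudocount * (len(table.counts) + 1)
    return {vid: (c + pseudocount) / denom for vid, c in table.counts.items()}


def transcript_abundance(
    cdna_freqs: Mapping[str, float], pdna_freqs: Mapping[str, float]
) -> dict[str, float]:
    """cDNA frequency / pDNA frequency per variant.

    Variants absent from the pDNA pool (frequency 0) cannot be ratioed and
    are flagged missing (NaN) rather than dropped.
    """
    out: dict[str, float] = {}
    for vid, cf in cdna_freqs.items():
        pf = pdna_freqs.get(vid, 0.0)
        out[vid] = cf / pf if pf > 0 else float("nan")
    return out


def normalize_to_control(
    abundance: Mapping[str, float], control_id: str
) -> dict[str, float]:
    """Express each abundance relative to the non-targeted control (= 1)."""
    ctrl = abundance.get(control_id)
    if ctrl is None or not math.isfinite(ctrl) or ctrl <= 0:
        raise ValueError(f"control {control_id!r} absent or without positive abundance")
    return {vid: a / ctrl for vid, a in abundance.items()}


def translational_efficiency(
    heavy_freqs: Mapping[str, float], mono_freqs: Mapping[str, float]
) -> dict[str, float]:
    """Heavy-polysome frequency / monosome frequency per variant (NaN if mono = 0)."""
    out: dict[str, float] = {}
    for vid, hf in heavy_freqs.items():
        mf = mono_freqs.get(vid, 0.0)
        out[vid] = hf / mf if mf > 0 else float("nan")
    return out


def aggregate_replicates(per_replicate: Sequence[Mapping[str, float]]) -> pd.DataFrame:
    """Mean and sample s.d. (ddof=1) per variant across replicates.

    Missing (NaN) replicate values are excluded; the number of replicates
    actually used is recorded in ``n``. With a single usable replicate the
    s.d. is NaN (undefined), not zero.
    """
    if not per_replicate:
        raise ValueError("at least one replicate required")
    df = pd.DataFrame(per_replicate).T  # variants x replicates
    out = pd.DataFrame(
        {
            "mean": df.mean(axis=1, skipna=True),
            "sd": df.std(axis=1, ddof=1, skipna=True),
            "n": df.notna().sum(axis=1),
        }
    )
    out.index.name = "variant_id"
    return out


def quantify_screen(
    tables: Mapping[str, Sequence[CountTable]],
    control_id: str,
    pseudocount: float = 0.0,
) -> pd.DataFrame:
    """Full count-table -> expression-table chain for one screen.

    ``tables`` maps library ids ('pDNA', 'cDNA' and optionally 'monosome',
    'heavy') to per-replicate count tables in matching order. Returns a
    DataFrame indexed by variant_id with per-replicate normalised expression
    columns ``expr_rep<i>``, their ``mean``/``sd``/``n``, and, when polysome
    libraries are present, translational efficiency ``te_rep<i>`` /
    ``te_mean`` / ``te_sd``.
    """
    if "pDNA" not in tables or "cDNA" not in tables:
        raise ValueError("pDNA and cDNA libraries are required")
    n_rep = len(tables["pDNA"])
    if len(tables["cDNA"]) != n_rep:
        raise ValueError("pDNA and cDNA replicate counts differ")

    expr_reps: list[dict[str, float]] = []
    for p_tab, c_tab in zip(tables["pDNA"], tables["cDNA"]):
        pf = frequencies(p_tab, pseudocount)
        cf = frequencies(c_tab, pseudocount)
        expr_reps.append(normalize_to_control(transcript_abundance(cf, pf), control_id))
    out = aggregate_replicates(expr_reps)
    for i, rep in enumerate(expr_reps, 1):
        out[f"expr_rep{i}"] = pd.Series(rep)

    if "monosome" in tables and "heavy" in tables:
        te_reps = []
        for h_tab, m_tab in zip(tables["heavy"], tables["monosome"]):
            te_reps.append(
                translational_efficiency(
                    frequencies(h_tab, pseudocount), frequencies(m_tab, pseudocount)
                )
            )
        te = aggregate_replicates(te_reps)
        out["te_mean"] = te["mean"]
        out["te_sd"] = te["sd"]
        for i, rep in enumerate(te_reps, 1):
            out[f"te_rep{i}"] = pd.Series(rep)
    return out


def mean_fold_derepression(
    singles: Mapping[str, float], perfect_expression: float
) -> tuple[float, float]:
    """Mean fold-change of single-variant expression over the perfect MRE.

    Returns (mean fold, half-width of a normal-approximation 95% CI,
    1.96 * sd / sqrt(n)).
    """
    if perfect_expression <= 0:
        raise ValueError("perfect MRE expression must be positive")
    folds = np.array([v / perfect_expression for v in singles.values()], dtype=float)
    if folds.size == 0:
        raise ValueError("no single variants supplied")
    ci = 1.96 * folds.std(ddof=1) / math.sqrt(folds.size) if folds.size > 1 else 0.0
    return float(folds.mean()), float(ci)


def position_effect_matrix(
    mean_expression: Mapping[str, float], mirna: MiRNA
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-position effect matrices over single and double variants.

    Returns (single, double): ``single`` is alt base (A/C/G/T) x miRNA
    position with NaN at each position's complementary base; ``double`` is
    the symmetric position x position matrix of mean expression over the
    (up to 9) base combinations per pair, NaN on the diagonal. Variant ids
    that do not parse as canonical substitution ids (controls) are ignored.
    """
    L = mirna.length
    single = pd.DataFrame(np.nan, index=list("ACGT"), columns=range(1, L + 1))
    dsum = np.zeros((L, L))
    dcnt = np.zeros((L, L), dtype=int)
    for vid, val in mean_expression.items():
        try:
            subs = sorted(parse_variant_id(vid))
        except ValueError:
            continue
        if len(subs) == 1:
            (pos, alt), = subs
            single.loc[alt, pos] = val
        elif len(subs) == 2:
            (p1, _), (p2, _) = subs
            dsum[p1 - 1, p2 - 1] += val
            dcnt[p1 - 1, p2 - 1] += 1
    with np.errstate(invalid="ignore"):
        dmat = np.where(dcnt > 0, dsum / np.maximum(dcnt, 1), np.nan)
    dmat = np.where(np.isnan(dmat) & ~np.isnan(dmat.T), dmat.T, dmat)
    np.fill_diagonal(dmat, np.nan)
    double = pd.DataFrame(dmat, index=range(1, L + 1), columns=range(1, L + 1))
    return single, double


def ddct(
    ct_target: float,
    ct_ref: float,
    ct_target_control: float,
    ct_ref_control: float,
) -> float:
    """Relative expression by the delta-delta-Ct method.

    2**-((ct_target - ct_ref) - (ct_target_control - ct_ref_control)); the
    reference gene is the unsilenced internal control transcript.
    """
    for ct in (ct_target, ct_ref, ct_target_control, ct_ref_control):
        if not math.isfinite(ct):
            raise ValueError("Ct values must be finite")
    return 2.0 ** -((ct_target - ct_ref) - (ct_target_control - ct_ref_control))


def aggregate_pcr_error(cycles: int, per_base_rate: float) -> float:
    """Upper bound on the per-base error accumulated over PCR cycles.

    Linear accumulation (cycles x per-cycle polymerase error rate), the
    conservative bound used to argue amplification error cannot distort
    variant frequencies.
    """
    if cycles < 0 or per_base_rate < 0:
        raise ValueError("cycles and rate must be non-negative")
    return cycles * per_base_rate
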