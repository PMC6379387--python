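"""Pooled ssODN donor design and endogenous knock-in quantification.

Fine-tuner elements are short enough to be written into a native 3'UTR by
CRISPR/Cas9 homology-directed repair with single-stranded oligonucleotide
(ssODN) donors. Each donor carries one MRE insert plus a diagnostic NheI
site, flanked by homology arms, and ablates the locus's endogenous SacI
site so that wild-type (unedited) amplicons can be removed by restriction
digestion before sequencing. Expression per donor is the cDNA/gDNA
frequency ratio normalised to a scrambled-MRE control; repression is one
minus that.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .mre import DNA_BASES, MiRNA, make_variant, parse_variant_id, perfect_mre, reverse_complement
from .quantify import CountTable, aggregate_replicates, frequencies

__all__ = [
    "SACI_SITE",
    "NHEI_SITE",
    "Donor",
    "DonorPanel",
    "build_donor_panel",
    "scrambled_mre",
    "digest_filter",
    "knockin_expression",
    "aggregate_knockin",
    "expected_repression_sd",
]

SACI_SITE = "GAGCTC"
NHEI_SITE = "GCTAGC"


def scrambled_mre(mirna: MiRNA, seed: int = 17) -> str:
    """A scrambled control insert: the perfect MRE's bases in fixed shuffled order.

    Same length and base composition as the perfect site but without
    miRNA complementarity; deterministic for a given seed.
    """
    rng = np.random.default_rng(seed)
    bases = list(perfect_mre(mirna).mre_sequence)
    for _ in range(100):
        rng.shuffle(bases)
        seq = "".join(bases)
        if (
            seq != perfect_mre(mirna).mre_sequence
            and SACI_SITE not in seq
            and NHEI_SITE not in seq
        ):
            return seq
    raise RuntimeError("could not scramble without creating a restriction site")


@dataclass(frozen=True)
class Donor:
    donor_id: str
    insert: str  # MRE (+ spacer for tandem sites) + NheI site
    ssodn: str  # arm5 + edited locus core + arm3


@dataclass(frozen=True)
class DonorPanel:
    """A pooled HDR donor panel sharing homology arms and restriction edits."""

    donors: tuple[Donor, ...]
    arm_length: int
    ablated_site: str = SACI_SITE
    introduced_site: str = NHEI_SITE
    scrambled_id: str = "scrambled"

    def __post_init__(self) -> None:
        ids = [d.donor_id for d in self.donors]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate donor ids")
        arms5 = {d.ssodn[: self.arm_length] for d in self.donors}
        arms3 = {d.ssodn[-self.arm_length :] for d in self.donors}
        if len(arms5) != 1 or len(arms3) != 1:
            raise ValueError("homology arms must be identical across donors")
        for d in self.donors:
            if _site_present(d.ssodn, self.ablated_site):
                raise ValueError(f"donor {d.donor_id} retains the ablated site")
            if not _site_present(d.ssodn, self.introduced_site):
                raise ValueError(f"donor {d.donor_id} lacks the introduced site")

    def ids(self) -> list[str]:
        return [d.donor_id for d in self.donors]

    def sequences(self) -> dict[str, str]:
        return {d.donor_id: d.ssodn for d in self.donors}


def _site_present(seq: str, site: str) -> bool:
    """Site present on either strand (restriction enzymes cut dsDNA)."""
    return site in seq or reverse_complement(site, "DNA") in seq


def _ablate(site: str) -> str:
    """Single-base substitution destroying a recognition site (last base cycled)."""
    last = site[-1]
    alt = DNA_BASES[(DNA_BASES.index(last) + 1) % 4]
    return site[:-1] + alt


def build_donor_panel(
    variant_ids: Sequence[str],
    mirna: MiRNA,
    locus: str,
    arms: int = 45,
    spacer: str = "ACT",
) -> DonorPanel:
    """Design the 18-donor knock-in pool for a target locus.

    ``variant_ids`` are 15 distinct canonical single/double variant ids;
    the panel adds 1x and 2x perfectly complementary sites and a scrambled
    control (18 donors). ``locus`` is the reference 3'UTR segment (plain
    sequence, 5'->3') and must contain the SacI site to ablate with at
    least ``arms`` nt of flank on both sides. Each ssODN is
    arm5 + SacI-ablated core + MRE insert + NheI + arm3; the ablation is a
    single synonymous-style base substitution outside the insert.
    """
    if len(variant_ids) != 15:
        raise ValueError(f"exactly 15 variant ids required, got {len(variant_ids)}")
    if len(set(variant_ids)) != 15:
        raise ValueError("duplicate variant ids in panel")
    locus = locus.upper()
    s = locus.find(SACI_SITE)
    if s < 0:
        raise ValueError("locus does not contain a SacI site (GAGCTC) to ablate")
    if s < arms or len(locus) < s + len(SACI_SITE) + arms:
        raise ValueError(f"locus needs >= {arms} nt of flank on both sides of the SacI site")

    arm5 = locus[s - arms : s]
    arm3 = locus[s + len(SACI_SITE) : s + len(SACI_SITE) + arms]
    core = _ablate(SACI_SITE)
    perfect = perfect_mre(mirna).mre_sequence

    inserts: dict[str, str] = {}
    for vid in variant_ids:
        inserts[vid] = make_variant(mirna, parse_variant_id(vid)).mre_sequence
    inserts["perfect_1x"] = perfect
    inserts["perfect_2x"] = perfect + spacer + perfect
    inserts["scrambled"] = scrambled_mre(mirna)

    donors = []
    for donor_id, mre in inserts.items():
        insert = mre + NHEI_SITE
        donors.append(Donor(donor_id=donor_id, insert=insert, ssodn=arm5 + core + insert + arm3))
    return DonorPanel(donors=tuple(donors), arm_length=arms)


def digest_filter(reads, site: str = SACI_SITE):
    """Emulate restriction digestion: drop records containing ``site`` on either strand.

    ``reads`` may yield Bio.SeqRecords, (id, sequence, quality) triples, or
    plain strings. Returns (retained records, retention fraction);
    idempotent by construction.
    """
    if not site:
        raise ValueError("site must be non-empty")
    rc = reverse_complement(site, "DNA")
    retained = []
    total = 0
    for read in reads:
        if isinstance(read, str):
            seq = read
        elif isinstance(read, tuple):
            seq = read[1]
        else:
            seq = str(read.seq)
        total += 1
        seq = seq.upper()
        if site not in seq and rc not in seq:
            retained.append(read)
    fraction = len(retained) / total if total else 0.0
    return retained, fraction


def knockin_expression(
    gdna: CountTable, cdna: CountTable, scrambled_id: str = "scrambled"
) -> pd.DataFrame:
    """Per-donor expression and repression for one replicate.

    expression = (cDNA freq / gDNA freq) normalised to the scrambled
    control; repression = 1 - expression. Donors with zero gDNA frequency
    are flagged missing (NaN). The wild-type bucket ('WT'), if present, is
    excluded from the result.
    """
    gf = frequencies(gdna)
    cf = frequencies(cdna)
    if gf.get(scrambled_id, 0) <= 0 or cf.get(scrambled_id, 0) <= 0:
        raise ValueError(f"scrambled control {scrambled_id!r} must have counts in both tables")
    scr = (cf[scrambled_id] / gf[scrambled_id])
    rows = {}
    for donor_id in gdna.counts:
        if donor_id == "WT":
            continue
        g = gf[donor_id]
        c = cf.get(donor_id, 0.0)
        expr = (c / g) / scr if g > 0 else float("nan")
        rows[donor_id] = {
            "gdna_freq": g,
            "cdna_freq": c,
            "expression": expr,
            "repression": 1.0 - expr if math.isfinite(expr) else float("nan"),
        }
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index.name = "donor_id"
    return df


def aggregate_knockin(
    gdna_tables: Sequence[CountTable],
    cdna_tables: Sequence[CountTable],
    scrambled_id: str = "scrambled",
) -> pd.DataFrame:
    """Replicate-aggregated knock-in result (mean/sd of expression and repression)."""
    if len(gdna_tables) != len(cdna_tables) or not gdna_tables:
        raise ValueError("matched, non-empty gDNA/cDNA replicate lists required")
    per_rep = [
        knockin_expression(g, c, scrambled_id)
        for g, c in zip(gdna_tables, cdna_tables)
    ]
    expr = aggregate_replicates([df["expression"].to_dict() for df in per_rep])
    out = pd.DataFrame(
        {
            "gdna_freq": aggregate_replicates([df["gdna_freq"].to_dict() for df in per_rep])["mean"],
            "cdna_freq": aggregate_replicates([df["cdna_freq"].to_dict() for df in per_rep])["mean"],
            "expression": expr["mean"],
            "expression_sd": expr["sd"],
            "n": expr["n"],
        }
    )
    out["repression"] = 1.0 - out["expression"]
    out["repression_sd"] = out["expression_sd"]
    out.index.name = "donor_id"
    return out


def expected_repression_sd(
    gdna_probs: Mapping[str, float],
    cdna_probs: Mapping[str, float],
    depths: Mapping[str, int],
    scrambled_id: str = "scrambled",
) -> dict[str, float]:
    """Delta-method sampling s.d. of a single replicate's repression estimate.

    The estimator is a ratio of four multinomial frequencies; on the log
    scale its variance is approximately the sum of 1/E[count] over the four
    counts involved, so sd(repression) ~ expression * sqrt(sum 1/E[count]).
    Useful for checking recovered repression against ground truth at the
    simulation's own noise scale.
    """
    out = {}
    gs = gdna_probs[scrambled_id] * depths["gDNA"]
    cs = cdna_probs[scrambled_id] * depths["cDNA"]
    scr_ratio = cdna_probs[scrambled_id] / gdna_probs[scrambled_id]
    for donor_id, gp in gdna_probs.items():
        if donor_id in ("WT", scrambled_id):
            continue
        cp = cdna_probs[donor_id]
        eg = gp * depths["gDNA"]
        ec = cp * depths["cDNA"]
        expr = (cp / gp) / scr_ratio
        var_log = 1.0 / eg + 1.0 / ec + 1.0 / gs + 1.0 / cs
        out[donor_id] = expr * math.sqrt(var_log)
    return out
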