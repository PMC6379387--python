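"""File-format plumbing: TSV count/expression tables, FASTA/FASTQ, YAML config.

TSV with a header row is the interchange format between pipeline stages;
sequences travel as FASTA/FASTQ (Phred+33). Count tables use a long format
(library, replicate, variant_id, count) with the reserved variant_id
``__other__`` for unassigned reads.
"""

from __future__ import annotations

import os
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .mre import MiRNA, MREVariant, pairing_profile
from .quantify import CountTable

OTHER_ROW_ID = "__other__"

__all__ = [
    "OTHER_ROW_ID",
    "write_count_tables",
    "read_count_tables",
    "write_fastq",
    "read_fastq",
    "variants_to_fasta",
    "variants_to_tsv",
    "sequences_to_fasta",
    "write_tsv",
    "load_config",
]


def write_count_tables(tables: Iterable[CountTable], path: str | os.PathLike) -> None:
    """Write count tables to one long-format TSV (atomically via a temp file)."""
    rows = []
    for t in tables:
        for vid, c in t.counts.items():
            rows.append((t.library_id, t.replicate, vid, c))
        rows.append((t.library_id, t.replicate, OTHER_ROW_ID, t.other_count))
    df = pd.DataFrame(rows, columns=["library", "replicate", "variant_id", "count"])
    _atomic_write(path, df.to_csv(sep="\t", index=False))


def read_count_tables(path: str | os.PathLike) -> dict[str, list[CountTable]]:
    """Read a long-format count TSV back into per-library replicate lists."""
    df = pd.read_csv(path, sep="\t", dtype={"variant_id": str})
    required = {"library", "replicate", "variant_id", "count"}
    if not required.issubset(df.columns):
        raise ValueError(f"count TSV {path} must have columns {sorted(required)}")
    out: dict[str, list[CountTable]] = {}
    for (lib, rep), grp in df.groupby(["library", "replicate"], sort=True):
        counts = dict(zip(grp["variant_id"], grp["count"].astype(int)))
        other = counts.pop(OTHER_ROW_ID, 0)
        out.setdefault(lib, []).append(
            CountTable(library_id=lib, replicate=int(rep), counts=counts, other_count=other)
        )
    for lib in out:
        out[lib].sort(key=lambda t: t.replicate)
    return out


def write_fastq(reads: Iterable[tuple[str, str, str]], path: str | os.PathLike) -> int:
    """Write (id, sequence, quality) triples as Phred+33 FASTQ; returns record count."""
    records = []
    for rid, seq, qual in reads:
        rec = SeqRecord(Seq(seq), id=rid, description="")
        rec.letter_annotations["phred_quality"] = [ord(q) - 33 for q in qual]
        records.append(rec)
    return SeqIO.write(records, os.fspath(path), "fastq")


def read_fastq(path: str | os.PathLike):
    """Iterate FASTQ records (Bio.SeqRecord)."""
    return SeqIO.parse(os.fspath(path), "fastq")


def variants_to_fasta(variants: Sequence[MREVariant], path: str | os.PathLike) -> int:
    """Export variants as FASTA, id = canonical variant id."""
    records = [
        SeqRecord(Seq(v.mre_sequence), id=v.variant_id, description="") for v in variants
    ]
    return SeqIO.write(records, os.fspath(path), "fasta")


def sequences_to_fasta(seqs: Mapping[str, str], path: str | os.PathLike) -> int:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    return SeqIO.write(records, os.fspath(path), "fasta")


def variants_to_tsv(
    variants: Sequence[MREVariant], mirna: MiRNA, path: str | os.PathLike
) -> pd.DataFrame:
    """Export variants as TSV: id, sequence, substituted positions/bases/classes."""
    rows = []
    for v in variants:
        prof = pairing_profile(mirna, v)
        subs = sorted(v.substitutions)
        rows.append(
            {
                "variant_id": v.variant_id,
                "mre_sequence": v.mre_sequence,
                "n_mismatches": v.n_mismatches,
                "positions": ",".join(str(p) for p, _ in subs),
                "alt_bases": ",".join(b for _, b in subs),
                "pairing_classes": ",".join(prof.pairing_class(p) for p, _ in subs),
                "regions": ",".join(prof.region(p) for p, _ in subs),
            }
        )
    df = pd.DataFrame(rows)
    _atomic_write(path, df.to_csv(sep="\t", index=False))
    return df


def write_tsv(df: pd.DataFrame, path: str | os.PathLike, index: bool = True) -> None:
    """Write a DataFrame as TSV atomically."""
    _atomic_write(path, df.to_csv(sep="\t", index=index))


def load_config(path: str | os.PathLike) -> dict:
    """Load a YAML run configuration into a plain dict."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError(f"config {path} must be a YAML mapping")
    return cfg


def _atomic_write(path: str | os.PathLike, text: str) -> None:
    path = Path(path)
    tmp = path.with_suffix(path.suffix + ".tmp")
    tmp.write_text(text)
    os.replace(tmp, path)
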