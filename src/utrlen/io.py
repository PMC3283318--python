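"""Reading and validating 5'UTR sequence sets.

Sequences are handled in mRNA space: DNA input (``T``) is transparently
converted to RNA (``U``) and lowercase is uppercased.  Records containing
ambiguity codes (``N``, ``R``, ...) after normalization are dropped rather
than masked, because per-sequence base frequencies would be ill-defined on
masked sequences; drops are logged and reported.

When a gene has several transcript isoforms, :func:`select_one_transcript_per_gene`
keeps exactly one, chosen uniformly at random with an explicit seed, so that
genes with many annotated isoforms do not dominate downstream regressions.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence, TextIO

import numpy as np
import pandas as pd
from Bio import SeqIO

logger = logging.getLogger(__name__)

RNA_ALPHABET = frozenset("ACGU")


@dataclass(frozen=True)
class HeaderRule:
    """How to recover gene and transcript identifiers from a FASTA header.

    The first whitespace-delimited token of the header is split on
    ``delimiter``; ``gene_field`` and ``transcript_field`` are 0-based
    indices into the resulting parts.  If the header has too few parts the
    whole token is used as both identifiers.
    """

    delimiter: str = "|"
    gene_field: int = 0
    transcript_field: int = 1


@dataclass(frozen=True)
class UTRRecord:
    """One 5'UTR sequence with its gene/transcript identity."""

    gene_id: str
    transcript_id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.gene_id:
            raise ValueError("gene_id must be non-empty")
        if not self.transcript_id:
            raise ValueError("transcript_id must be non-empty")
        if not self.sequence:
            raise ValueError("sequence must be non-empty")
        if not RNA_ALPHABET.issuperset(self.sequence):
            bad = sorted(set(self.sequence) - RNA_ALPHABET)
            raise ValueError(f"sequence contains non-ACGU characters: {bad}")

    @property
    def length(self) -> int:
        return len(self.sequence)


def normalize_sequence(raw: str) -> str:
    """Uppercase and convert DNA ``T`` to RNA ``U`` (no other changes)."""
    return raw.upper().replace("T", "U")


def _open_maybe_gzip(path: Path) -> TextIO:
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path, "rt")


def _parse_header(token: str, rule: HeaderRule) -> tuple[str, str]:
    parts = token.split(rule.delimiter)
    try:
        return parts[rule.gene_field], parts[rule.transcript_field]
    except IndexError:
        return parts[0] if parts[0] else token, token


def read_utr_fasta(
    path: str | Path,
    header_rule: HeaderRule | None = None,
) -> tuple[list[UTRRecord], pd.DataFrame]:
    """Read a (possibly gzipped) FASTA of 5'UTR sequences.

    Returns the valid records plus a drop report with columns
    ``gene_id, transcript_id, reason`` — one row per record that was
    rejected (empty sequence, or characters outside A/C/G/T/U after
    uppercasing).

    Raises
    ------
    FileNotFoundError
        If the file does not exist.
    ValueError
        If the file contains no FASTA records at all.
    """
    rule = header_rule or HeaderRule()
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)

    records: list[UTRRecord] = []
    drops: list[tuple[str, str, str]] = []
    n_seen = 0
    with _open_maybe_gzip(path) as handle:
        for rec in SeqIO.parse(handle, "fasta"):
            n_seen += 1
            gene_id, transcript_id = _parse_header(rec.id, rule)
            seq = normalize_sequence(str(rec.seq))
            if not seq:
                drops.append((gene_id, transcript_id, "empty_sequence"))
                logger.warning("dropped %s|%s: empty sequence", gene_id, transcript_id)
                continue
            if not RNA_ALPHABET.issuperset(seq):
                drops.append((gene_id, transcript_id, "invalid_alphabet"))
                logger.warning(
                    "dropped %s|%s: non-ACGU characters", gene_id, transcript_id
                )
                continue
            records.append(UTRRecord(gene_id, transcript_id, seq))

    if n_seen == 0:
        raise ValueError(f"no records in {path}")

    drop_report = pd.DataFrame(drops, columns=["gene_id", "transcript_id", "reason"])
    return records, drop_report


def write_utr_fasta(
    records: Iterable[UTRRecord],
    path: str | Path,
    delimiter: str = "|",
) -> None:
    """Write records as FASTA with ``gene<delimiter>transcript`` headers."""
    with open(path, "w") as out:
        for rec in records:
            out.write(f">{rec.gene_id}{delimiter}{rec.transcript_id}\n{rec.sequence}\n")


def select_one_transcript_per_gene(
    records: Sequence[UTRRecord],
    seed: int,
) -> list[UTRRecord]:
    """Keep exactly one transcript per gene, chosen uniformly at random.

    The choice uses a generator seeded with ``seed``; output is sorted by
    gene_id, so the result is fully deterministic given (input, seed).
    """
    by_gene: dict[str, list[UTRRecord]] = {}
    for rec in records:
        by_gene.setdefault(rec.gene_id, []).append(rec)

    rng = np.random.default_rng(seed)
    chosen: list[UTRRecord] = []
    for gene_id in sorted(by_gene):
        group = by_gene[gene_id]
        if len(group) == 1:
            chosen.append(group[0])
        else:
            chosen.append(group[int(rng.integers(len(group)))])
    return chosen
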