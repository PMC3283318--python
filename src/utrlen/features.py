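"""Per-sequence composition features of 5'UTRs.

The regression framework models log10 5'UTR length as a linear function of
nine per-sequence composition features: G+C content, the observed-to-expected
(OE) ratios of the start trinucleotide AUG and the three stop trinucleotides
UGA, UAA, UAG, and the OE ratios of the dinucleotides CG (methylation), UG
(mutation product of CG, subsequence of AUG/UGA), and UU/UA (mRNA
destabilization).  A 0/1 upstream-ORF presence flag can be added as a tenth
covariate.

For a motif m = b1..bk in a sequence of length L with base fractions f_i,
the expected count is

    E[m] = L * f_{b1} * ... * f_{bk}

(the number of windows is taken as L, not L-k+1, matching the standard
closed form for CpG-style OE statistics on long sequences; the L-k+1
alternative is available through ``windows="L-k+1"``).  The OE ratio is the
overlapping sliding-window occurrence count divided by E[m], defined as 0
when the expected count is 0 (some required base absent — in which case the
observed count is necessarily 0 as well).

The *minimal length* for a trinucleotide to occur once by chance is the L
solving E[m] = 1, i.e. the reciprocal of the product of its base
frequencies; short UTRs below this length cannot exhibit selection on that
trinucleotide through the OE statistic.

An upstream ORF (uORF) is one AUG, the first downstream in-frame stop codon
(UAA/UAG/UGA) lying entirely within the 5'UTR, and at least one non-stop
codon in between.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .io import UTRRecord

logger = logging.getLogger(__name__)

START_TRINUCLEOTIDE = "AUG"
STOP_TRINUCLEOTIDES = ("UGA", "UAA", "UAG")
TRINUCLEOTIDES = ("AUG", "UGA", "UAA", "UAG")
DINUCLEOTIDES = ("CG", "UG", "UU", "UA")
TRACKED_MOTIFS = TRINUCLEOTIDES + DINUCLEOTIDES

#: feature-table columns holding the nine candidate predictors, in the
#: canonical model order (G+C, trinucleotide OEs, dinucleotide OEs)
PREDICTORS = [
    "gc",
    "oe_aug",
    "oe_uga",
    "oe_uaa",
    "oe_uag",
    "oe_cg",
    "oe_ug",
    "oe_uu",
    "oe_ua",
]
RESPONSE = "log10_length"

#: minimum sequence length for the feature set (one trinucleotide window)
MIN_FEATURE_LENGTH = 3

_BASES = "ACGU"
_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(_BASES):
    _CODE[ord(_b)] = _i
_DECODE = np.frombuffer(b"ACGU", dtype=np.uint8)


def encode(sequence: str) -> np.ndarray:
    """Encode an RNA string into uint8 codes A=0, C=1, G=2, U=3."""
    raw = np.frombuffer(sequence.encode("ascii"), dtype=np.uint8)
    codes = _CODE[raw]
    if codes.max(initial=0) == 255:
        raise ValueError(f"non-ACGU character in sequence: {sequence!r}")
    return codes


def decode(codes: np.ndarray) -> str:
    return _DECODE[codes].tobytes().decode("ascii")


@dataclass(frozen=True)
class NucleotideFrequencies:
    """Per-sequence base fractions f_A, f_C, f_G, f_U (summing to 1)."""

    freq: Mapping[str, float]

    def __post_init__(self) -> None:
        if set(self.freq) != set(_BASES):
            raise ValueError("frequencies must cover exactly A, C, G, U")
        total = sum(self.freq.values())
        if abs(total - 1.0) > 1e-12:
            raise ValueError(f"frequencies sum to {total}, not 1")

    def __getitem__(self, base: str) -> float:
        return self.freq[base]


def nucleotide_frequencies(sequence: str) -> NucleotideFrequencies:
    """Exact base counts divided by sequence length."""
    if not sequence:
        raise ValueError("degenerate sequence (empty)")
    codes = encode(sequence)
    counts = np.bincount(codes, minlength=4)
    L = len(sequence)
    return NucleotideFrequencies(
        {base: counts[i] / L for i, base in enumerate(_BASES)}
    )


def observed_count(sequence: str, motif: str) -> int:
    """Overlapping sliding-window occurrence count of ``motif``."""
    s = encode(sequence)
    m = encode(motif)
    k, L = len(m), len(s)
    if k == 0:
        raise ValueError("empty motif")
    if k > L:
        return 0
    match = np.ones(L - k + 1, dtype=bool)
    for i in range(k):
        match &= s[i : L - k + 1 + i] == m[i]
    return int(match.sum())


def expected_count(
    freqs: NucleotideFrequencies,
    L: int,
    motif: str,
    windows: str = "L",
) -> float:
    """Expected occurrence count L * prod(f_base) under independent bases.

    ``windows="L-k+1"`` uses the exact number of sliding windows instead of
    L; the difference is negligible for long UTRs.
    """
    if L < 1:
        raise ValueError("L must be >= 1")
    if windows == "L":
        n_win = L
    elif windows == "L-k+1":
        n_win = max(L - len(motif) + 1, 0)
    else:
        raise ValueError(f"unknown windows convention {windows!r}")
    # accumulate left-to-right starting from the window count, matching the
    # vectorized path bit for bit
    out = float(n_win)
    for base in motif:
        out *= freqs[base]
    return out


def oe_ratio(sequence: str, motif: str, windows: str = "L") -> float:
    """Observed/expected ratio; 0 when the expected count is 0 or L < k."""
    if len(sequence) < len(motif):
        return 0.0
    freqs = nucleotide_frequencies(sequence)
    exp = expected_count(freqs, len(sequence), motif, windows=windows)
    if exp == 0.0:
        return 0.0
    return observed_count(sequence, motif) / exp


def gc_content(freqs: NucleotideFrequencies) -> float:
    return freqs["G"] + freqs["C"]


def minimal_length(freqs: NucleotideFrequencies, motif: str) -> float:
    """Shortest L at which ``motif`` is expected once by chance: 1/prod(f).

    Infinite when a required base is absent.
    """
    prod = 1.0
    for base in motif:
        prod *= freqs[base]
    if prod == 0.0:
        return math.inf
    return 1.0 / prod


@dataclass(frozen=True)
class UorfInterval:
    """A uORF: start of its AUG and start of its in-frame stop (0-based)."""

    start: int
    stop_start: int

    def __post_init__(self) -> None:
        span = self.stop_start - self.start
        if span < 6:
            raise ValueError("uORF needs at least one codon between AUG and stop")
        if span % 3 != 0:
            raise ValueError("stop codon not in frame with the AUG")

    @property
    def end(self) -> int:
        """0-based exclusive end (one past the stop codon)."""
        return self.stop_start + 3


_STOP_CODES = tuple(encode(s) for s in STOP_TRINUCLEOTIDES)
_AUG_CODES = encode(START_TRINUCLEOTIDE)


def _find_uorfs_codes(s: np.ndarray) -> list[tuple[int, int]]:
    L = len(s)
    if L < 9:
        return []
    top = L - 2
    aug = (s[0:top] == 0) & (s[1 : top + 1] == 3) & (s[2 : top + 2] == 2)
    stop = np.zeros(top, dtype=bool)
    for m in _STOP_CODES:
        stop |= (s[0:top] == m[0]) & (s[1 : top + 1] == m[1]) & (s[2 : top + 2] == m[2])
    out: list[tuple[int, int]] = []
    for p in np.flatnonzero(aug):
        q = p + 3
        while q + 3 <= L:
            if stop[q]:
                if q - p >= 6:
                    out.append((int(p), int(q)))
                break
            q += 3
    return out


def find_uorfs(sequence: str) -> list[UorfInterval]:
    """All uORFs in a 5'UTR.

    For every AUG the downstream in-frame codons are scanned for the FIRST
    stop codon lying entirely within the sequence; the pair is reported only
    if at least one codon separates them.  AUGs whose first in-frame stop is
    immediately adjacent, or that have no in-frame stop inside the UTR, yield
    nothing (stops inside the downstream CDS are invisible here).
    """
    return [UorfInterval(p, q) for p, q in _find_uorfs_codes(encode(sequence))]


@dataclass(frozen=True)
class FeatureVector:
    """Response and candidate predictors for one 5'UTR."""

    log10_length: float
    gc_content: float
    oe_aug: float
    oe_uga: float
    oe_uaa: float
    oe_uag: float
    oe_cg: float
    oe_ug: float
    oe_uu: float
    oe_ua: float
    uorf_present: int


def feature_vector(record: UTRRecord, windows: str = "L") -> FeatureVector:
    """Assemble the full feature vector for one record (requires L >= 3)."""
    seq = record.sequence
    if record.length < MIN_FEATURE_LENGTH:
        raise ValueError("sequence too short for trinucleotide features")
    freqs = nucleotide_frequencies(seq)
    oe = {m: oe_ratio(seq, m, windows=windows) for m in TRACKED_MOTIFS}
    return FeatureVector(
        log10_length=math.log10(record.length),
        gc_content=gc_content(freqs),
        oe_aug=oe["AUG"],
        oe_uga=oe["UGA"],
        oe_uaa=oe["UAA"],
        oe_uag=oe["UAG"],
        oe_cg=oe["CG"],
        oe_ug=oe["UG"],
        oe_uu=oe["UU"],
        oe_ua=oe["UA"],
        uorf_present=1 if find_uorfs(seq) else 0,
    )


# ---------------------------------------------------------------------------
# bulk (vectorized) feature computation
# ---------------------------------------------------------------------------

def _bulk_features(
    flat: np.ndarray,
    lengths: np.ndarray,
    windows: str = "L",
) -> dict[str, np.ndarray]:
    """Feature columns for many sequences stored as one flat code array.

    ``flat`` concatenates the uint8-encoded sequences; ``lengths`` gives the
    per-sequence lengths (all >= 3).  Returns a dict of per-sequence arrays
    for every column except the uORF flag.
    """
    n = len(lengths)
    lengths = np.asarray(lengths, dtype=np.int64)
    starts = np.concatenate(([0], np.cumsum(lengths)[:-1]))
    seg = np.repeat(np.arange(n), lengths)
    total = flat.size

    base_counts = np.bincount(seg * 4 + flat, minlength=4 * n).reshape(n, 4)
    freqs = base_counts / lengths[:, None]

    # bases remaining at each flat position, including the current one
    remaining = lengths[seg] - (np.arange(total) - starts[seg])

    out: dict[str, np.ndarray] = {
        "length": lengths.copy(),
        "log10_length": np.log10(lengths.astype(float)),
        "gc": freqs[:, 1] + freqs[:, 2],
    }
    for motif in TRACKED_MOTIFS:
        m = encode(motif)
        k = len(m)
        top = total - k + 1
        match = flat[0:top] == m[0]
        for i in range(1, k):
            match = match & (flat[i : top + i] == m[i])
        match &= remaining[:top] >= k
        obs = np.bincount(seg[:top][match], minlength=n)
        if windows == "L":
            n_win = lengths
        else:
            n_win = np.maximum(lengths - k + 1, 0)
        exp = n_win.astype(float)
        for i in range(k):
            exp = exp * freqs[:, m[i]]
        oe = np.zeros(n)
        np.divide(obs, exp, out=oe, where=exp > 0)
        out[f"oe_{motif.lower()}"] = oe

    tri = np.stack([out[f"oe_{m.lower()}"] for m in TRINUCLEOTIDES])
    out["n_zero_tri_oe"] = (tri == 0).sum(axis=0).astype(np.int64)
    return out


def _uorf_present_flat(flat: np.ndarray, lengths: np.ndarray) -> np.ndarray:
    starts = np.concatenate(([0], np.cumsum(lengths)[:-1]))
    present = np.zeros(len(lengths), dtype=np.int64)
    for i, (s0, L) in enumerate(zip(starts, lengths)):
        if L >= 9 and _find_uorfs_codes(flat[s0 : s0 + L]):
            present[i] = 1
    return present


FEATURE_TABLE_COLUMNS = (
    ["gene_id", "transcript_id", "length", "log10_length"]
    + PREDICTORS
    + ["uorf_present", "n_zero_tri_oe"]
)


def features_frame(
    records: Sequence[UTRRecord],
    windows: str = "L",
    include_uorf: bool = True,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Feature table (one row per record) plus a drop report.

    Records shorter than three nucleotides cannot support trinucleotide
    features and are dropped with reason ``too_short``.  Column order
    follows :data:`FEATURE_TABLE_COLUMNS`; the computation convention is
    recorded in ``df.attrs``.
    """
    kept: list[UTRRecord] = []
    drops: list[tuple[str, str, str]] = []
    for rec in records:
        if rec.length < MIN_FEATURE_LENGTH:
            drops.append((rec.gene_id, rec.transcript_id, "too_short"))
            logger.warning(
                "dropped %s|%s: length %d < %d",
                rec.gene_id, rec.transcript_id, rec.length, MIN_FEATURE_LENGTH,
            )
        else:
            kept.append(rec)

    drop_report = pd.DataFrame(drops, columns=["gene_id", "transcript_id", "reason"])
    if not kept:
        df = pd.DataFrame(columns=FEATURE_TABLE_COLUMNS)
        df.attrs["windows"] = windows
        return df, drop_report

    lengths = np.array([r.length for r in kept], dtype=np.int64)
    flat = np.concatenate([encode(r.sequence) for r in kept])
    cols = _bulk_features(flat, lengths, windows=windows)
    if include_uorf:
        cols["uorf_present"] = _uorf_present_flat(flat, lengths)
    else:
        cols["uorf_present"] = np.zeros(len(kept), dtype=np.int64)

    df = pd.DataFrame(
        {
            "gene_id": [r.gene_id for r in kept],
            "transcript_id": [r.transcript_id for r in kept],
            **{c: cols[c] for c in FEATURE_TABLE_COLUMNS[2:]},
        }
    )
    df.attrs["windows"] = windows
    df.attrs["n_dropped_short"] = len(drops)
    return df, drop_report


def write_feature_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_feature_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def uorfs_to_bed(records: Iterable[UTRRecord], path: str | Path) -> int:
    """Write all uORF intervals as BED (0-based, half-open); returns count."""
    n = 0
    with open(path, "w") as out:
        for rec in records:
            for i, u in enumerate(find_uorfs(rec.sequence)):
                out.write(
                    f"{rec.transcript_id}\t{u.start}\t{u.end}\t"
                    f"{rec.gene_id}_uorf{i + 1}\t0\t+\n"
                )
                n += 1
    return n
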