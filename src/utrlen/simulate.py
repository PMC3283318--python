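"""Synthetic 5'UTR sets with planted, known statistical structure.

The generator emulates the aspects of real per-species 5'UTR collections
that the analysis pipeline consumes:

* right-skewed lengths — log-normal with a median near 160 nt;
* per-sequence G+C variation — Beta-distributed G+C content, bases drawn
  iid with P(G)=P(C)=gc/2 and P(A)=P(U)=(1-gc)/2;
* motif enrichment/depletion — a per-motif factor s (1 = neutral) thins or
  plants occurrences so the realized rate is scaled toward s times the
  neutral expectation;
* a planted linear relationship — log10 length is drawn as
  b0 + sum_k b_k (x_k - mean(x_k)) + eps with eps ~ N(0, noise_sd), where
  the covariates x_k are the *generative* G+C value and motif factors.

Effects are planted on generative covariates and then re-measured from the
realized sequences, so coefficient-recovery checks face the same
errors-in-variables attenuation as the real analysis; the helper
:func:`recovery_analysis` estimates the per-covariate reliability slope and
reports attenuation-corrected coefficients with delta-method standard
errors.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from . import features as ft
from .features import RESPONSE, decode, encode
from .io import UTRRecord
from .regression import fit_ols

ModifierSpec = float | tuple[float, float]


@dataclass
class SyntheticSpec:
    """Generative parameters for one synthetic 5'UTR species set.

    ``motif_modifiers`` maps an RNA motif to either a fixed factor or a
    ``(low, high)`` range from which a per-gene factor is drawn uniformly.
    ``planted_beta`` maps covariate names (``"gc"`` or a motif that has a
    *ranged* modifier) to true regression coefficients on the log10-length
    scale; covariates are centered at their theoretical means before
    entering the linear predictor, so ``length_median`` stays the median
    length whatever the coefficients.
    """

    n_genes: int = 1000
    length_median: float = 160.0
    noise_sd: float = 0.30                # sd of eps, log10 units
    gc_alpha: float = 11.0
    gc_beta: float = 8.0
    motif_modifiers: Mapping[str, ModifierSpec] = field(default_factory=dict)
    planted_beta: Mapping[str, float] = field(default_factory=dict)
    transcripts_per_gene: int | tuple[int, int] = 1
    seed: int = 0
    max_resample_passes: int = 10

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise ValueError("n_genes must be >= 1")
        if self.length_median < 3:
            raise ValueError("length_median must be >= 3")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.gc_alpha <= 0 or self.gc_beta <= 0:
            raise ValueError("gc Beta parameters must be positive")
        for motif, mod in self.motif_modifiers.items():
            if set(motif) - set("ACGU"):
                raise ValueError(f"motif {motif!r} is not an RNA string")
            lo, hi = (mod, mod) if np.isscalar(mod) else mod
            if lo < 0 or hi < lo:
                raise ValueError(f"invalid modifier for {motif!r}: {mod}")
        for name in self.planted_beta:
            if name == "gc":
                continue
            mod = self.motif_modifiers.get(name)
            if mod is None or np.isscalar(mod):
                raise ValueError(
                    f"planted coefficient on {name!r} requires a ranged "
                    "modifier (low, high) so the covariate varies"
                )

    def covariate_mean(self, name: str) -> float:
        if name == "gc":
            return self.gc_alpha / (self.gc_alpha + self.gc_beta)
        mod = self.motif_modifiers[name]
        if np.isscalar(mod):
            return float(mod)
        lo, hi = mod
        return (lo + hi) / 2.0


# ---------------------------------------------------------------------------
# base-level sequence generation
# ---------------------------------------------------------------------------

def _draw_codes(u: np.ndarray, cum_rows: np.ndarray) -> np.ndarray:
    """Map uniforms to base codes given per-position cumulative probs."""
    return (u[:, None] > cum_rows).sum(axis=1).astype(np.uint8)


def _redraw_windows(
    flat: np.ndarray,
    pos: np.ndarray,
    k: int,
    cum_flat: np.ndarray,
    rng: np.random.Generator,
    forbid: np.ndarray,
) -> None:
    """Redraw k-windows at ``pos`` in place, rejecting exact re-creation."""
    active = pos
    offsets = np.arange(k)
    for _ in range(20):
        if active.size == 0:
            return
        idx = (active[:, None] + offsets).ravel()
        flat[idx] = _draw_codes(rng.random(idx.size), cum_flat[idx])
        win = flat[active[:, None] + offsets]
        active = active[(win == forbid).all(axis=1)]


def _generate_flat(
    lengths: np.ndarray,
    gc: np.ndarray,
    modifiers: Mapping[str, np.ndarray],
    rng: np.random.Generator,
    max_passes: int = 10,
) -> np.ndarray:
    """Generate many sequences into one flat uint8 code array.

    ``modifiers`` maps motif -> per-sequence factor array.  Suppression
    (s < 1) keeps each neutral occurrence with probability s and redraws the
    rest, iterating over newly created occurrences up to ``max_passes``;
    enrichment (s > 1) plants Poisson((s-1) * L * prod f) extra copies at
    uniform positions.
    """
    lengths = np.asarray(lengths, dtype=np.int64)
    gc = np.asarray(gc, dtype=float)
    n = len(lengths)
    if np.any(lengths < 3):
        raise ValueError("all lengths must be >= 3")
    total = int(lengths.sum())
    starts = np.concatenate(([0], np.cumsum(lengths)[:-1]))
    seg = np.repeat(np.arange(n), lengths)

    probs = np.column_stack([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    cum = np.cumsum(probs, axis=1)
    cum[:, -1] = 1.0
    cum_flat = cum[seg]

    flat = _draw_codes(rng.random(total), cum_flat)
    remaining = lengths[seg] - (np.arange(total) - starts[seg])

    for motif in sorted(modifiers):
        s = np.asarray(modifiers[motif], dtype=float)
        if s.shape != (n,):
            raise ValueError(f"modifier array for {motif!r} has wrong shape")
        if np.all(s == 1.0):
            continue
        m = encode(motif)
        k = len(m)
        q = probs[:, m].prod(axis=1)  # neutral per-window motif probability
        if np.any((s > 1.0) & (q == 0.0)):
            raise ValueError(
                f"impossible composition: cannot enrich {motif!r} in a "
                "sequence lacking a required base"
            )

        keep = np.minimum(s, 1.0)
        if np.any(keep < 1.0):
            top = total - k + 1
            offsets = np.arange(k)
            handled = np.zeros(top, dtype=bool)
            for _ in range(max_passes):
                match = flat[0:top] == m[0]
                for i in range(1, k):
                    match = match & (flat[i : top + i] == m[i])
                match &= remaining[:top] >= k
                pos = np.flatnonzero(match & ~handled)
                if pos.size == 0:
                    break
                redraw = rng.random(pos.size) >= keep[seg[pos]]
                handled[pos] = True
                rpos = pos[redraw]
                if rpos.size == 0:
                    break
                _redraw_windows(flat, rpos, k, cum_flat, rng, m)
                # windows overlapping a redrawn region are up for re-decision
                lo = np.maximum(rpos - (k - 1), 0)
                for a, b in zip(lo, np.minimum(rpos + k, top)):
                    handled[a:b] = False
                handled[rpos] = True  # the redrawn start itself was decided

        extra_rate = np.clip(s - 1.0, 0.0, None) * lengths * q
        if np.any(extra_rate > 0):
            counts = rng.poisson(extra_rate)
            if counts.sum() > 0:
                rep = np.repeat(np.arange(n), counts)
                off = rng.integers(0, lengths[rep] - k + 1)
                ppos = starts[rep] + off
                flat[ppos[:, None] + np.arange(k)] = m
    return flat


def generate_sequence(
    length: int,
    gc: float,
    motif_modifiers: Mapping[str, float] | None = None,
    rng: np.random.Generator | int = 0,
    max_passes: int = 10,
) -> str:
    """Generate a single RNA sequence (see :func:`_generate_flat`)."""
    if length < 3:
        raise ValueError("length must be >= 3")
    if not 0.0 <= gc <= 1.0:
        raise ValueError("gc must be in [0, 1]")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    mods = {
        m: np.array([float(v)]) for m, v in (motif_modifiers or {}).items()
    }
    flat = _generate_flat(
        np.array([length]), np.array([gc]), mods, rng, max_passes
    )
    return decode(flat)


# ---------------------------------------------------------------------------
# dataset generation
# ---------------------------------------------------------------------------

def _draw_gene_level(
    spec: SyntheticSpec, rng: np.random.Generator
) -> tuple[np.ndarray, dict[str, np.ndarray], np.ndarray]:
    gc = rng.beta(spec.gc_alpha, spec.gc_beta, spec.n_genes)
    mods: dict[str, np.ndarray] = {}
    for motif in sorted(spec.motif_modifiers):
        v = spec.motif_modifiers[motif]
        if np.isscalar(v):
            mods[motif] = np.full(spec.n_genes, float(v))
        else:
            lo, hi = v
            mods[motif] = rng.uniform(lo, hi, spec.n_genes)
    tpg = spec.transcripts_per_gene
    if isinstance(tpg, tuple):
        n_t = rng.integers(tpg[0], tpg[1] + 1, spec.n_genes)
    else:
        n_t = np.full(spec.n_genes, int(tpg))
    return gc, mods, n_t


def _linear_predictor(
    spec: SyntheticSpec, gc: np.ndarray, mods: dict[str, np.ndarray]
) -> np.ndarray:
    eta = np.full(spec.n_genes, math.log10(spec.length_median))
    for name, beta in spec.planted_beta.items():
        x = gc if name == "gc" else mods[name]
        eta = eta + beta * (x - spec.covariate_mean(name))
    return eta


def _draw_lengths(
    spec: SyntheticSpec,
    eta_tx: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    y = eta_tx + rng.normal(0.0, spec.noise_sd, len(eta_tx))
    raw = 10.0 ** y
    frac_short = float(np.mean(raw < 2.5))
    if frac_short > 0.01:
        raise ValueError(
            f"{frac_short:.1%} of drawn lengths fall below 3 nt; increase "
            "length_median or decrease noise_sd / planted effect sizes"
        )
    return np.maximum(np.rint(raw).astype(np.int64), 3)


def _truth_frame(
    spec: SyntheticSpec,
    gene_ids: list[str],
    transcript_ids: list[str],
    lengths: np.ndarray,
    gc_tx: np.ndarray,
    mods_tx: dict[str, np.ndarray],
) -> pd.DataFrame:
    truth = pd.DataFrame(
        {
            "gene_id": gene_ids,
            "transcript_id": transcript_ids,
            "length": lengths,
            "log10_length": np.log10(lengths.astype(float)),
            "gc_true": gc_tx,
            **{f"s_{m.lower()}": v for m, v in mods_tx.items()},
        }
    )
    truth.attrs["planted_beta"] = dict(spec.planted_beta)
    truth.attrs["noise_sd"] = spec.noise_sd
    truth.attrs["seed"] = spec.seed
    return truth


def _generate_core(
    spec: SyntheticSpec,
) -> tuple[np.ndarray, np.ndarray, pd.DataFrame]:
    """Shared generation: returns (flat codes, lengths, truth table)."""
    rng = np.random.default_rng(spec.seed)
    gc, mods, n_t = _draw_gene_level(spec, rng)
    eta = _linear_predictor(spec, gc, mods)

    gene_idx = np.repeat(np.arange(spec.n_genes), n_t)
    lengths = _draw_lengths(spec, eta[gene_idx], rng)
    gc_tx = gc[gene_idx]
    mods_tx = {m: v[gene_idx] for m, v in mods.items()}

    flat = _generate_flat(
        lengths, gc_tx, mods_tx, rng, spec.max_resample_passes
    )

    gene_ids = [f"g{i + 1:05d}" for i in gene_idx]
    tx_counter: dict[int, int] = {}
    transcript_ids = []
    for g in gene_idx:
        tx_counter[g] = tx_counter.get(g, 0) + 1
        transcript_ids.append(f"t{tx_counter[g]}")
    truth = _truth_frame(
        spec, gene_ids, transcript_ids, lengths, gc_tx, mods_tx
    )
    return flat, lengths, truth


def generate_dataset(
    spec: SyntheticSpec,
) -> tuple[list[UTRRecord], pd.DataFrame]:
    """Generate records plus the ground-truth covariate table.

    The truth table has one row per transcript (gene_id, transcript_id,
    realized length, generative gc, generative motif factors) and carries
    the planted coefficient vector in ``.attrs["planted_beta"]``.
    """
    flat, lengths, truth = _generate_core(spec)
    starts = np.concatenate(([0], np.cumsum(lengths)[:-1]))
    records = [
        UTRRecord(g, t, decode(flat[s0 : s0 + L]))
        for g, t, s0, L in zip(
            truth["gene_id"], truth["transcript_id"], starts, lengths
        )
    ]
    return records, truth


def generate_feature_table(
    spec: SyntheticSpec,
    windows: str = "L",
    compute_uorf: bool = False,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate and featurize in one pass, without materializing strings.

    Returns (feature table, truth table), row-aligned.  The uORF flag is
    skipped by default because large simulation studies do not use it.
    """
    flat, lengths, truth = _generate_core(spec)
    cols = ft._bulk_features(flat, lengths, windows=windows)
    if compute_uorf:
        cols["uorf_present"] = ft._uorf_present_flat(flat, lengths)
    else:
        cols["uorf_present"] = np.zeros(len(lengths), dtype=np.int64)
    df = pd.DataFrame(
        {
            "gene_id": truth["gene_id"],
            "transcript_id": truth["transcript_id"],
            **{c: cols[c] for c in ft.FEATURE_TABLE_COLUMNS[2:]},
        }
    )
    df.attrs["windows"] = windows
    df.attrs["seed"] = spec.seed
    return df, truth


# ---------------------------------------------------------------------------
# attenuation-corrected coefficient recovery
# ---------------------------------------------------------------------------

def sibling_split(
    features: pd.DataFrame, truth: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame, np.ndarray]:
    """Split a two-transcripts-per-gene dataset for split-sample designs.

    Returns (features of transcript t1, truth of t1, log10 lengths of t2).
    The two transcripts of a gene share the generative covariates but have
    independent noise and independent sequence realizations, so the t2
    response is independent of every feature *measured* on t1 given the
    covariates — the configuration needed for exactly valid calibration
    and null-hypothesis checks.
    """
    mask1 = (truth["transcript_id"] == "t1").to_numpy()
    mask2 = (truth["transcript_id"] == "t2").to_numpy()
    if mask1.sum() != mask2.sum() or mask1.sum() + mask2.sum() != len(truth):
        raise ValueError("sibling_split requires exactly 2 transcripts/gene")
    f1 = features.loc[mask1].reset_index(drop=True)
    t1 = truth.loc[mask1].reset_index(drop=True)
    y2 = features.loc[mask2, RESPONSE].to_numpy(dtype=float)
    return f1, t1, y2


def recovery_analysis(
    feature_table: pd.DataFrame,
    truth: pd.DataFrame,
    mapping: Mapping[str, str],
    response: str = RESPONSE,
    response_values: np.ndarray | None = None,
) -> pd.DataFrame:
    """Naive fit on measured features plus regression-calibration correction.

    ``mapping`` pairs each measured feature column with the ground-truth
    covariate column it estimates (e.g. ``{"gc": "gc_true",
    "oe_uga": "s_uga"}``).  Because features are measured from finite
    sequences they are noisy, cross-contaminated surrogates of the
    generative covariates, so the naive coefficients are attenuated and
    mixed.  The correction is multivariate regression calibration: each
    true covariate is regressed on *all* measured features, the fitted
    values (best linear predictions of the truth) replace the measured
    features, and the response is refit on them.  The per-covariate
    ``reliability`` column reports the diagonal of the calibration matrix.

    ``response_values`` optionally replaces the response column — pass the
    sibling-transcript lengths from :func:`sibling_split` to obtain a
    response whose noise is independent of the feature measurement error
    (measurement error of a UTR's own features shares the UTR's length,
    which biases within-sequence calibration).
    """
    meas_cols = list(mapping)
    true_cols = [mapping[c] for c in meas_cols]
    y = (
        np.asarray(response_values, dtype=float)
        if response_values is not None
        else feature_table[response].to_numpy(dtype=float)
    )
    work = feature_table[meas_cols].copy()
    work["_y"] = y
    naive = fit_ols(work, meas_cols, "_y")

    A = np.column_stack(
        [np.ones(len(work)), work[meas_cols].to_numpy(dtype=float)]
    )
    G, *_ = np.linalg.lstsq(A, truth[true_cols].to_numpy(dtype=float), rcond=None)
    calibrated = pd.DataFrame(A @ G, columns=true_cols)
    calibrated["_y"] = y
    corrected = fit_ols(calibrated, true_cols, "_y")

    return pd.DataFrame(
        {
            "truth": true_cols,
            "beta_naive": naive.coefficients[1:],
            "se_naive": naive.standard_errors[1:],
            "beta_corrected": corrected.coefficients[1:],
            "se_corrected": corrected.standard_errors[1:],
            "reliability": np.diag(G[1:, :]),
        },
        index=pd.Index(meas_cols, name="measured"),
    )


# ---------------------------------------------------------------------------
# hand-computed toy fixture
# ---------------------------------------------------------------------------

# Five featurizable sequences with every feature derivable by hand, plus a
# too-short record (dropped at featurization) and a record with an ambiguity
# code (dropped at reading).
TOY_SEQUENCES: tuple[tuple[str, str, str], ...] = (
    ("g01", "t1", "AUGAUG"),
    ("g02", "t1", "AUGAAAUAA"),
    ("g03", "t1", "AUGUGAUAAUAGCGUU"),
    ("g04", "t1", "ACGUACGUACGU"),
    ("g05", "t1", "AUGAUAAUGACC"),
    ("g06", "t1", "AU"),
    ("g07", "t1", "ACGNACG"),
)


def _toy_row(
    gene: str,
    tx: str,
    L: int,
    counts: dict[str, int],
    obs: dict[str, int],
    uorf: int,
) -> dict:
    """Expected feature row from hand-tallied base and motif counts."""
    f = {b: counts.get(b, 0) / L for b in "ACGU"}

    def exp_count(motif: str) -> float:
        e = float(L)
        for b in motif:
            e = e * f[b]
        return e

    def oe(motif: str) -> float:
        e = exp_count(motif)
        return obs.get(motif, 0) / e if e > 0 else 0.0

    tri_oe = [oe(m) for m in ("AUG", "UGA", "UAA", "UAG")]
    return {
        "gene_id": gene,
        "transcript_id": tx,
        "length": L,
        "log10_length": float(np.log10(float(L))),
        "gc": f["C"] + f["G"],
        "oe_aug": tri_oe[0],
        "oe_uga": tri_oe[1],
        "oe_uaa": tri_oe[2],
        "oe_uag": tri_oe[3],
        "oe_cg": oe("CG"),
        "oe_ug": oe("UG"),
        "oe_uu": oe("UU"),
        "oe_ua": oe("UA"),
        "uorf_present": uorf,
        "n_zero_tri_oe": sum(1 for v in tri_oe if v == 0.0),
    }


def toy_expected_features() -> pd.DataFrame:
    """The hand-computed feature table for the five valid toy sequences.

    Base counts, overlapping motif counts and uORF calls below were tallied
    by hand from the sequences in :data:`TOY_SEQUENCES`; OE ratios follow
    from obs / (L * prod f).
    """
    rows = [
        # AUGAUG: windows AUG,UGA,GAU,AUG -> AUG x2, UGA x1; pairs
        # AU,UG,GA,AU,UG -> UG x2; no C anywhere; too short for a uORF.
        _toy_row(
            "g01", "t1", 6,
            {"A": 2, "G": 2, "U": 2},
            {"AUG": 2, "UGA": 1, "UG": 2},
            uorf=0,
        ),
        # AUGAAAUAA: codons AUG|AAA|UAA -> a uORF with one codon inside.
        _toy_row(
            "g02", "t1", 9,
            {"A": 6, "U": 2, "G": 1},
            {"AUG": 1, "UGA": 1, "UAA": 1, "UG": 1, "UA": 1},
            uorf=1,
        ),
        # AUGUGAUAAUAGCGUU: all four trinucleotides occur once; the AUG's
        # first in-frame stop (UGA at offset 3) is adjacent -> no uORF.
        _toy_row(
            "g03", "t1", 16,
            {"A": 5, "U": 6, "G": 4, "C": 1},
            {
                "AUG": 1, "UGA": 1, "UAA": 1, "UAG": 1,
                "CG": 1, "UG": 2, "UU": 1, "UA": 2,
            },
            uorf=0,
        ),
        # ACGUACGU x1.5: uniform composition, no start/stop trinucleotide.
        _toy_row(
            "g04", "t1", 12,
            {"A": 3, "C": 3, "G": 3, "U": 3},
            {"CG": 3, "UA": 2},
            uorf=0,
        ),
        # AUGAUAAUGACC: two AUGs, neither followed by an in-frame stop.
        _toy_row(
            "g05", "t1", 12,
            {"A": 5, "U": 3, "G": 2, "C": 2},
            {"AUG": 2, "UGA": 2, "UAA": 1, "UG": 2, "UA": 1},
            uorf=0,
        ),
    ]
    return pd.DataFrame(rows, columns=ft.FEATURE_TABLE_COLUMNS)


def make_toy_fixture(outdir: str | Path) -> tuple[Path, Path]:
    """Write the toy FASTA and its expected feature TSV; return the paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    fasta = outdir / "toy_utrs.fasta"
    with open(fasta, "w") as out:
        for gene, tx, seq in TOY_SEQUENCES:
            out.write(f">{gene}|{tx}\n{seq}\n")
    tsv = outdir / "toy_expected_features.tsv"
    toy_expected_features().to_csv(tsv, sep="\t", index=False)
    return fasta, tsv
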