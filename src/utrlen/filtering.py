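"""Dataset cleaning for the 5'UTR length regression.

Short 5'UTRs frequently show zero OE ratios for one or more of the four
trinucleotides simply because the expected counts are below one — a zero
there is uninformative about selection.  The default cleaning rule drops
every UTR with more than one zero among the four trinucleotide OE ratios
(dinucleotide OEs are never inspected: their expected counts are an order
of magnitude larger and zeros are rare).  An alternative hard length
threshold (e.g. drop L < 30) is provided for comparison; it skews the
log-length distribution away from normality, which the quantile/normality
report below makes visible.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .features import FeatureVector

TRI_OE_COLUMNS = ["oe_aug", "oe_uga", "oe_uaa", "oe_uag"]


def count_zero_trinucleotide_oe(fv: FeatureVector) -> int:
    """Number of the four trinucleotide OE ratios equal to 0 (range 0-4)."""
    return sum(
        1 for v in (fv.oe_aug, fv.oe_uga, fv.oe_uaa, fv.oe_uag) if v == 0.0
    )


def zero_tri_oe_counts(table: pd.DataFrame) -> pd.Series:
    """Vectorized zero count over the four trinucleotide OE columns."""
    return (table[TRI_OE_COLUMNS] == 0.0).sum(axis=1)


def apply_zero_oe_filter(table: pd.DataFrame, max_zeros: int = 1) -> pd.DataFrame:
    """Retain rows with at most ``max_zeros`` zero trinucleotide OE ratios.

    Raises ``ValueError`` if nothing survives.  Retained/removed counts are
    recorded in ``.attrs`` of the returned frame.
    """
    if table.empty:
        raise ValueError("empty dataset after filtering")
    mask = zero_tri_oe_counts(table) <= max_zeros
    out = table.loc[mask].copy()
    if out.empty:
        raise ValueError("empty dataset after filtering")
    out.attrs.update(table.attrs)
    out.attrs["filter"] = {
        "rule": "zero_oe",
        "max_zeros": max_zeros,
        "n_in": int(len(table)),
        "n_retained": int(len(out)),
        "n_removed": int(len(table) - len(out)),
    }
    return out


def apply_length_threshold_filter(
    table: pd.DataFrame, min_length: int = 30
) -> pd.DataFrame:
    """Alternative rule: drop UTRs shorter than ``min_length`` nucleotides."""
    if table.empty:
        raise ValueError("empty dataset after filtering")
    mask = table["length"] >= min_length
    out = table.loc[mask].copy()
    if out.empty:
        raise ValueError("empty dataset after filtering")
    out.attrs.update(table.attrs)
    out.attrs["filter"] = {
        "rule": "length_threshold",
        "min_length": min_length,
        "n_in": int(len(table)),
        "n_retained": int(len(out)),
        "n_removed": int(len(table) - len(out)),
    }
    return out


def filter_report(table: pd.DataFrame) -> pd.DataFrame:
    """One-row TSV-ready summary of the filter recorded in ``.attrs``."""
    info = table.attrs.get("filter", {})
    return pd.DataFrame([info])


def length_distribution_report(
    table: pd.DataFrame,
    quantiles: Sequence[float] = (0.05, 0.25, 0.5, 0.75, 0.95),
) -> dict:
    """Empirical length quantiles plus a log-scale normality statistic.

    The normality statistic is the Shapiro–Francia-type correlation between
    the ordered log10 lengths and the corresponding normal order-statistic
    quantiles (1.0 = perfectly normal); it lets filtering strategies be
    compared on how close to normal they leave the log-length distribution.
    """
    if table.empty:
        raise ValueError("empty table")
    lengths = table["length"].to_numpy(float)
    log10 = table["log10_length"].to_numpy(float)
    q = list(quantiles)
    report = {
        "n": int(len(table)),
        "quantiles": q,
        "length": np.quantile(lengths, q).tolist(),
        "log10_length": np.quantile(log10, q).tolist(),
    }
    if len(log10) >= 3 and np.ptp(log10) > 0:
        (_, _), (_, _, r) = stats.probplot(log10, dist="norm")
        report["normality_r_log10"] = float(r)
    else:
        report["normality_r_log10"] = float("nan")
    return report
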