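"""High-confidence m5C candidate calling from bisulfite pileups.

The per-position test is a one-sided upper-tail binomial test of the
non-converted count against the spike-in derived conversion error; q-values
are Benjamini-Hochberg adjusted over all coverage-eligible ("tested")
positions of a replicate.  A candidate passes with coverage >= 10,
non-conversion rate > 0.2 and q < 0.01 (all configurable), and a consensus
site must pass in all replicates of a sample type.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

DEFAULT_MIN_COV = 10
DEFAULT_MIN_RATE = 0.2
DEFAULT_MAX_FDR = 0.01
DEFAULT_EPS_MIN = 1e-4

SITE_KEY = ["chrom", "pos", "strand"]


class CallingError(ValueError):
    pass


@dataclass(frozen=True)
class SpikeInEstimate:
    """Pooled conversion-error estimate from unmethylated spike-in pileups."""

    conversion_rate: float
    error: float  # epsilon, floored at eps_min
    n_positions: int
    total_evidence: int


def estimate_conversion_error(
    spike_pileups: pd.DataFrame, eps_min: float = DEFAULT_EPS_MIN
) -> SpikeInEstimate:
    """epsilon = sum(k) / sum(n), pooled over all spike-in C positions."""
    total_n = int(spike_pileups["n"].sum())
    total_k = int(spike_pileups["k"].sum())
    if total_n == 0:
        raise CallingError("no spike-in evidence (sum of coverage is zero)")
    raw = total_k / total_n
    eps = max(raw, eps_min)
    return SpikeInEstimate(
        conversion_rate=1.0 - raw,
        error=eps,
        n_positions=len(spike_pileups),
        total_evidence=total_n,
    )


def binomial_pvalue(n, k, eps):
    """Exact upper-tail P(X >= k | X ~ Binomial(n, eps)); vectorized.

    k = 0 gives p = 1 by convention (sf(-1) = 1).
    """
    n = np.asarray(n)
    k = np.asarray(k)
    if np.any(k < 0) or np.any(k > n):
        raise ValueError("require 0 <= k <= n")
    p = stats.binom.sf(k - 1, n, eps)
    if p.ndim == 0:
        return float(p)
    return p


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, order-preserving."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return q


def call_candidates(
    pileups: pd.DataFrame,
    eps: float,
    min_cov: int = DEFAULT_MIN_COV,
    min_rate: float = DEFAULT_MIN_RATE,
    max_fdr: float = DEFAULT_MAX_FDR,
) -> pd.DataFrame:
    """Per-position methylation calls for one replicate.

    Returns one row per pileup position with columns rate/p_value/q_value and
    the pass flags; BH runs over the coverage-eligible positions only
    (q_value is NaN for untested positions).
    """
    df = pileups.copy().reset_index(drop=True)
    n = df["n"].to_numpy()
    k = df["k"].to_numpy()
    with np.errstate(invalid="ignore", divide="ignore"):
        rate = np.where(n > 0, k / np.maximum(n, 1), 0.0)
    df["rate"] = rate
    df["p_value"] = binomial_pvalue(n, k, eps)
    tested = n >= min_cov
    q = np.full(len(df), np.nan)
    q[tested] = bh_adjust(df.loc[tested, "p_value"].to_numpy())
    df["q_value"] = q
    df["pass_coverage"] = tested
    df["pass_rate"] = rate > min_rate
    df["pass_fdr"] = tested & (q < max_fdr)
    df["passed"] = df["pass_coverage"] & df["pass_rate"] & df["pass_fdr"]
    return df


def replicate_consensus(calls_per_replicate: list[pd.DataFrame],
                        n_reps: int = 3) -> pd.DataFrame:
    """Sites passing in every replicate, with per-replicate and mean stats.

    A site absent (untested or missing) from any replicate is dropped:
    absence is "not present".
    """
    if len(calls_per_replicate) != n_reps:
        raise CallingError(
            f"expected {n_reps} replicates, got {len(calls_per_replicate)}"
        )
    passed = []
    for i, calls in enumerate(calls_per_replicate, 1):
        sub = calls.loc[calls["passed"], SITE_KEY + ["n", "k", "rate"]].copy()
        sub = sub.rename(columns={c: f"{c}_rep{i}" for c in ("n", "k", "rate")})
        passed.append(sub)
    merged = passed[0]
    for sub in passed[1:]:
        merged = merged.merge(sub, on=SITE_KEY, how="inner")
    n_cols = [f"n_rep{i}" for i in range(1, n_reps + 1)]
    r_cols = [f"rate_rep{i}" for i in range(1, n_reps + 1)]
    merged["mean_coverage"] = merged[n_cols].mean(axis=1)
    merged["mean_rate"] = merged[r_cols].mean(axis=1)
    merged["consensus"] = True
    return merged.sort_values(SITE_KEY, ignore_index=True)


# --------------------------------------------------------------------------
# Read-level aggregation (m-bias trimming, base-quality filtering)
# --------------------------------------------------------------------------

def pileup_from_reads(
    reads: pd.DataFrame,
    references: dict[str, str],
    trim_fwd: int = 10,
    trim_rev: int = 7,
    q_min: int = 35,
) -> pd.DataFrame:
    """Aggregate positioned reads into a per-cytosine pileup.

    Bases within the trimmed 5' window (``trim_fwd`` for forward reads,
    ``trim_rev`` for reverse reads, where the reverse 5' end is the
    rightmost base) or below ``q_min`` contribute nothing.  C/T evidence at
    reference C positions is counted as non-converted/converted.

    ``references`` maps transcript_id -> transcript-strand sequence; the
    output pileup uses transcript_id as chrom and transcript coordinates.
    """
    counts: dict[tuple[str, int], list[int]] = {}
    for row in reads.itertuples():
        ref = references.get(row.transcript_id)
        if ref is None:
            raise CallingError(f"unknown transcript {row.transcript_id!r}")
        start = int(row.start)
        seq = row.seq
        qual = row.qual
        if start < 0 or start + len(seq) > len(ref):
            raise CallingError(
                f"read at {row.transcript_id}:{start} extends beyond transcript"
            )
        rl = len(seq)
        for off, base in enumerate(seq):
            from_5p = off if row.orientation == "fwd" else rl - 1 - off
            trim = trim_fwd if row.orientation == "fwd" else trim_rev
            if from_5p < trim:
                continue
            if ord(qual[off]) - 33 < q_min:
                continue
            if ref[start + off] != "C":
                continue
            if base not in ("C", "T"):
                continue
            nk = counts.setdefault((row.transcript_id, start + off), [0, 0])
            nk[0] += 1
            if base == "C":
                nk[1] += 1
    rows = [
        (tid, pos, "+", nk[0], nk[1])
        for (tid, pos), nk in sorted(counts.items())
    ]
    return pd.DataFrame(rows, columns=["chrom", "pos", "strand", "n", "k"])
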