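"""Permutation tests of m5C overlap with interval tracks, RBP site
preparation, m6A motif scanning and codon-proximal distributions.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core_io import FeatureTrack, GenomicSite, TrackInterval, TranscriptModel
from .structure_filter import to_rna

MIRSVR_MAX_SCORE = -0.1
RBP_MERGE_GAP = 15
RBP_MAX_LENGTH = 200


class OverlapError(ValueError):
    pass


# --------------------------------------------------------------------------
# Track preparation
# --------------------------------------------------------------------------

def filter_mirna_track(track: FeatureTrack,
                       max_score: float = MIRSVR_MAX_SCORE) -> FeatureTrack:
    """Keep only target sites with mirSVR score below the cutoff."""
    ivs = [iv for iv in track.intervals if iv.score is not None and iv.score < max_score]
    return FeatureTrack(track.name, ivs, dict(track.metadata))


def prepare_rbp_sites(
    track: FeatureTrack,
    merge_gap: int = RBP_MERGE_GAP,
    max_length: int = RBP_MAX_LENGTH,
) -> FeatureTrack:
    """Merge sites closer than ``merge_gap`` nt, then drop merged intervals
    that are >= ``max_length`` nt or claimed by more than one factor
    (interval labels name the factor)."""
    by_group: dict[tuple[str, str], list[TrackInterval]] = {}
    for iv in track.intervals:
        by_group.setdefault((iv.chrom, iv.strand), []).append(iv)

    merged: list[TrackInterval] = []
    for (chrom, strand), ivs in sorted(by_group.items()):
        ivs = sorted(ivs, key=lambda t: (t.start, t.end))
        cur_start, cur_end = ivs[0].start, ivs[0].end
        labels = {ivs[0].label}
        for iv in ivs[1:]:
            if iv.start - cur_end < merge_gap:
                cur_end = max(cur_end, iv.end)
                labels.add(iv.label)
            else:
                merged.append(_merged_interval(chrom, strand, cur_start, cur_end, labels))
                cur_start, cur_end, labels = iv.start, iv.end, {iv.label}
        merged.append(_merged_interval(chrom, strand, cur_start, cur_end, labels))

    kept = [
        iv for iv in merged
        if iv.end - iv.start < max_length and "," not in iv.label
    ]
    return FeatureTrack(track.name, kept, dict(track.metadata))


def _merged_interval(chrom: str, strand: str, start: int, end: int,
                     labels: set[str]) -> TrackInterval:
    return TrackInterval(chrom, start, end, strand, ",".join(sorted(labels)))


# --------------------------------------------------------------------------
# Permutation test
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class PermutationResult:
    track: str
    observed_overlap: int
    null_mean: float
    null_sd: float
    z_score: float | None  # None when the null is degenerate (sd = 0)
    p_low: float
    p_high: float
    iterations: int
    seed: int


class _TrackIndex:
    """Sorted-interval membership lookup per (chrom, strand)."""

    def __init__(self, track: FeatureTrack):
        ivs: dict[tuple[str, str], list[tuple[int, int]]] = {}
        for iv in track.intervals:
            ivs.setdefault((iv.chrom, iv.strand), []).append((iv.start, iv.end))
        self._index: dict[tuple[str, str], tuple[np.ndarray, np.ndarray]] = {}
        for key, spans in ivs.items():
            spans.sort()
            starts = np.array([s for s, _ in spans])
            ends = np.maximum.accumulate(np.array([e for _, e in spans]))
            self._index[key] = (starts, ends)

    def contains(self, site: GenomicSite) -> bool:
        for strand in (site.strand, "."):
            idx = self._index.get((site.chrom, strand))
            if idx is None:
                continue
            starts, ends = idx
            i = int(np.searchsorted(starts, site.pos, side="right")) - 1
            if i >= 0 and site.pos < ends[i]:
                return True
        return False


def overlap_permutation_test(
    m5c_sites: Sequence[GenomicSite],
    track: FeatureTrack,
    background_cs: Sequence[GenomicSite],
    iterations: int = 10_000,
    seed: int = 0,
) -> PermutationResult:
    """Permutation test of the observed m5C/track overlap count.

    Each iteration samples |m5C set| cytosines without replacement from the
    background and counts how many fall inside the track.  Empirical p-values
    carry the add-one correction p = (#{null >=/<= obs} + 1) / (N + 1).
    """
    n_bg = len(background_cs)
    m = len(m5c_sites)
    if m > n_bg:
        raise OverlapError(f"background ({n_bg}) smaller than sample size ({m})")
    index = _TrackIndex(track)
    observed = sum(index.contains(s) for s in m5c_sites)
    member = np.array([index.contains(s) for s in background_cs], dtype=bool)

    rng = np.random.default_rng(seed)
    null = np.empty(iterations, dtype=np.int64)
    for it in range(iterations):
        idx = rng.choice(n_bg, size=m, replace=False)
        null[it] = int(member[idx].sum())

    null_mean = float(null.mean())
    null_sd = float(null.std(ddof=1)) if iterations > 1 else 0.0
    z = None if null_sd == 0 else (observed - null_mean) / null_sd
    p_high = (int((null >= observed).sum()) + 1) / (iterations + 1)
    p_low = (int((null <= observed).sum()) + 1) / (iterations + 1)
    return PermutationResult(
        track=track.name,
        observed_overlap=int(observed),
        null_mean=null_mean,
        null_sd=null_sd,
        z_score=z,
        p_low=p_low,
        p_high=p_high,
        iterations=iterations,
        seed=seed,
    )


def reported_p(result: PermutationResult) -> float:
    """The single p-value matching the Z sign (depletion -> lower tail)."""
    if result.z_score is not None and result.z_score < 0:
        return result.p_low
    return result.p_high


# --------------------------------------------------------------------------
# m6A motif scan
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class MotifHit:
    transcript_id: str
    position: int  # 0-based position of the methylatable A
    matched: str


_M6A_RE = re.compile(r"(?=([ACU]GGAC[ACGU][ACGU]))")


def scan_m6a_motif(sequences: Mapping[str, str]) -> list[MotifHit]:
    """All (overlapping) HGGACNN matches; hit position is the A (offset +3)."""
    hits: list[MotifHit] = []
    for tid in sorted(sequences):
        rna = to_rna(sequences[tid])
        for match in _M6A_RE.finditer(rna):
            seven = match.group(1)
            hits.append(MotifHit(tid, match.start() + 3, seven))
    return hits


# --------------------------------------------------------------------------
# Codon-proximal distribution
# --------------------------------------------------------------------------

WINDOW = 500
BIN = 25
N_BINS = 2 * WINDOW // BIN  # 40


def _anchor_tpos(model: TranscriptModel, anchor: str) -> int | None:
    segs = model.segments()
    if segs is None:
        return None
    if anchor == "AUG":
        return segs["cds"][0]
    if anchor == "STOP":
        return segs["cds"][1] - 3  # first base of the final codon
    raise ValueError(f"anchor must be AUG or STOP, got {anchor!r}")


def codon_proximal_distribution(
    m5c_positions: Sequence[tuple[str, int]],
    m6a_positions: Sequence[tuple[str, int]],
    models: Sequence[TranscriptModel],
    anchor: str,
) -> tuple[pd.DataFrame, list[str]]:
    """25-nt binned percentages of m5C/m6A sites within +/- 500 nt of the
    anchor codon.

    Sites outside the window contribute to the denominator only; sites on
    transcripts lacking the anchor are skipped and logged.  Returns
    (DataFrame with bin_start/percent_m5C/percent_m6A, skip log).
    """
    by_id = {m.transcript_id: m for m in models}
    log: list[str] = []

    def binned(positions: Sequence[tuple[str, int]]) -> tuple[np.ndarray, int]:
        counts = np.zeros(N_BINS, dtype=int)
        denom = 0
        for tid, tpos in positions:
            model = by_id.get(tid)
            a = _anchor_tpos(model, anchor) if model is not None else None
            if a is None:
                log.append(f"{tid}:{tpos} skipped: no {anchor} anchor")
                continue
            denom += 1
            off = tpos - a
            if -WINDOW <= off < WINDOW:
                counts[(off + WINDOW) // BIN] += 1
        return counts, denom

    c5, d5 = binned(m5c_positions)
    c6, d6 = binned(m6a_positions)
    df = pd.DataFrame(
        {
            "bin_start": np.arange(-WINDOW, WINDOW, BIN),
            "percent_m5C": 100.0 * c5 / d5 if d5 else np.zeros(N_BINS),
            "percent_m6A": 100.0 * c6 / d6 if d6 else np.zeros(N_BINS),
        }
    )
    return df, log
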