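"""Transcript-feature assignment, meta-gene profiles and segment/start-codon
enrichment statistics for m5C sites.

The enrichment background is the set of all cytosine positions of the
transcripts that carry at least one m5C (the caller selects the transcript
set); the AUG +/- 25 nt window is tested within the same background.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .core_io import GenomicSite, TranscriptModel

FEATURES = ("utr5", "cds", "utr3", "intron", "non_annotated")
AUG_HALF_WINDOW = 25


class PositionalError(ValueError):
    pass


@dataclass(frozen=True)
class SegmentAssignment:
    site: GenomicSite
    feature: str
    transcript_id: str | None

    def __post_init__(self) -> None:
        if self.feature not in FEATURES:
            raise ValueError(f"unknown feature {self.feature!r}")


def _segment_of(model: TranscriptModel, tpos: int) -> str:
    segs = model.segments()
    assert segs is not None
    for name, (a, b) in segs.items():
        if a <= tpos < b:
            return name
    raise AssertionError("transcript position outside segment partition")


def assign_segment(
    site: GenomicSite, models: Sequence[TranscriptModel]
) -> SegmentAssignment:
    """Assign one feature to a site.

    Precedence: exonic feature of a coding transcript (transcript chosen by
    longest CDS, ties broken by transcript_id) > intron > non_annotated.
    Exonic hits on non-coding transcripts carry no segment and fall back to
    non_annotated.
    """
    exonic: list[tuple[int, str, TranscriptModel, int]] = []
    intronic = False
    for model in models:
        if model.chrom != site.chrom or model.strand != site.strand:
            continue
        tpos = model.genomic_to_transcript(site.pos)
        if tpos is not None:
            if model.is_coding:
                exonic.append((model.cds_length, model.transcript_id, model, tpos))
        else:
            span = (model.exons[0][0], model.exons[-1][1])
            if span[0] <= site.pos < span[1]:
                intronic = True
    if exonic:
        exonic.sort(key=lambda t: (-t[0], t[1]))
        _, tid, model, tpos = exonic[0]
        return SegmentAssignment(site, _segment_of(model, tpos), tid)
    if intronic:
        return SegmentAssignment(site, "intron", None)
    return SegmentAssignment(site, "non_annotated", None)


# --------------------------------------------------------------------------
# Meta-gene profile
# --------------------------------------------------------------------------

@dataclass
class MetaGeneProfile:
    percent: np.ndarray            # 100 bins, sums to 100
    counts: np.ndarray
    boundaries: tuple[float, float]  # utr5|cds and cds|utr3 in bin units
    average_lengths: dict[str, float]
    n_sites: int


def average_segment_lengths(models: Sequence[TranscriptModel]) -> dict[str, float]:
    lens = {"utr5": [], "cds": [], "utr3": []}
    for m in models:
        segs = m.segments()
        if segs is None:
            continue
        for name, (a, b) in segs.items():
            lens[name].append(b - a)
    if not lens["cds"]:
        raise PositionalError("no coding transcripts for meta-gene scaling")
    return {name: float(np.mean(v)) for name, v in lens.items()}


def metagene_profile(
    assignments: Sequence[SegmentAssignment],
    models: Sequence[TranscriptModel],
) -> MetaGeneProfile:
    """1%-bin profile over a normalized meta-transcript whose segments are
    rescaled to their average lengths."""
    by_id = {m.transcript_id: m for m in models}
    avg = average_segment_lengths(models)
    total = sum(avg.values())
    offsets = {
        "utr5": 0.0,
        "cds": avg["utr5"],
        "utr3": avg["utr5"] + avg["cds"],
    }
    counts = np.zeros(100, dtype=int)
    n = 0
    for asn in assignments:
        if asn.feature not in ("utr5", "cds", "utr3"):
            raise PositionalError(
                f"meta-gene profile needs mRNA-segment sites, got {asn.feature}"
            )
        model = by_id[asn.transcript_id]
        segs = model.segments()
        a, b = segs[asn.feature]
        if b - a == 0:
            raise PositionalError(
                f"{model.transcript_id} lacks segment {asn.feature}"
            )
        tpos = model.genomic_to_transcript(asn.site.pos)
        if tpos is None or not a <= tpos < b:
            raise PositionalError("site does not fall in its assigned segment")
        rel = (tpos - a) / (b - a)
        coord = offsets[asn.feature] + rel * avg[asn.feature]
        b_idx = min(int(np.floor(100.0 * coord / total)), 99)
        counts[b_idx] += 1
        n += 1
    percent = 100.0 * counts / n if n else counts.astype(float)
    boundaries = (100.0 * avg["utr5"] / total,
                  100.0 * (avg["utr5"] + avg["cds"]) / total)
    return MetaGeneProfile(percent, counts, boundaries, avg, n)


# --------------------------------------------------------------------------
# Random-C control
# --------------------------------------------------------------------------

def all_transcript_cs(
    models: Sequence[TranscriptModel], sequences: Mapping[str, str]
) -> list[GenomicSite]:
    """Every exonic transcript-strand C of the given transcripts, one entry
    per unique genomic site (first owning transcript by sorted id)."""
    seen: set[tuple[str, int, str]] = set()
    out: list[GenomicSite] = []
    for model in sorted(models, key=lambda m: m.transcript_id):
        seq = model.spliced_sequence(sequences)
        for tpos, base in enumerate(seq):
            if base != "C":
                continue
            gpos = model.transcript_to_genomic(tpos)
            key = (model.chrom, gpos, model.strand)
            if key in seen:
                continue
            seen.add(key)
            out.append(GenomicSite(model.chrom, gpos, model.strand,
                                   transcript_id=model.transcript_id,
                                   transcript_pos=tpos))
    return out


def sample_random_cs(
    models: Sequence[TranscriptModel],
    sequences: Mapping[str, str],
    n: int,
    rng_seed: int,
) -> list[GenomicSite]:
    """Uniform sample (without replacement) of n cytosines from the same
    transcript set; deterministic under rng_seed."""
    universe = all_transcript_cs(models, sequences)
    if n > len(universe):
        raise PositionalError(
            f"requested {n} random Cs but only {len(universe)} available"
        )
    rng = np.random.default_rng(rng_seed)
    idx = rng.choice(len(universe), size=n, replace=False)
    return [universe[i] for i in sorted(idx)]


# --------------------------------------------------------------------------
# Enrichment (two-sided Fisher)
# --------------------------------------------------------------------------

REGIONS = ("utr5", "cds", "utr3", "aug25")


@dataclass(frozen=True)
class EnrichmentResult:
    region: str
    table: tuple[int, int, int, int]  # (a, b, c, d)
    odds_ratio: float
    ci95: tuple[float, float]
    p_value: float
    n_m5c: int


def _in_region(model: TranscriptModel, tpos: int, region: str) -> bool:
    segs = model.segments()
    if region == "aug25":
        aug = segs["cds"][0]
        return abs(tpos - aug) <= AUG_HALF_WINDOW
    a, b = segs[region]
    return a <= tpos < b


def odds_ratio_ci(a: int, b: int, c: int, d: int) -> tuple[float, tuple[float, float]]:
    """Sample odds ratio with Haldane 0.5 correction iff any cell is zero;
    Woolf 95% CI on the (corrected) cells."""
    cells = [a, b, c, d]
    if any(x == 0 for x in cells):
        cells = [x + 0.5 for x in cells]
    ah, bh, ch, dh = cells
    orr = (ah * dh) / (bh * ch)
    se = np.sqrt(1 / ah + 1 / bh + 1 / ch + 1 / dh)
    ci = (float(np.exp(np.log(orr) - 1.96 * se)),
          float(np.exp(np.log(orr) + 1.96 * se)))
    return float(orr), ci


def segment_enrichment(
    m5c_sites: Sequence[GenomicSite],
    models: Sequence[TranscriptModel],
    sequences: Mapping[str, str],
    region: str,
) -> EnrichmentResult:
    """2x2 Fisher test of m5C membership in a region vs the cytosine
    background of the same transcripts."""
    if region not in REGIONS:
        raise ValueError(f"region must be one of {REGIONS}")
    coding = [m for m in models if m.is_coding]
    background = all_transcript_cs(coding, sequences)
    if not background:
        raise PositionalError("empty cytosine background")
    by_id = {m.transcript_id: m for m in coding}
    m5c_keys = {s.key() for s in m5c_sites}

    a = b = c = d = 0
    for site in background:
        model = by_id[site.transcript_id]
        inside = _in_region(model, site.transcript_pos, region)
        is_m5c = site.key() in m5c_keys
        if is_m5c and inside:
            a += 1
        elif is_m5c:
            b += 1
        elif inside:
            c += 1
        else:
            d += 1
    _, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    orr, ci = odds_ratio_ci(a, b, c, d)
    return EnrichmentResult(region, (a, b, c, d), orr, ci, float(p), a + b)


def enrichment_table(
    m5c_sites: Sequence[GenomicSite],
    models: Sequence[TranscriptModel],
    sequences: Mapping[str, str],
) -> list[EnrichmentResult]:
    return [segment_enrichment(m5c_sites, models, sequences, r) for r in REGIONS]
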