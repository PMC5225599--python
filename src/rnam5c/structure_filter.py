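"""Secondary-structure filtering of candidate m5C sites.

Candidates predicted to be base-paired in the folded structure of their
containing transcript (or a local genomic window for intronic /
non-annotated sites) are discarded; a candidate paired to any partner
counts as paired.

The folding backend is pluggable: the ``mea`` engine delegates to the
thermodynamic MEA predictor of the ViennaRNA python bindings (temperature
and gamma are honored) when those are importable; the always-available
``maxpair`` fallback computes a maximum base-pairing (Nussinov-style)
structure with minimum loop 3 and the same pair-distance cap, and ignores
temperature/gamma.  The engine used is recorded in every annotation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .core_io import GenomicSite, TranscriptModel


class StructureError(ValueError):
    pass


@dataclass(frozen=True)
class FoldConfig:
    temperature: float = 70.0
    gamma: float = 0.1
    max_pair_distance: int = 150
    intron_window: int = 300
    min_loop: int = 3

    def __post_init__(self) -> None:
        if self.gamma <= 0:
            raise ValueError("gamma must be > 0")
        if self.max_pair_distance < 4:
            raise ValueError("max_pair_distance must be >= 4")


@dataclass(frozen=True)
class StructureAnnotation:
    site: GenomicSite
    paired: bool
    dot_bracket: str
    offset: int  # site position within dot_bracket
    engine: str


_RNA_CODE = {"A": 0, "C": 1, "G": 2, "U": 3}
# Watson-Crick + GU wobble
_ALLOWED = np.zeros((4, 4), dtype=bool)
for a, b in (("A", "U"), ("C", "G"), ("G", "U")):
    _ALLOWED[_RNA_CODE[a], _RNA_CODE[b]] = True
    _ALLOWED[_RNA_CODE[b], _RNA_CODE[a]] = True


def to_rna(seq: str) -> str:
    seq = seq.upper().replace("T", "U")
    if any(b not in "ACGU" for b in seq):
        bad = sorted({b for b in seq if b not in "ACGU"})
        raise StructureError(f"non-RNA characters in sequence: {bad}")
    return seq


def _encode(seq: str) -> np.ndarray:
    return np.array([_RNA_CODE[b] for b in seq], dtype=np.int8)


def fold_maxpair(sequence: str, config: FoldConfig = FoldConfig()) -> str:
    """Maximum base-pairing dot-bracket (Nussinov DP, vectorized).

    Recurrence: M[i,j] = max(M[i+1,j], max over pairable k of
    M[i+1,k-1] + M[k+1,j] + 1) with min loop ``config.min_loop`` and
    pair span k-i <= ``config.max_pair_distance``.  The traceback prefers
    pairing the left base whenever an optimal pairing exists.
    """
    seq = to_rna(sequence)
    n = len(seq)
    if n == 0:
        return ""
    code = _encode(seq)
    pairable = _ALLOWED[code[:, None], code[None, :]]
    minspan = config.min_loop + 1
    maxd = config.max_pair_distance

    # diagonal-major DP: diags[L][i] == M[i, i+L]; contiguous slices keep the
    # inner loop in vectorized numpy
    diags: list[np.ndarray] = [np.zeros(n - L, dtype=np.int32) for L in range(min(n, minspan))]
    pair_diags = [np.diagonal(pairable, d).copy() for d in range(n)]
    zeros = np.zeros(n, dtype=np.int32)
    for L in range(minspan, n):
        width = n - L
        best = diags[L - 1][1:].copy()  # i left unpaired
        for d in range(minspan, min(L, maxd) + 1):
            left = diags[d - 2][1:width + 1]            # M[i+1, i+d-1]
            if d == L:
                right = zeros[:width]                   # M[j+1, j] == 0
            else:
                right = diags[L - d - 1][d + 1:d + 1 + width]  # M[i+d+1, j]
            cand = left + right + 1
            ok = pair_diags[d][:width]
            np.maximum(best, np.where(ok, cand, -1), out=best)
        diags.append(best)

    M = np.zeros((n + 1, n + 1), dtype=np.int32)
    for L in range(n):
        idx = np.arange(n - L)
        M[idx, idx + L] = diags[L]

    structure = ["."] * n
    stack = [(0, n - 1)]
    while stack:
        i, j = stack.pop()
        while j - i >= minspan and M[i, j] > 0:
            target = M[i, j]
            paired = False
            for k in range(i + minspan, min(i + maxd, j) + 1):
                if pairable[i, k] and M[i + 1, k - 1] + M[k + 1, j] + 1 == target:
                    structure[i] = "("
                    structure[k] = ")"
                    if k + 1 < j:
                        stack.append((k + 1, j))
                    i, j = i + 1, k - 1
                    paired = True
                    break
            if not paired:
                i += 1
    return "".join(structure)


def _mea_available() -> bool:
    try:
        import RNA  # noqa: F401
    except ImportError:
        return False
    return True


def fold_mea_vienna(sequence: str, config: FoldConfig = FoldConfig()) -> str:
    """Thermodynamic MEA structure via the ViennaRNA bindings."""
    import RNA

    seq = to_rna(sequence)
    md = RNA.md()
    md.temperature = config.temperature
    md.max_bp_span = config.max_pair_distance
    fc = RNA.fold_compound(seq, md)
    fc.pf()
    structure, _ = fc.MEA(config.gamma)
    return structure


def fold_mea(
    sequence: str, config: FoldConfig = FoldConfig(), engine: str = "auto"
) -> tuple[str, str]:
    """Fold a sequence, returning (dot_bracket, engine_name).

    ``engine``: 'mea' (requires ViennaRNA), 'maxpair' (fallback), or 'auto'
    (mea when available, else maxpair).
    """
    if engine == "auto":
        engine = "mea" if _mea_available() else "maxpair"
    if engine == "mea":
        if not _mea_available():
            raise StructureError(
                "ViennaRNA python bindings not available; use engine='maxpair'"
            )
        return fold_mea_vienna(sequence, config), "mea"
    if engine == "maxpair":
        return fold_maxpair(sequence, config), "maxpair"
    raise ValueError(f"unknown engine {engine!r}")


def validate_dot_bracket(db: str, max_pair_distance: int | None = None) -> list[tuple[int, int]]:
    """Check balance/non-crossing and the distance cap; return the pair list."""
    stack: list[int] = []
    pairs: list[tuple[int, int]] = []
    for i, c in enumerate(db):
        if c == "(":
            stack.append(i)
        elif c == ")":
            if not stack:
                raise StructureError("unbalanced dot-bracket")
            pairs.append((stack.pop(), i))
        elif c != ".":
            raise StructureError(f"invalid dot-bracket character {c!r}")
    if stack:
        raise StructureError("unbalanced dot-bracket")
    if max_pair_distance is not None:
        for i, j in pairs:
            if j - i > max_pair_distance:
                raise StructureError(f"pair ({i},{j}) exceeds distance cap")
    return pairs


# --------------------------------------------------------------------------
# Context extraction and filtering
# --------------------------------------------------------------------------

def extract_fold_context(
    site: GenomicSite,
    models: Sequence[TranscriptModel],
    sequences: Mapping[str, str],
    config: FoldConfig = FoldConfig(),
) -> tuple[str, int]:
    """Sequence window to fold and the site's offset within it.

    Exonic sites get the full spliced transcript; intronic/non-annotated
    sites get ``intron_window`` nt of genomic context centered on the site
    (strand-oriented, truncated at contig ends).  Raises if the base at the
    site is not a C on the transcript strand.
    """
    for model in models:
        if model.chrom != site.chrom or model.strand != site.strand:
            continue
        tpos = model.genomic_to_transcript(site.pos)
        if tpos is None:
            continue
        seq = to_rna(model.spliced_sequence(sequences))
        if seq[tpos] != "C":
            raise StructureError(
                f"site {site.chrom}:{site.pos}({site.strand}) is "
                f"{seq[tpos]} not C in {model.transcript_id}"
            )
        return seq, tpos

    contig = sequences[site.chrom]
    half = config.intron_window // 2
    start = max(0, site.pos - half)
    end = min(len(contig), site.pos + half)
    window = contig[start:end]
    offset = site.pos - start
    if site.strand == "-":
        from Bio.Seq import reverse_complement

        window = reverse_complement(window)
        offset = len(window) - 1 - offset
    window = to_rna(window)
    if window[offset] != "C":
        raise StructureError(
            f"site {site.chrom}:{site.pos}({site.strand}) is "
            f"{window[offset]} not C"
        )
    return window, offset


def annotate_structures(
    sites: Sequence[GenomicSite],
    models: Sequence[TranscriptModel],
    sequences: Mapping[str, str],
    config: FoldConfig = FoldConfig(),
    engine: str = "auto",
) -> list[StructureAnnotation]:
    """Fold each site's context (cached per window) and record paired state."""
    cache: dict[str, tuple[str, str]] = {}
    out = []
    for site in sites:
        window, offset = extract_fold_context(site, models, sequences, config)
        if window not in cache:
            cache[window] = fold_mea(window, config, engine)
        db, used_engine = cache[window]
        out.append(
            StructureAnnotation(
                site=site,
                paired=db[offset] != ".",
                dot_bracket=db,
                offset=offset,
                engine=used_engine,
            )
        )
    return out


def filter_paired_candidates(
    sites: Sequence[GenomicSite],
    annotations: Sequence[StructureAnnotation],
) -> tuple[list[GenomicSite], list[StructureAnnotation]]:
    """Retain unpaired candidates; return (retained, discard log)."""
    by_key = {a.site.key(): a for a in annotations}
    retained: list[GenomicSite] = []
    discarded: list[StructureAnnotation] = []
    for site in sites:
        ann = by_key.get(site.key())
        if ann is None:
            raise StructureError(
                f"no structure annotation for {site.chrom}:{site.pos}({site.strand})"
            )
        if ann.paired:
            discarded.append(ann)
        else:
            retained.append(site)
    return retained, discarded


def write_discard_log(discards: Sequence[StructureAnnotation],
                      path, context: int = 15) -> None:
    with open(path, "w") as fh:
        fh.write("chrom\tpos\tstrand\tengine\tcontext\n")
        for ann in discards:
            a = max(0, ann.offset - context)
            b = min(len(ann.dot_bracket), ann.offset + context + 1)
            fh.write(
                f"{ann.site.chrom}\t{ann.site.pos}\t{ann.site.strand}"
                f"\t{ann.engine}\t{ann.dot_bracket[a:b]}\n"
            )
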