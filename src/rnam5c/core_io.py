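"""Data model, coordinate conventions and readers/writers.

All internal coordinates are 0-based half-open on the genome (BED native);
GTF records are converted on read.  Transcript coordinates are 0-based
offsets into the spliced transcript in 5'->3' transcript orientation.
Site report TSVs are written 1-based and say so in their header.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio.Seq import reverse_complement


class AnnotationError(ValueError):
    """Malformed or inconsistent transcript annotation."""


class TrackError(ValueError):
    """Malformed interval track."""


# --------------------------------------------------------------------------
# Domain types
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class GenomicSite:
    """A strand-resolved single-base genomic position (0-based)."""

    chrom: str
    pos: int
    strand: str
    transcript_id: str | None = None
    transcript_pos: int | None = None

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"invalid strand {self.strand!r}")
        if self.pos < 0:
            raise ValueError(f"negative position {self.pos}")

    def key(self) -> tuple[str, int, str]:
        return (self.chrom, self.pos, self.strand)


@dataclass(frozen=True)
class TrackInterval:
    """Half-open [start, end) genomic interval with optional label/score."""

    chrom: str
    start: int
    end: int
    strand: str = "."
    label: str = "."
    score: float | None = None

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise TrackError(
                f"interval start >= end: {self.chrom}:{self.start}-{self.end}"
            )


@dataclass
class FeatureTrack:
    """A named collection of genomic intervals (miRNA targets, RBP sites, ...)."""

    name: str
    intervals: list[TrackInterval] = field(default_factory=list)
    metadata: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self):
        return iter(self.intervals)

    def sorted(self) -> "FeatureTrack":
        ivs = sorted(self.intervals, key=lambda t: (t.chrom, t.start, t.end, t.label))
        return FeatureTrack(self.name, ivs, dict(self.metadata))


@dataclass
class TranscriptModel:
    """Gene/transcript structure with derived UTR/CDS segments.

    ``exons`` are genomic half-open intervals, stored sorted by genomic start;
    transcript orientation (5'->3') follows ``strand``.  ``cds_start``/``cds_end``
    are genomic coordinates of the translated span (half-open); ``None`` for
    non-coding transcripts.
    """

    transcript_id: str
    gene_id: str
    chrom: str
    strand: str
    exons: list[tuple[int, int]]
    cds_start: int | None = None
    cds_end: int | None = None

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise AnnotationError(
                f"{self.transcript_id}: invalid strand {self.strand!r}"
            )
        self.exons = sorted((int(s), int(e)) for s, e in self.exons)
        if not self.exons:
            raise AnnotationError(f"{self.transcript_id}: no exons")
        prev_end = None
        for s, e in self.exons:
            if s >= e:
                raise AnnotationError(
                    f"{self.transcript_id}: empty/inverted exon [{s},{e})"
                )
            if prev_end is not None and s < prev_end:
                raise AnnotationError(f"{self.transcript_id}: overlapping exons")
            prev_end = e
        if (self.cds_start is None) != (self.cds_end is None):
            raise AnnotationError(
                f"{self.transcript_id}: cds_start/cds_end must be set together"
            )
        if self.cds_start is not None:
            if self.cds_start >= self.cds_end:
                raise AnnotationError(f"{self.transcript_id}: empty CDS")
            if (
                self.genomic_to_transcript(self.cds_start) is None
                or self.genomic_to_transcript(self.cds_end - 1) is None
            ):
                raise AnnotationError(
                    f"{self.transcript_id}: CDS bounds outside exon union"
                )
            lo, hi = self._cds_transcript_bounds()
            if hi - lo < 3:
                raise AnnotationError(f"{self.transcript_id}: CDS shorter than 3 nt")

    # -- coordinates ------------------------------------------------------

    @property
    def transcript_length(self) -> int:
        return sum(e - s for s, e in self.exons)

    @property
    def is_coding(self) -> bool:
        return self.cds_start is not None

    def genomic_to_transcript(self, pos: int) -> int | None:
        """0-based spliced-transcript offset of a genomic position, or None
        if the position is not exonic."""
        off = 0
        for s, e in self.exons:
            if s <= pos < e:
                plus_off = off + (pos - s)
                if self.strand == "+":
                    return plus_off
                return self.transcript_length - 1 - plus_off
            off += e - s
        return None

    def transcript_to_genomic(self, tpos: int) -> int:
        n = self.transcript_length
        if not 0 <= tpos < n:
            raise ValueError(f"{self.transcript_id}: transcript pos {tpos} out of range")
        plus_off = tpos if self.strand == "+" else n - 1 - tpos
        for s, e in self.exons:
            if plus_off < e - s:
                return s + plus_off
            plus_off -= e - s
        raise AssertionError("unreachable")

    def exonic_positions(self) -> list[int]:
        """All genomic exonic positions, in genomic order."""
        out: list[int] = []
        for s, e in self.exons:
            out.extend(range(s, e))
        return out

    # -- segments ---------------------------------------------------------

    def _cds_transcript_bounds(self) -> tuple[int, int]:
        t1 = self.genomic_to_transcript(self.cds_start)
        t2 = self.genomic_to_transcript(self.cds_end - 1)
        assert t1 is not None and t2 is not None
        lo, hi = min(t1, t2), max(t1, t2) + 1
        return lo, hi

    def segments(self) -> dict[str, tuple[int, int]] | None:
        """Transcript-coordinate half-open intervals for utr5/cds/utr3,
        or None for non-coding transcripts."""
        if not self.is_coding:
            return None
        lo, hi = self._cds_transcript_bounds()
        return {
            "utr5": (0, lo),
            "cds": (lo, hi),
            "utr3": (hi, self.transcript_length),
        }

    @property
    def cds_length(self) -> int:
        if not self.is_coding:
            return 0
        lo, hi = self._cds_transcript_bounds()
        return hi - lo

    # -- sequence ---------------------------------------------------------

    def spliced_sequence(self, genome: Mapping[str, str]) -> str:
        """Spliced transcript sequence in transcript orientation (DNA alphabet)."""
        chrom_seq = genome[self.chrom]
        seq = "".join(chrom_seq[s:e] for s, e in self.exons)
        if self.strand == "-":
            seq = reverse_complement(seq)
        return seq


# --------------------------------------------------------------------------
# Annotation readers
# --------------------------------------------------------------------------

def read_annotation(path: str | os.PathLike) -> list[TranscriptModel]:
    """Read a GTF or BED12 annotation into TranscriptModels.

    The dialect is chosen by file extension (``.bed``/``.bed12`` vs
    anything else = GTF).  GTF 1-based closed coordinates are converted to
    0-based half-open on read.
    """
    path = os.fspath(path)
    if path.endswith((".bed", ".bed12")):
        return _read_bed12(path)
    return _read_gtf(path)


def _read_gtf(path: str) -> list[TranscriptModel]:
    import gffutils

    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            if len(line.rstrip("\n").split("\t")) != 9:
                raise AnnotationError(f"{path}:{lineno}: expected 9 tab-separated fields")
    try:
        db = gffutils.create_db(
            path,
            ":memory:",
            force=True,
            keep_order=True,
            merge_strategy="create_unique",
            disable_infer_genes=True,
            disable_infer_transcripts=True,
        )
    except Exception as exc:  # pragma: no cover - gffutils error text varies
        raise AnnotationError(f"{path}: failed to parse GTF: {exc}") from exc

    exons: dict[str, dict] = {}
    for ftype in ("exon", "CDS"):
        for feat in db.features_of_type(ftype):
            try:
                tid = feat.attributes["transcript_id"][0]
                gid = feat.attributes["gene_id"][0]
            except KeyError as exc:
                raise AnnotationError(
                    f"{path}: {ftype} record without transcript_id/gene_id "
                    f"at {feat.seqid}:{feat.start}"
                ) from exc
            rec = exons.setdefault(
                tid,
                {"gene_id": gid, "chrom": feat.seqid, "strand": feat.strand,
                 "exons": [], "cds": []},
            )
            # gffutils keeps GTF 1-based closed coords; convert here
            iv = (feat.start - 1, feat.end)
            rec[{"exon": "exons", "CDS": "cds"}[ftype]].append(iv)

    models = []
    for tid in sorted(exons):
        rec = exons[tid]
        cds_start = cds_end = None
        if rec["cds"]:
            cds_start = min(s for s, _ in rec["cds"])
            cds_end = max(e for _, e in rec["cds"])
        models.append(
            TranscriptModel(
                transcript_id=tid,
                gene_id=rec["gene_id"],
                chrom=rec["chrom"],
                strand=rec["strand"],
                exons=rec["exons"],
                cds_start=cds_start,
                cds_end=cds_end,
            )
        )
    return models


def _read_bed12(path: str) -> list[TranscriptModel]:
    models = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 12:
                raise AnnotationError(f"{path}:{lineno}: BED12 needs 12 fields")
            try:
                chrom = fields[0]
                start, end = int(fields[1]), int(fields[2])
                name = fields[3]
                strand = fields[5]
                thick_start, thick_end = int(fields[6]), int(fields[7])
                n_blocks = int(fields[9])
                sizes = [int(x) for x in fields[10].rstrip(",").split(",")]
                starts = [int(x) for x in fields[11].rstrip(",").split(",")]
            except ValueError as exc:
                raise AnnotationError(f"{path}:{lineno}: {exc}") from exc
            if len(sizes) != n_blocks or len(starts) != n_blocks:
                raise AnnotationError(f"{path}:{lineno}: blockCount mismatch")
            exons = [(start + bs, start + bs + sz) for bs, sz in zip(starts, sizes)]
            if exons[0][0] != start or exons[-1][1] != end:
                raise AnnotationError(
                    f"{path}:{lineno}: blocks do not span chromStart..chromEnd"
                )
            coding = thick_start < thick_end
            models.append(
                TranscriptModel(
                    transcript_id=name,
                    gene_id=name,
                    chrom=chrom,
                    strand=strand,
                    exons=exons,
                    cds_start=thick_start if coding else None,
                    cds_end=thick_end if coding else None,
                )
            )
    return models


def write_gtf(models: Sequence[TranscriptModel], path: str | os.PathLike) -> None:
    """Write models as ensembl-dialect GTF (gene/transcript/exon/CDS lines)."""
    with open(path, "w") as fh:
        for m in models:
            attrs = f'gene_id "{m.gene_id}"; transcript_id "{m.transcript_id}";'
            gstart = m.exons[0][0] + 1
            gend = m.exons[-1][1]
            fh.write(
                f"{m.chrom}\trnam5c\ttranscript\t{gstart}\t{gend}\t.\t{m.strand}\t.\t{attrs}\n"
            )
            for s, e in m.exons:
                fh.write(
                    f"{m.chrom}\trnam5c\texon\t{s + 1}\t{e}\t.\t{m.strand}\t.\t{attrs}\n"
                )
            if m.is_coding:
                for s, e in m.exons:
                    cs, ce = max(s, m.cds_start), min(e, m.cds_end)
                    if cs < ce:
                        fh.write(
                            f"{m.chrom}\trnam5c\tCDS\t{cs + 1}\t{ce}\t.\t{m.strand}\t.\t{attrs}\n"
                        )


# --------------------------------------------------------------------------
# Tracks and sites
# --------------------------------------------------------------------------

def read_track(path: str | os.PathLike, name: str | None = None) -> FeatureTrack:
    """Read a BED3/6/12 file into a FeatureTrack (BED12 blocks are ignored;
    the record span is kept as a single interval)."""
    path = os.fspath(path)
    intervals = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise TrackError(f"{path}:{lineno}: BED needs >=3 fields")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise TrackError(f"{path}:{lineno}: {exc}") from exc
            if start >= end:
                raise TrackError(f"{path}:{lineno}: start >= end")
            label = fields[3] if len(fields) > 3 else "."
            score: float | None = None
            if len(fields) > 4 and fields[4] not in (".", ""):
                try:
                    score = float(fields[4])
                except ValueError:
                    score = None
            strand = fields[5] if len(fields) > 5 else "."
            intervals.append(TrackInterval(fields[0], start, end, strand, label, score))
    return FeatureTrack(name or os.path.basename(path), intervals)


def write_track(track: FeatureTrack, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for iv in track.intervals:
            score = "." if iv.score is None else f"{iv.score:g}"
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.label}\t{score}\t{iv.strand}\n"
            )


def write_sites(
    sites: Iterable[GenomicSite],
    bed_path: str | os.PathLike,
    tsv_path: str | os.PathLike | None = None,
) -> None:
    """Write sites as BED6 (0-based half-open) and, optionally, a 1-based TSV
    report (the convention is stated in the TSV header)."""
    sites = list(sites)
    with open(bed_path, "w") as fh:
        for s in sites:
            label = s.transcript_id or "."
            fh.write(f"{s.chrom}\t{s.pos}\t{s.pos + 1}\t{label}\t0\t{s.strand}\n")
    if tsv_path is not None:
        with open(tsv_path, "w") as fh:
            fh.write("# site report; pos is 1-based\n")
            fh.write("chrom\tpos\tstrand\ttranscript_id\ttranscript_pos\n")
            for s in sites:
                tid = s.transcript_id or "."
                tp = "." if s.transcript_pos is None else str(s.transcript_pos + 1)
                fh.write(f"{s.chrom}\t{s.pos + 1}\t{s.strand}\t{tid}\t{tp}\n")


def read_sites(bed_path: str | os.PathLike) -> list[GenomicSite]:
    """Read single-base sites back from a BED6 file written by write_sites."""
    track = read_track(bed_path)
    sites = []
    for iv in track.intervals:
        if iv.end - iv.start != 1:
            raise TrackError(f"{bed_path}: non single-base site {iv}")
        tid = None if iv.label == "." else iv.label
        sites.append(GenomicSite(iv.chrom, iv.start, iv.strand, transcript_id=tid))
    return sites


# --------------------------------------------------------------------------
# Pileups and FASTA
# --------------------------------------------------------------------------

PILEUP_COLUMNS = ["chrom", "pos", "strand", "n", "k"]


def read_pileup(path: str | os.PathLike) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#")
    missing = set(PILEUP_COLUMNS) - set(df.columns)
    if missing:
        raise TrackError(f"{path}: pileup missing columns {sorted(missing)}")
    if ((df["k"] < 0) | (df["k"] > df["n"])).any():
        raise TrackError(f"{path}: pileup with k outside [0, n]")
    return df


def write_pileup(df: pd.DataFrame, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        fh.write("# per-cytosine bisulfite pileup; pos is 0-based\n")
        df.to_csv(fh, sep="\t", index=False, columns=PILEUP_COLUMNS)


def read_fasta(path: str | os.PathLike) -> dict[str, str]:
    from Bio import SeqIO

    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(os.fspath(path), "fasta")}


def write_fasta(seqs: Mapping[str, str], path: str | os.PathLike, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name in seqs:
            fh.write(f">{name}\n")
            seq = seqs[name]
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")
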