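"""Synthetic transcriptome and bisulfite-evidence generator with known truth.

Produces a small genome with gene models (5'UTR/CDS/3'UTR, introns,
intergenic spacers), unmethylated spike-in contigs, planted methylation
states, planted hairpins (6-bp C:G stem + UUCG tetraloop) and unstructured
spacer cytosines, planted m6A motifs, per-replicate pileups (and optionally
positioned reads), and miRNA/RBP/m6A feature tracks.

Everything is a deterministic function of the config seed.
"""

from __future__ import annotations

import json
import os
import zlib
from dataclasses import dataclass, field, replace, asdict

import numpy as np
import pandas as pd

from .core_io import (
    FeatureTrack,
    GenomicSite,
    TrackInterval,
    TranscriptModel,
    write_fasta,
    write_gtf,
    write_pileup,
    write_track,
)


class ConfigError(ValueError):
    """Invalid simulation configuration."""


# hairpin mirroring the validation oligo: 6-bp C:G stem, UUCG tetraloop
HAIRPIN_STEM5 = "CCCCCC"
HAIRPIN_LOOP = "TTCG"  # DNA spelling of UUCG
HAIRPIN_STEM3 = "GGGGGG"
# G-free spacer zone whose Cs cannot base-pair (no G partner in reach)
SPACER_ZONE = "AAAAAC" * 3 + "AAAAA"
SPACER_C_OFFSETS = (5, 11, 17)


@dataclass
class SimulationConfig:
    seed: int = 0
    n_genes: int = 30
    utr5_mean: int = 80
    cds_mean: int = 300
    utr3_mean: int = 150
    exons_per_transcript: tuple[int, int] = (1, 3)
    intron_mean: int = 120
    intergenic_mean: int = 200
    coverage_mean: float = 50.0
    # probability an unmethylated C reads as C (non-conversion error)
    conversion_error: float = 0.005
    # probability a methylated C reads as T (inappropriate conversion)
    inappropriate_conversion: float = 0.0
    # fraction of cytosines planted as methylated, per segment; the optional
    # "aug25" key concentrates additional sites in the AUG +/- 25 nt window
    meth_fraction: dict = field(
        default_factory=lambda: {"utr5": 0.02, "cds": 0.02, "utr3": 0.02}
    )
    meth_level_range: tuple[float, float] = (0.2, 1.0)
    n_replicates: int = 3
    read_length: int = 100
    base_quality_mean: int = 38
    n_spikeins: int = 2
    spikein_length: int = 400
    spikein_coverage_mean: float = 100.0
    hairpin_fraction: float = 0.0
    plant_hairpin_sites: bool = True
    structure_pad: int = 150  # G-free buffer so spacer Cs stay unpaired
    n_m6a_per_transcript: int = 1
    sample_overlap: float = 0.5
    sample_types: tuple[str, str] = ("ESC", "brain")

    def __post_init__(self) -> None:
        for name in ("utr5_mean", "cds_mean", "utr3_mean"):
            if getattr(self, name) < 10:
                raise ConfigError(f"{name} must be >= 10 nt")
        if not 0.0 <= self.conversion_error <= 1.0:
            raise ConfigError("conversion_error must be in [0, 1]")
        if not 0.0 <= self.inappropriate_conversion <= 1.0:
            raise ConfigError("inappropriate_conversion must be in [0, 1]")
        if self.n_genes < 1:
            raise ConfigError("n_genes must be >= 1")
        lo, hi = self.meth_level_range
        if not 0.0 < lo <= hi <= 1.0:
            raise ConfigError("meth_level_range must satisfy 0 < lo <= hi <= 1")


@dataclass(frozen=True)
class PlantedSite:
    transcript_id: str
    transcript_pos: int
    chrom: str
    pos: int
    strand: str
    level: float

    def site(self) -> GenomicSite:
        return GenomicSite(
            self.chrom, self.pos, self.strand,
            transcript_id=self.transcript_id, transcript_pos=self.transcript_pos,
        )


@dataclass(frozen=True)
class Hairpin:
    transcript_id: str
    stem5: tuple[int, int]
    loop: tuple[int, int]
    stem3: tuple[int, int]


@dataclass
class GroundTruth:
    """Planted structure/feature truth of a generated transcriptome."""

    hairpins: list[Hairpin] = field(default_factory=list)
    spacer_cs: list[tuple[str, int]] = field(default_factory=list)
    m6a_sites: list[tuple[str, int]] = field(default_factory=list)  # (tid, tpos of A)


@dataclass
class SyntheticTranscriptome:
    genome: dict[str, str]
    models: list[TranscriptModel]
    spikein_ids: list[str]
    truth: GroundTruth
    config: SimulationConfig

    def model(self, transcript_id: str) -> TranscriptModel:
        return next(m for m in self.models if m.transcript_id == transcript_id)

    def transcript_sequences(self) -> dict[str, str]:
        return {m.transcript_id: m.spliced_sequence(self.genome) for m in self.models}


def _rng(config: SimulationConfig, *tokens) -> np.random.Generator:
    parts = [config.seed & 0xFFFFFFFF]
    for t in tokens:
        if isinstance(t, str):
            parts.append(zlib.crc32(t.encode()))
        else:
            parts.append(int(t) & 0xFFFFFFFF)
    return np.random.default_rng(parts)


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=length))


# --------------------------------------------------------------------------
# Transcriptome generation
# --------------------------------------------------------------------------

def generate_transcriptome(config: SimulationConfig) -> SyntheticTranscriptome:
    """Build the genome, transcript models, spike-ins and structural truth."""
    rng = _rng(config, "transcriptome")
    chrom = "chr1"
    genome_parts: list[str] = []
    cursor = 0
    models: list[TranscriptModel] = []
    truth = GroundTruth()

    hairpin_flags = rng.random(config.n_genes) < config.hairpin_fraction

    for gi in range(config.n_genes):
        gene_id = f"gene{gi + 1:04d}"
        tid = f"tx{gi + 1:04d}"
        strand = "+" if gi % 2 == 0 else "-"

        spacer = _random_seq(rng, max(20, int(rng.poisson(config.intergenic_mean))))
        genome_parts.append(spacer)
        cursor += len(spacer)

        utr5_len = max(10, int(rng.poisson(config.utr5_mean)))
        cds_len = max(30, int(rng.poisson(config.cds_mean)))
        utr3_len = max(10, int(rng.poisson(config.utr3_mean)))

        utr5 = _random_seq(rng, utr5_len)
        cds = "ATG" + _random_seq(rng, cds_len - 3)
        utr3 = _random_seq(rng, utr3_len)

        # plant exact m6A motif instances (HGGACNN) inside the CDS
        m6a_tpos: list[int] = []
        if config.n_m6a_per_transcript > 0 and cds_len >= 30:
            slots = rng.choice(
                np.arange(3, cds_len - 7),
                size=min(config.n_m6a_per_transcript, max(1, (cds_len - 10) // 20)),
                replace=False,
            )
            cds_chars = list(cds)
            taken: list[int] = []
            for s in sorted(int(x) for x in slots):
                if any(abs(s - t) < 7 for t in taken):
                    continue
                h = str(rng.choice(list("ACT")))
                nn = _random_seq(rng, 2)
                cds_chars[s:s + 7] = list(h + "GGAC" + nn)
                taken.append(s)
                m6a_tpos.append(utr5_len + s + 3)  # position of the A
            cds = "".join(cds_chars)

        tx_seq = utr5 + cds + utr3

        # hairpin-carrying transcripts get a designed, G-free 3' tail with
        # unstructured spacer Cs plus the stem-loop itself
        hairpin = None
        spacer_tpos: list[int] = []
        if hairpin_flags[gi]:
            pad = "A" * config.structure_pad
            tail_start = len(tx_seq)
            tail = pad + SPACER_ZONE + pad + HAIRPIN_STEM5 + HAIRPIN_LOOP + HAIRPIN_STEM3 + "A" * 10
            spacer_tpos = [
                tail_start + config.structure_pad + off for off in SPACER_C_OFFSETS
            ]
            hp = tail_start + config.structure_pad + len(SPACER_ZONE) + config.structure_pad
            hairpin = Hairpin(
                tid,
                stem5=(hp, hp + 6),
                loop=(hp + 6, hp + 10),
                stem3=(hp + 10, hp + 16),
            )
            tx_seq = tx_seq + tail
            utr3_len += len(tail)

        # split the transcript into exons and interleave introns
        n_exons = int(rng.integers(config.exons_per_transcript[0],
                                   config.exons_per_transcript[1] + 1))
        tx_len = len(tx_seq)
        if n_exons > 1:
            cuts = sorted(
                int(x) for x in rng.choice(np.arange(20, tx_len - 20), size=n_exons - 1,
                                           replace=False)
            )
            cuts = [c for i, c in enumerate(cuts) if i == 0 or c - cuts[i - 1] >= 20]
        else:
            cuts = []
        bounds = [0] + cuts + [tx_len]
        exon_chunks = [tx_seq[a:b] for a, b in zip(bounds, bounds[1:])]

        pre_parts: list[str] = []
        exon_iv_pre: list[tuple[int, int]] = []  # pre-mRNA coordinates
        off = 0
        for i, chunk in enumerate(exon_chunks):
            if i > 0:
                intron = _random_seq(rng, max(20, int(rng.poisson(config.intron_mean))))
                pre_parts.append(intron)
                off += len(intron)
            pre_parts.append(chunk)
            exon_iv_pre.append((off, off + len(chunk)))
            off += len(chunk)
        pre = "".join(pre_parts)

        if strand == "+":
            gene_seq = pre
            exons = [(cursor + s, cursor + e) for s, e in exon_iv_pre]
        else:
            gene_seq = _revcomp(pre)
            L = len(pre)
            exons = [(cursor + L - e, cursor + L - s) for s, e in exon_iv_pre]

        model = TranscriptModel(
            transcript_id=tid, gene_id=gene_id, chrom=chrom,
            strand=strand, exons=exons,
        )
        c0, c1 = utr5_len, utr5_len + cds_len  # transcript coords
        g1 = model.transcript_to_genomic(c0)
        g2 = model.transcript_to_genomic(c1 - 1)
        model = replace(model, cds_start=min(g1, g2), cds_end=max(g1, g2) + 1)
        models.append(model)

        if hairpin is not None:
            truth.hairpins.append(hairpin)
            truth.spacer_cs.extend((tid, tp) for tp in spacer_tpos)
        truth.m6a_sites.extend((tid, tp) for tp in m6a_tpos)

        genome_parts.append(gene_seq)
        cursor += len(gene_seq)

    tail_spacer = _random_seq(rng, max(20, int(rng.poisson(config.intergenic_mean))))
    genome_parts.append(tail_spacer)
    genome = {chrom: "".join(genome_parts)}

    spike_ids = []
    for si in range(config.n_spikeins):
        name = f"spikein_{si + 1}"
        genome[name] = _random_seq(rng, config.spikein_length)
        spike_ids.append(name)

    st = SyntheticTranscriptome(genome, models, spike_ids, truth, config)
    _check_truth(st)
    return st


def _revcomp(seq: str) -> str:
    from Bio.Seq import reverse_complement

    return reverse_complement(seq)


def _check_truth(st: SyntheticTranscriptome) -> None:
    tseqs = st.transcript_sequences()
    for tid, tp in st.truth.spacer_cs:
        assert tseqs[tid][tp] == "C", "spacer truth position is not a C"
    for hp in st.truth.hairpins:
        s5 = tseqs[hp.transcript_id][hp.stem5[0]:hp.stem5[1]]
        assert s5 == HAIRPIN_STEM5, "hairpin stem truth mismatch"


# --------------------------------------------------------------------------
# Methylation truth
# --------------------------------------------------------------------------

def transcript_c_positions(model: TranscriptModel, genome: dict[str, str]) -> np.ndarray:
    """Transcript coordinates of every C on the transcript strand."""
    seq = model.spliced_sequence(genome)
    return np.frombuffer(seq.encode(), dtype=np.uint8).view(np.uint8) == ord("C")


def plant_methylation(
    st: SyntheticTranscriptome,
    sample_type: str = "ESC",
    meth_fraction: dict | None = None,
) -> list[PlantedSite]:
    """Choose methylated cytosines per segment at the configured fractions."""
    config = st.config
    frac = dict(config.meth_fraction if meth_fraction is None else meth_fraction)
    rng = _rng(config, "truth", sample_type)
    lo, hi = config.meth_level_range
    sites: list[PlantedSite] = []
    chosen: set[tuple[str, int]] = set()

    def add(model: TranscriptModel, tpos: int, level: float) -> None:
        key = (model.transcript_id, tpos)
        if key in chosen:
            return
        chosen.add(key)
        gpos = model.transcript_to_genomic(tpos)
        sites.append(PlantedSite(model.transcript_id, tpos, model.chrom, gpos,
                                 model.strand, level))

    for model in st.models:
        seq = model.spliced_sequence(st.genome)
        segs = model.segments()
        if segs is None:
            continue
        for seg_name in ("utr5", "cds", "utr3"):
            f = frac.get(seg_name, 0.0)
            if f <= 0:
                continue
            a, b = segs[seg_name]
            cpos = [i for i in range(a, b) if seq[i] == "C"]
            if not cpos:
                continue
            take = rng.random(len(cpos)) < f
            for i, tp in enumerate(cpos):
                if take[i]:
                    add(model, tp, float(rng.uniform(lo, hi)))
        if frac.get("aug25", 0.0) > 0:
            aug = segs["cds"][0]
            a = max(0, aug - 25)
            b = min(model.transcript_length, aug + 25 + 1)
            cpos = [i for i in range(a, b) if seq[i] == "C"]
            take = rng.random(len(cpos)) < frac["aug25"]
            for i, tp in enumerate(cpos):
                if take[i]:
                    add(model, tp, float(rng.uniform(max(lo, 0.5), hi)))

    if config.plant_hairpin_sites:
        for hp in st.truth.hairpins:
            model = st.model(hp.transcript_id)
            for tp in range(*hp.stem5):
                add(model, tp, 1.0)
        for tid, tp in st.truth.spacer_cs:
            add(st.model(tid), tp, 1.0)

    sites.sort(key=lambda s: (s.chrom, s.pos, s.strand))
    return sites


def plant_sample_truths(st: SyntheticTranscriptome) -> dict[str, list[PlantedSite]]:
    """Two sample types sharing a configurable fraction of planted sites."""
    config = st.config
    a_name, b_name = config.sample_types
    pool = plant_methylation(st, "pool")
    rng = _rng(config, "sample-split")
    truths: dict[str, list[PlantedSite]] = {a_name: [], b_name: []}
    for s in pool:
        u = rng.random()
        if u < config.sample_overlap:
            truths[a_name].append(s)
            truths[b_name].append(s)
        elif u < config.sample_overlap + (1 - config.sample_overlap) / 2:
            truths[a_name].append(s)
        else:
            truths[b_name].append(s)
    return truths


# --------------------------------------------------------------------------
# Pileup / read simulation
# --------------------------------------------------------------------------

def _nonconversion_prob(level: np.ndarray, eps: float, delta: float) -> np.ndarray:
    return level * (1.0 - delta) + (1.0 - level) * eps


def simulate_pileups(
    st: SyntheticTranscriptome,
    truth_sites: list[PlantedSite],
    sample_type: str,
    replicate: int,
) -> pd.DataFrame:
    """Per-cytosine pileup for one replicate over all exonic transcript Cs.

    At each C, non-converted count ~ Binomial(n, r(1-d) + (1-r)e), with
    r = 0 for unmethylated Cs.  The replicate index perturbs only the
    sampling, never the truth.
    """
    config = st.config
    rng = _rng(config, "pileup", sample_type, replicate)
    level = {(s.transcript_id, s.transcript_pos): s.level for s in truth_sites}

    rows: list[tuple] = []
    for model in st.models:
        seq = model.spliced_sequence(st.genome)
        tpos = [i for i, b in enumerate(seq) if b == "C"]
        if not tpos:
            continue
        r = np.array([level.get((model.transcript_id, i), 0.0) for i in tpos])
        n = rng.poisson(config.coverage_mean, size=len(tpos))
        p = _nonconversion_prob(r, config.conversion_error,
                                config.inappropriate_conversion)
        k = rng.binomial(n, p)
        gpos = [model.transcript_to_genomic(i) for i in tpos]
        rows.extend(
            zip([model.chrom] * len(tpos), gpos, [model.strand] * len(tpos), n, k)
        )
    df = pd.DataFrame(rows, columns=["chrom", "pos", "strand", "n", "k"])
    return df.sort_values(["chrom", "pos", "strand"], ignore_index=True)


def simulate_spikein_pileups(
    st: SyntheticTranscriptome, sample_type: str, replicate: int
) -> pd.DataFrame:
    """Pileups over the wholly unmethylated spike-in contigs (r = 0 everywhere)."""
    config = st.config
    rng = _rng(config, "spike", sample_type, replicate)
    rows: list[tuple] = []
    for name in st.spikein_ids:
        seq = st.genome[name]
        pos = [i for i, b in enumerate(seq) if b == "C"]
        n = rng.poisson(config.spikein_coverage_mean, size=len(pos))
        k = rng.binomial(n, config.conversion_error)
        rows.extend(zip([name] * len(pos), pos, ["+"] * len(pos), n, k))
    return pd.DataFrame(rows, columns=["chrom", "pos", "strand", "n", "k"])


READ_COLUMNS = ["transcript_id", "start", "orientation", "seq", "qual"]


def simulate_reads(
    st: SyntheticTranscriptome,
    truth_sites: list[PlantedSite],
    sample_type: str,
    replicate: int,
    mbias_error: float = 0.0,
    low_quality_frac: float = 0.0,
    low_quality_q: int = 20,
) -> pd.DataFrame:
    """Positioned reads on transcript coordinates with per-base qualities.

    Reads are reported on the transcript strand; ``orientation`` marks which
    physical end is the sequencing 5' end (``fwd`` = left, ``rev`` = right),
    which is what m-bias trimming acts on.  ``mbias_error`` adds spurious
    non-conversion within the 5'-most 10 bases of each read.
    """
    config = st.config
    rng = _rng(config, "reads", sample_type, replicate)
    level = {(s.transcript_id, s.transcript_pos): s.level for s in truth_sites}
    eps, delta = config.conversion_error, config.inappropriate_conversion

    rows: list[tuple] = []
    for model in st.models:
        seq = model.spliced_sequence(st.genome)
        L = len(seq)
        rl = min(config.read_length, L)
        n_reads = max(1, int(round(config.coverage_mean * L / rl)))
        starts = rng.integers(0, L - rl + 1, size=n_reads)
        for start in starts:
            orientation = "fwd" if rng.random() < 0.5 else "rev"
            bases = list(seq[start:start + rl])
            for off in range(rl):
                if bases[off] != "C":
                    continue
                r = level.get((model.transcript_id, start + off), 0.0)
                p = r * (1 - delta) + (1 - r) * eps
                from_5p = off if orientation == "fwd" else rl - 1 - off
                if from_5p < 10 and rng.random() < mbias_error:
                    p = 1.0
                bases[off] = "C" if rng.random() < p else "T"
            quals = np.full(rl, config.base_quality_mean, dtype=int)
            if low_quality_frac > 0:
                lowq = rng.random(rl) < low_quality_frac
                quals[lowq] = low_quality_q
            qual = "".join(chr(q + 33) for q in quals)
            rows.append((model.transcript_id, int(start), orientation,
                         "".join(bases), qual))
    return pd.DataFrame(rows, columns=READ_COLUMNS)


def simulate_expression_counts(
    st: SyntheticTranscriptome,
    sample_type: str,
    scale: dict[str, float] | None = None,
) -> pd.DataFrame:
    """Exon-union read counts per gene per replicate (Poisson around the
    expected fragment count); ``scale`` rescales individual genes."""
    config = st.config
    rng = _rng(config, "expr", sample_type)
    scale = scale or {}
    data = {}
    genes = [m.gene_id for m in st.models]
    lam = np.array(
        [
            config.coverage_mean * m.transcript_length / config.read_length
            * scale.get(m.gene_id, 1.0)
            for m in st.models
        ]
    )
    for rep in range(1, config.n_replicates + 1):
        data[f"rep{rep}"] = rng.poisson(lam)
    return pd.DataFrame(data, index=pd.Index(genes, name="gene_id"))


# --------------------------------------------------------------------------
# Feature tracks
# --------------------------------------------------------------------------

def _contiguous_runs(model: TranscriptModel, a: int, b: int) -> list[tuple[int, int]]:
    """Maximal transcript-coordinate runs inside [a, b) whose genomic images
    are contiguous (i.e. runs that do not cross an exon junction)."""
    runs: list[tuple[int, int]] = []
    start = a
    prev_g = None
    for t in range(a, b):
        g = model.transcript_to_genomic(t)
        if prev_g is not None and abs(g - prev_g) != 1:
            runs.append((start, t))
            start = t
        prev_g = g
    if start < b:
        runs.append((start, b))
    return runs


def _t_interval_to_genomic(model: TranscriptModel, a: int, b: int) -> tuple[int, int]:
    g1 = model.transcript_to_genomic(a)
    g2 = model.transcript_to_genomic(b - 1)
    return (min(g1, g2), max(g1, g2) + 1)


def generate_feature_tracks(
    st: SyntheticTranscriptome,
    truth_sites: list[PlantedSite],
    mirna_mode: str = "null",
    rbp_factors: tuple[str, ...] = ("RBP1", "RBP2"),
    site_length: int = 20,
    sites_per_transcript: int = 1,
) -> dict[str, FeatureTrack]:
    """miRNA target / RBP / m6A tracks with a known relation to the truth.

    ``mirna_mode``: 'null' places target sites independently of planted
    m5Cs, 'enrich' centers them on planted 3'UTR m5Cs, 'exclude' rejects
    placements overlapping any planted site.
    """
    if mirna_mode not in ("null", "enrich", "exclude"):
        raise ValueError(f"unknown mirna_mode {mirna_mode!r}")
    config = st.config
    rng = _rng(config, "tracks", mirna_mode)
    planted = {(s.transcript_id, s.transcript_pos) for s in truth_sites}

    mirna_ivs: list[TrackInterval] = []
    for model in st.models:
        segs = model.segments()
        if segs is None:
            continue
        a, b = segs["utr3"]
        if b - a < site_length + 2:
            continue
        placed = 0
        if mirna_mode == "enrich":
            utr3_m5c = sorted(
                tp for tid, tp in planted
                if tid == model.transcript_id and a <= tp < b
            )
            for tp in utr3_m5c[:sites_per_transcript]:
                ta = max(a, tp - site_length // 2)
                tb = min(b, ta + site_length)
                for ra, rb in _contiguous_runs(model, ta, tb):
                    if ra <= tp < rb:
                        gs, ge = _t_interval_to_genomic(model, ra, rb)
                        score = -float(rng.uniform(0.2, 1.0))
                        mirna_ivs.append(TrackInterval(
                            model.chrom, gs, ge, model.strand,
                            f"mir_{model.transcript_id}_{placed}", score))
                        placed += 1
        else:
            tries = 0
            while placed < sites_per_transcript and tries < 50:
                tries += 1
                ta = int(rng.integers(a, b - site_length))
                tb = ta + site_length
                if mirna_mode == "exclude" and any(
                    (model.transcript_id, tp) in planted for tp in range(ta, tb)
                ):
                    continue
                runs = _contiguous_runs(model, ta, tb)
                ra, rb = max(runs, key=lambda r: r[1] - r[0])
                if rb - ra < 8:
                    continue
                gs, ge = _t_interval_to_genomic(model, ra, rb)
                score = -float(rng.uniform(0.2, 1.0))
                mirna_ivs.append(TrackInterval(
                    model.chrom, gs, ge, model.strand,
                    f"mir_{model.transcript_id}_{placed}", score))
                placed += 1

    rbp_tracks: dict[str, FeatureTrack] = {}
    for fi, factor in enumerate(rbp_factors):
        ivs: list[TrackInterval] = []
        for model in st.models:
            if int(rng.random() < 0.7):
                a, b = 0, model.transcript_length
                if b - a < site_length + 2:
                    continue
                ta = int(rng.integers(a, b - site_length))
                runs = _contiguous_runs(model, ta, min(b, ta + site_length))
                ra, rb = max(runs, key=lambda r: r[1] - r[0])
                if rb - ra < 8:
                    continue
                gs, ge = _t_interval_to_genomic(model, ra, rb)
                ivs.append(TrackInterval(model.chrom, gs, ge, model.strand,
                                         factor, None))
        rbp_tracks[factor] = FeatureTrack(factor, ivs)

    m6a_ivs: list[TrackInterval] = []
    for tid, tpos in st.truth.m6a_sites:
        model = st.model(tid)
        gs, ge = _t_interval_to_genomic(model, tpos - 3, tpos + 4)
        m6a_ivs.append(TrackInterval(model.chrom, gs, ge, model.strand, "m6A", None))

    tracks = {"miRNA_targets": FeatureTrack("miRNA_targets", mirna_ivs).sorted(),
              "m6A_peaks": FeatureTrack("m6A_peaks", m6a_ivs).sorted()}
    for factor, track in rbp_tracks.items():
        tracks[factor] = track.sorted()
    return tracks


# --------------------------------------------------------------------------
# Writers
# --------------------------------------------------------------------------

def write_truth(sites: list[PlantedSite], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        fh.write("# planted methylation truth; pos is 0-based\n")
        fh.write("transcript_id\ttranscript_pos\tchrom\tpos\tstrand\tlevel\n")
        for s in sites:
            fh.write(
                f"{s.transcript_id}\t{s.transcript_pos}\t{s.chrom}\t{s.pos}"
                f"\t{s.strand}\t{s.level:.6f}\n"
            )


def read_truth(path: str | os.PathLike) -> list[PlantedSite]:
    df = pd.read_csv(path, sep="\t", comment="#")
    return [
        PlantedSite(r.transcript_id, int(r.transcript_pos), r.chrom, int(r.pos),
                    r.strand, float(r.level))
        for r in df.itertuples()
    ]


def write_simulation(st: SyntheticTranscriptome, outdir: str | os.PathLike) -> dict:
    """Write FASTA/GTF/pileups/tracks/truth + manifest for both sample types."""
    outdir = os.fspath(outdir)
    os.makedirs(outdir, exist_ok=True)
    config = st.config

    write_fasta(st.genome, os.path.join(outdir, "genome.fa"))
    write_gtf(st.models, os.path.join(outdir, "annotation.gtf"))

    truths = plant_sample_truths(st)
    manifest = {
        "config": {k: list(v) if isinstance(v, tuple) else v
                   for k, v in asdict(config).items()},
        "samples": {},
        "spikeins": st.spikein_ids,
    }
    all_sites = sorted(
        {s for sites in truths.values() for s in sites},
        key=lambda s: (s.chrom, s.pos, s.strand),
    )
    tracks = generate_feature_tracks(st, all_sites)
    for name, track in tracks.items():
        write_track(track, os.path.join(outdir, f"track_{name}.bed"))

    for sample, sites in truths.items():
        write_truth(sites, os.path.join(outdir, f"truth_{sample}.tsv"))
        files = {"truth": f"truth_{sample}.tsv", "pileups": [], "spikein_pileups": []}
        for rep in range(1, config.n_replicates + 1):
            p = f"pileup_{sample}_rep{rep}.tsv"
            write_pileup(simulate_pileups(st, sites, sample, rep),
                         os.path.join(outdir, p))
            files["pileups"].append(p)
            sp = f"spikein_{sample}_rep{rep}.tsv"
            write_pileup(simulate_spikein_pileups(st, sample, rep),
                         os.path.join(outdir, sp))
            files["spikein_pileups"].append(sp)
        manifest["samples"][sample] = files

    with open(os.path.join(outdir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest
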