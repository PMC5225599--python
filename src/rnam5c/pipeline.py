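"""End-to-end pipeline on synthetic data: simulate -> call -> consensus ->
structure filter -> sample comparison -> positional statistics -> overlap
statistics.  Fully deterministic under the config seed; all outputs are
plain-text TSV/BED/JSON.
"""

from __future__ import annotations

import json
import os

import pandas as pd

from . import calling, comparison, overlap, positional, structure_filter, synthetic_data
from .core_io import GenomicSite, write_pileup, write_sites, write_track


def _site_from_row(row) -> GenomicSite:
    return GenomicSite(row.chrom, int(row.pos), row.strand)


def run_all(
    seed: int,
    outdir: str | os.PathLike,
    config: synthetic_data.SimulationConfig | None = None,
    iterations: int = 2000,
    engine: str = "maxpair",
) -> dict:
    """Run the whole analysis on a freshly simulated dataset.

    Returns a summary dict (also written to ``summary.json``).
    """
    outdir = os.fspath(outdir)
    os.makedirs(outdir, exist_ok=True)
    if config is None:
        config = synthetic_data.SimulationConfig(
            seed=seed, n_genes=20, hairpin_fraction=0.2, cds_mean=240,
            coverage_mean=60.0,
        )
    st = synthetic_data.generate_transcriptome(config)
    synthetic_data.write_simulation(st, os.path.join(outdir, "sim"))

    truths = synthetic_data.plant_sample_truths(st)
    samples = list(config.sample_types)
    genome = st.genome
    tseqs = st.transcript_sequences()

    calls: dict[str, list[pd.DataFrame]] = {}
    pileups: dict[str, list[pd.DataFrame]] = {}
    consensus: dict[str, pd.DataFrame] = {}
    expression: dict[str, comparison.ExpressionTable] = {}
    summary: dict = {"seed": seed, "samples": {}}

    for sample in samples:
        calls[sample] = []
        pileups[sample] = []
        for rep in range(1, config.n_replicates + 1):
            pile = synthetic_data.simulate_pileups(st, truths[sample], sample, rep)
            spike = synthetic_data.simulate_spikein_pileups(st, sample, rep)
            est = calling.estimate_conversion_error(spike)
            rep_calls = calling.call_candidates(pile, est.error)
            calls[sample].append(rep_calls)
            pileups[sample].append(pile)
            rep_calls.to_csv(
                os.path.join(outdir, f"calls_{sample}_rep{rep}.tsv"),
                sep="\t", index=False,
            )
        cons = calling.replicate_consensus(calls[sample], config.n_replicates)
        consensus[sample] = cons
        cons.to_csv(os.path.join(outdir, f"consensus_{sample}.tsv"),
                    sep="\t", index=False)
        expression[sample] = comparison.estimate_expression(
            synthetic_data.simulate_expression_counts(st, sample)
        )
        summary["samples"][sample] = {"consensus_sites": int(len(cons))}

    # structure filter on each sample's consensus sites
    fold_cfg = structure_filter.FoldConfig()
    retained: dict[str, list[GenomicSite]] = {}
    for sample in samples:
        sites = [_site_from_row(r) for r in consensus[sample].itertuples()]
        anns = structure_filter.annotate_structures(
            sites, st.models, genome, fold_cfg, engine=engine
        )
        kept, discards = structure_filter.filter_paired_candidates(sites, anns)
        retained[sample] = kept
        write_sites(kept, os.path.join(outdir, f"retained_{sample}.bed"),
                    os.path.join(outdir, f"retained_{sample}.tsv"))
        structure_filter.write_discard_log(
            discards, os.path.join(outdir, f"discarded_{sample}.tsv")
        )
        summary["samples"][sample]["retained_sites"] = len(kept)
        summary["samples"][sample]["structure_discarded"] = len(discards)

    # unique/common classification + decomposition, both directions
    site_gene = {}
    for m in st.models:
        for tpos, base in enumerate(tseqs[m.transcript_id]):
            if base == "C":
                gpos = m.transcript_to_genomic(tpos)
                site_gene[(m.chrom, gpos, m.strand)] = m.gene_id
    for a, b in (samples, samples[::-1]):
        cmp_df = comparison.compare_samples(
            consensus[a], calls[b], pileups[b], expression[b], site_gene,
            label_unique=f"unique_{a}",
        )
        cmp_df.to_csv(os.path.join(outdir, f"comparison_{a}_vs_{b}.tsv"),
                      sep="\t", index=False)
        summary["samples"][a]["unique"] = int((cmp_df["status"] == f"unique_{a}").sum())
        summary["samples"][a]["common"] = int((cmp_df["status"] == "common").sum())

    # positional statistics on the retained sites of the first sample
    focal = samples[0]
    assignments = [positional.assign_segment(s, st.models) for s in retained[focal]]
    seg_counts = {f: 0 for f in positional.FEATURES}
    for asn in assignments:
        seg_counts[asn.feature] += 1
    mrna = [a for a in assignments if a.feature in ("utr5", "cds", "utr3")]
    if mrna:
        profile = positional.metagene_profile(mrna, st.models)
        pd.DataFrame(
            {"bin": range(100), "percent": profile.percent, "count": profile.counts}
        ).to_csv(os.path.join(outdir, "metagene.tsv"), sep="\t", index=False)
        tids = sorted({a.transcript_id for a in mrna})
        carrier = [m for m in st.models if m.transcript_id in tids]
        m5c = [a.site for a in mrna]
        rows = []
        for res in positional.enrichment_table(m5c, carrier, genome):
            rows.append(
                {"region": res.region, "p_value": res.p_value,
                 "odds_ratio": res.odds_ratio, "ci_low": res.ci95[0],
                 "ci_high": res.ci95[1], "n_m5c": res.n_m5c}
            )
        pd.DataFrame(rows).to_csv(os.path.join(outdir, "enrichment.tsv"),
                                  sep="\t", index=False)
    summary["segment_counts"] = seg_counts

    # overlap statistics (miRNA targets + RBP tracks) for the focal sample
    all_truth = sorted(
        {s for sites in truths.values() for s in sites},
        key=lambda s: (s.chrom, s.pos, s.strand),
    )
    tracks = synthetic_data.generate_feature_tracks(st, all_truth)
    mirna = overlap.filter_mirna_track(tracks["miRNA_targets"])
    utr3_sites = [a.site for a in assignments if a.feature == "utr3"]
    utr3_tids = sorted({a.transcript_id for a in assignments if a.feature == "utr3"})
    utr3_models = [m for m in st.models if m.transcript_id in utr3_tids]
    perm_rows = []
    if utr3_sites and utr3_models:
        background = [
            s for s in positional.all_transcript_cs(utr3_models, genome)
            if _in_segment(st, s, "utr3")
        ]
        if len(background) >= len(utr3_sites):
            res = overlap.overlap_permutation_test(
                utr3_sites, mirna, background, iterations=iterations, seed=seed
            )
            perm_rows.append(_perm_row(res))
    expressed = [
        m for m in st.models if expression[focal].expressed(m.gene_id)
    ]
    rbp_background = positional.all_transcript_cs(expressed, genome) if expressed else []
    combined = overlap.FeatureTrack(
        "RBP_combined",
        [iv for name, tr in sorted(tracks.items()) if name.startswith("RBP")
         for iv in tr.intervals],
    )
    rbp = overlap.prepare_rbp_sites(combined)
    focal_sites = retained[focal]
    if focal_sites and len(rbp_background) >= len(focal_sites):
        res = overlap.overlap_permutation_test(
            focal_sites, rbp, rbp_background, iterations=iterations, seed=seed + 1
        )
        perm_rows.append(_perm_row(res))
    pd.DataFrame(
        perm_rows,
        columns=["track", "observed", "null_mean", "null_sd", "z_score",
                 "p_low", "p_high", "iterations"],
    ).to_csv(os.path.join(outdir, "permutation.tsv"), sep="\t", index=False)

    # m6A motif scan + codon-proximal distributions
    hits = overlap.scan_m6a_motif(tseqs)
    with open(os.path.join(outdir, "m6a_hits.bed"), "w") as fh:
        for h in hits:
            model = st.model(h.transcript_id)
            gpos = model.transcript_to_genomic(h.position)
            fh.write(f"{model.chrom}\t{gpos}\t{gpos + 1}\t{h.matched}\t0\t{model.strand}\n")
    m5c_t = []
    for asn in mrna:
        model = st.model(asn.transcript_id)
        m5c_t.append((asn.transcript_id, model.genomic_to_transcript(asn.site.pos)))
    m6a_t = [(h.transcript_id, h.position) for h in hits]
    for anchor in ("AUG", "STOP"):
        dist, _ = overlap.codon_proximal_distribution(m5c_t, m6a_t, st.models, anchor)
        dist.to_csv(os.path.join(outdir, f"codon_distribution_{anchor}.tsv"),
                    sep="\t", index=False)

    with open(os.path.join(outdir, "summary.json"), "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return summary


def _in_segment(st, site: GenomicSite, segment: str) -> bool:
    model = st.model(site.transcript_id)
    segs = model.segments()
    if segs is None:
        return False
    a, b = segs[segment]
    return a <= site.transcript_pos < b


def _perm_row(res) -> dict:
    return {
        "track": res.track,
        "observed": res.observed_overlap,
        "null_mean": res.null_mean,
        "null_sd": res.null_sd,
        "z_score": "NA" if res.z_score is None else res.z_score,
        "p_low": res.p_low,
        "p_high": res.p_high,
        "iterations": res.iterations,
    }
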