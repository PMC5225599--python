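"""Cross-sample comparison: expression estimation, unique/common
classification of consensus sites, and decomposition of uniquely
methylated sites by their evidence in the other sample.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .calling import SITE_KEY

EXPRESSED_MIN_COUNT = 10.0  # expressed <=> mean normalized count > 10


class ComparisonError(ValueError):
    pass


# --------------------------------------------------------------------------
# Expression
# --------------------------------------------------------------------------

@dataclass
class ExpressionTable:
    counts: pd.DataFrame          # genes x replicates, raw exon-union counts
    size_factors: pd.Series       # per replicate
    normalized: pd.DataFrame      # counts / size factor
    mean_normalized: pd.Series    # per gene

    def expressed(self, gene_id: str) -> bool:
        return float(self.mean_normalized.get(gene_id, 0.0)) > EXPRESSED_MIN_COUNT


def estimate_expression(counts: pd.DataFrame) -> ExpressionTable:
    """Median-of-ratios normalization of an exon-union count table.

    Size factor per replicate = median over genes of count / geometric-mean,
    computed over genes with no zero count in any replicate.
    """
    if counts.shape[1] < 2:
        raise ComparisonError("need >= 2 replicates for expression estimation")
    if (counts.sum(axis=0) == 0).any():
        bad = counts.columns[counts.sum(axis=0) == 0].tolist()
        raise ComparisonError(f"replicate(s) with all-zero counts: {bad}")
    positive = (counts > 0).all(axis=1)
    if not positive.any():
        raise ComparisonError("no gene with positive counts in every replicate")
    log_geo = np.log(counts.loc[positive]).mean(axis=1)
    ratios = np.log(counts.loc[positive]).sub(log_geo, axis=0)
    size_factors = np.exp(ratios.median(axis=0))
    normalized = counts.div(size_factors, axis=1)
    return ExpressionTable(
        counts=counts,
        size_factors=size_factors,
        normalized=normalized,
        mean_normalized=normalized.mean(axis=1),
    )


# --------------------------------------------------------------------------
# Unique / common classification
# --------------------------------------------------------------------------

def _presence_counts(consensus: pd.DataFrame,
                     other_calls: list[pd.DataFrame]) -> pd.Series:
    """For each consensus site, in how many of the other sample's replicates
    it is present and passing."""
    count = pd.Series(0, index=pd.MultiIndex.from_frame(consensus[SITE_KEY]))
    for calls in other_calls:
        passed = calls.loc[calls["passed"], SITE_KEY]
        idx = pd.MultiIndex.from_frame(passed)
        count = count.add(pd.Series(1, index=idx), fill_value=0).reindex(count.index, fill_value=0)
    return count.astype(int)


def classify_unique_common(
    consensus_a: pd.DataFrame,
    calls_b: list[pd.DataFrame],
    label_unique: str = "unique_A",
) -> pd.DataFrame:
    """Classify each consensus site of sample A against sample B's replicates.

    unique: passing in 0 of B's replicates; common: passing in >= 1.
    Returns the consensus table with ``status`` and ``n_other_replicates``.
    """
    out = consensus_a.copy().reset_index(drop=True)
    if len(out) == 0:
        out["n_other_replicates"] = pd.Series(dtype=int)
        out["status"] = pd.Series(dtype=str)
        return out
    counts = _presence_counts(out, calls_b)
    out["n_other_replicates"] = counts.to_numpy()
    out["status"] = np.where(out["n_other_replicates"] == 0, label_unique, "common")
    return out


# --------------------------------------------------------------------------
# Decomposition of unique sites
# --------------------------------------------------------------------------

DECOMPOSITION_LABELS = (
    "not_expressed",
    "low_position_coverage",
    "biased_mean",
    "low_methylation_rate",
)


def decompose_unique_sites(
    unique_sites: pd.DataFrame,
    pileups_b: list[pd.DataFrame],
    expression_b: ExpressionTable | None,
    site_gene: dict[tuple[str, int, str], str] | None = None,
    min_cov: float = 10.0,
    min_rate: float = 0.2,
) -> pd.DataFrame:
    """Label each unique site of A by why it is absent from B.

    Precedence: not_expressed (gene mean normalized count <= 10 in B) ->
    low_position_coverage (mean site coverage < 10) -> biased_mean (mean
    rate >= 0.2 while the median replicate rate falls below it, i.e. the
    mean is skewed by an individual replicate) -> low_methylation_rate
    (mean rate < 0.2).  Sites missing from B's pileups count as coverage 0.
    Exactly one label per site.
    """
    piles = []
    for df in pileups_b:
        piles.append(df.set_index(SITE_KEY)[["n", "k"]])

    records = []
    for row in unique_sites.itertuples(index=False):
        key = (row.chrom, row.pos, row.strand)
        ns, rates = [], []
        for p in piles:
            if key in p.index:
                n = float(p.loc[key, "n"])
                k = float(p.loc[key, "k"])
            else:
                n, k = 0.0, 0.0
            ns.append(n)
            rates.append(k / n if n > 0 else 0.0)
        mean_cov = float(np.mean(ns)) if ns else 0.0
        mean_rate = float(np.mean(rates)) if rates else 0.0
        median_rate = float(np.median(rates)) if rates else 0.0

        gene = site_gene.get(key) if site_gene else None
        expressed = True
        if expression_b is not None and gene is not None:
            expressed = expression_b.expressed(gene)

        if not expressed:
            label = "not_expressed"
        elif mean_cov < min_cov:
            label = "low_position_coverage"
        elif mean_rate >= min_rate:
            label = "biased_mean"
        else:
            label = "low_methylation_rate"
        records.append(
            {
                "chrom": row.chrom,
                "pos": row.pos,
                "strand": row.strand,
                "other_mean_coverage": mean_cov,
                "other_mean_rate": mean_rate,
                "other_median_rate": median_rate,
                "decomposition": label,
            }
        )
    return pd.DataFrame.from_records(
        records,
        columns=SITE_KEY + ["other_mean_coverage", "other_mean_rate",
                            "other_median_rate", "decomposition"],
    )


def compare_samples(
    consensus_a: pd.DataFrame,
    calls_b: list[pd.DataFrame],
    pileups_b: list[pd.DataFrame],
    expression_b: ExpressionTable | None = None,
    site_gene: dict[tuple[str, int, str], str] | None = None,
    label_unique: str = "unique_A",
) -> pd.DataFrame:
    """Full A-vs-B comparison: status plus decomposition for unique sites."""
    classified = classify_unique_common(consensus_a, calls_b, label_unique)
    unique = classified[classified["status"] == label_unique]
    decomp = decompose_unique_sites(unique, pileups_b, expression_b, site_gene)
    if len(decomp):
        classified = classified.merge(decomp, on=SITE_KEY, how="left")
    else:
        classified["decomposition"] = pd.NA
    return classified
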