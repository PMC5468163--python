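"""Divergence-vs-introgression synthesis.

Four comparative layers connect the between-parental differentiation
scan to the admixed-population cline fit:

* Pearson correlations of |alpha| (cline center, absolute value) with
  F_ST, d_xy, |delta_pi| and the Mahalanobis distance, genomewide and on
  F_ST-thresholded subsets.
* Overlap of outlier-linked gene sets against a resampling null built
  from the background of all genes linked to analysed loci.
* Candidate-gene-set enrichment by Fisher's exact test (one-sided
  enrichment by default; every use case is an enrichment claim).
* The exact binomial symmetry test on east- vs west-ancestry outlier
  counts.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import binomtest, fisher_exact, pearsonr

from .data_io import CandidateGeneSet, ValidationError

logger = logging.getLogger("hybridzone")


@dataclass
class OverlapResult:
    """Observed gene overlap against its resampling null distribution."""

    observed_overlap: int
    null_overlaps: np.ndarray
    p_value: float
    n_resamples: int

    @property
    def significant(self) -> bool:
        """The overlap rule: observed exceeds the null's 95th quantile."""
        return self.observed_overlap > float(np.quantile(self.null_overlaps, 0.95))


@dataclass
class EnrichmentResult:
    set_name: str
    table: tuple[tuple[int, int], tuple[int, int]]  # (cand, not-cand) x (outlier, not)
    odds_ratio: float
    fisher_p: float


def correlate_divergence_introgression(
    stats: pd.DataFrame,
    fit,
    md: pd.Series | np.ndarray,
    fst_thresholds: Sequence[float] = (),
) -> pd.DataFrame:
    """Pearson correlations of |alpha| with each divergence statistic.

    Pairs: |alpha| vs fst, dxy, |delta_pi|, md — using absolute values of
    delta_pi and alpha (sign carries direction, not strength).  Optional
    ``fst_thresholds`` add subset rows restricted to loci with
    ``fst > t``.  Rows with any missing value are dropped pairwise; a
    pair with fewer than 3 complete observations reports NaN.
    """
    merged = stats.merge(
        fit.loci[["locus_id", "alpha_median"]], on="locus_id", how="inner"
    )
    md_arr = np.asarray(md, dtype=float)
    if len(md_arr) == len(stats):
        md_map = pd.Series(md_arr, index=stats["locus_id"].to_numpy())
        merged["md"] = md_map.reindex(merged["locus_id"]).to_numpy()
    else:
        raise ValidationError("md vector length must match the stats table")
    merged["abs_alpha"] = merged["alpha_median"].abs()
    merged["abs_delta_pi"] = merged["delta_pi"].abs()

    targets = [("fst", "fst"), ("dxy", "dxy"), ("abs_delta_pi", "|delta_pi|"), ("md", "md")]
    rows = []

    def corr_rows(df: pd.DataFrame, suffix: str):
        for col, label in targets:
            sub = df[["abs_alpha", col]].dropna()
            if len(sub) < 3 or sub[col].nunique() < 2 or sub["abs_alpha"].nunique() < 2:
                rows.append((f"|alpha| vs {label}{suffix}", np.nan, np.nan, len(sub)))
                continue
            r, p = pearsonr(sub["abs_alpha"], sub[col])
            rows.append((f"|alpha| vs {label}{suffix}", float(r), float(p), len(sub)))

    corr_rows(merged, "")
    for t in fst_thresholds:
        corr_rows(merged[merged["fst"] > t], f" [fst>{t:g}]")
    return pd.DataFrame(rows, columns=["pair", "r", "p", "n"])


def overlap_resampling_test(
    genes_a: set[str],
    genes_b: set[str],
    background: set[str],
    n_resamples: int = 1000,
    seed: int = 0,
) -> OverlapResult:
    """Observed overlap of two gene sets vs uniform resampling from background.

    Each resample draws |genes_a| and |genes_b| genes uniformly without
    replacement from the background and counts the intersection.  The
    p-value uses the +1 correction ``(1 + #{null >= obs}) / (n + 1)`` and
    never returns 0; ``significant`` applies the 95th-quantile rule.
    """
    if not genes_a <= background or not genes_b <= background:
        raise ValidationError("gene sets must be subsets of the background")
    bg = np.array(sorted(background))
    if max(len(genes_a), len(genes_b)) > len(bg):
        raise ValidationError("set larger than background")
    rng = np.random.default_rng(seed)
    observed = len(genes_a & genes_b)
    null = np.empty(n_resamples, dtype=np.int64)
    for i in range(n_resamples):
        a = rng.choice(len(bg), size=len(genes_a), replace=False)
        b = rng.choice(len(bg), size=len(genes_b), replace=False)
        null[i] = len(np.intersect1d(a, b))
    p = (1 + int((null >= observed).sum())) / (n_resamples + 1)
    return OverlapResult(
        observed_overlap=observed, null_overlaps=null, p_value=p, n_resamples=n_resamples
    )


def candidate_enrichment_test(
    outlier_genes: set[str],
    candidate: CandidateGeneSet,
    background: set[str],
    alternative: str = "greater",
) -> EnrichmentResult | None:
    """Fisher's exact test for candidate-set enrichment among outlier genes.

    The 2x2 table partitions the background by candidate membership and
    outlier linkage; the p-value is the exact hypergeometric tail
    (one-sided enrichment by default, ``alternative="two-sided"``
    available).  The sample odds ratio gets a 0.5 continuity correction
    when any cell is zero.  An empty candidate set yields None with a
    warning.
    """
    if not candidate.genes:
        warnings.warn(f"candidate set {candidate.name!r} is empty; skipping")
        return None
    if not candidate.genes <= background or not outlier_genes <= background:
        raise ValidationError("candidate and outlier genes must be subsets of the background")
    a = len(candidate.genes & outlier_genes)
    b = len(candidate.genes) - a
    c = len(outlier_genes) - a
    d = len(background) - a - b - c
    table = ((a, b), (c, d))
    _, p = fisher_exact([[a, b], [c, d]], alternative=alternative)
    if min(a, b, c, d) == 0:
        oa, ob, oc, od = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    else:
        oa, ob, oc, od = a, b, c, d
    odds = (oa * od) / (ob * oc)
    return EnrichmentResult(
        set_name=candidate.name, table=table, odds_ratio=float(odds), fisher_p=float(p)
    )


def ancestry_symmetry_test(count_east: int, count_west: int) -> float:
    """Two-sided exact binomial test of east vs west outlier counts.

    Tests ``count_east`` successes in ``count_east + count_west`` trials
    against proportion 0.5, two-sided by summing outcome probabilities no
    larger than the observed one.  Symmetric in its arguments.
    """
    if count_east < 0 or count_west < 0 or count_east + count_west == 0:
        raise ValueError("counts must be >= 0 and not both zero")
    return float(binomtest(count_east, count_east + count_west, 0.5).pvalue)
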