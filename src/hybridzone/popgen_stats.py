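"""Per-SNP diversity and differentiation statistics.

Three measures summarise each biallelic SNP between the two parental
populations:

* **pi** — Nei & Li per-site nucleotide diversity within a population,
  estimated without bias as ``2 p (1-p) n/(n-1)`` from ``n`` sampled
  alleles at frequency ``p`` (the mean pairwise difference over all
  allele pairs).
* **delta_pi** — ``pi_east - pi_west``: positive where the eastern
  population is the more diverse.
* **F_ST** — Weir & Cockerham's variance-components estimator (theta-hat)
  in its allele-count (haploid-sample) form, clamped to [0, 1]; negative
  estimates denote panmixia and are converted to zero.
* **d_xy** — absolute differentiation: the probability two alleles drawn
  one from each population differ, ``p_w (1-p_e) + p_e (1-p_w)``.

All statistics use non-missing alleles only; admixed samples never enter
these between-parental comparisons.

The allele-count form of Weir & Cockerham is an ANOVA on allele
indicators with populations as groups; it may differ from genotype-aware
implementations (which model within-individual correlation) in the third
decimal.  This is the one deliberate numerical deviation of the module.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .data_io import MISSING, GenotypeMatrix, PopulationMap, ValidationError

logger = logging.getLogger("hybridzone")

__all__ = ["site_pi", "wc_fst", "site_dxy", "compute_locus_stats"]


def site_pi(ref_count: float, n: float) -> float:
    """Unbiased per-site nucleotide diversity from ``n`` sampled alleles.

    Returns ``2 p (1-p) * n/(n-1)`` with ``p = ref_count/n``; equal to the
    average pairwise difference over all n(n-1)/2 allele pairs.  Undefined
    (NaN) for fewer than 2 alleles.
    """
    if n < 2:
        return float("nan")
    if not 0 <= ref_count <= n:
        raise ValueError(f"ref_count {ref_count} outside [0, {n}]")
    p = ref_count / n
    return 2.0 * p * (1.0 - p) * n / (n - 1.0)


def wc_fst(count_w: float, n_w: float, count_e: float, n_e: float) -> float:
    """Weir & Cockerham theta-hat for two populations from allele counts.

    ANOVA on the 0/1 allele indicator with populations as groups: the
    among-population variance component ``a`` over ``a + b`` where ``b``
    is the within-population component.  Clamped to [0, 1]; exactly 1 for
    reciprocal fixation and 0 for a site monomorphic overall.  NaN when
    either population has fewer than 2 non-missing alleles.
    """
    if n_w < 2 or n_e < 2:
        return float("nan")
    r = 2
    N = n_w + n_e
    p_w = count_w / n_w
    p_e = count_e / n_e
    pbar = (count_w + count_e) / N
    if pbar == 0.0 or pbar == 1.0:
        return 0.0
    # mean squares among (MSP) and within (MSG) populations
    msp = (n_w * (p_w - pbar) ** 2 + n_e * (p_e - pbar) ** 2) / (r - 1)
    msg = (n_w * p_w * (1 - p_w) + n_e * p_e * (1 - p_e)) / (N - r)
    n_c = (N - (n_w**2 + n_e**2) / N) / (r - 1)
    a = (msp - msg) / n_c
    b = msg
    denom = a + b
    if denom <= 0:
        return 0.0
    return float(min(max(a / denom, 0.0), 1.0))


def site_dxy(p_w: float, p_e: float) -> float:
    """Absolute per-site differentiation ``p_w (1-p_e) + p_e (1-p_w)``."""
    if not (0 <= p_w <= 1 and 0 <= p_e <= 1):
        raise ValueError("allele frequencies must lie in [0,1]")
    return p_w * (1.0 - p_e) + p_e * (1.0 - p_w)


def _allele_counts(gm: GenotypeMatrix, samples: list[str]) -> tuple[np.ndarray, np.ndarray]:
    """Per-locus (alt-allele count, non-missing allele total) for a sample set."""
    idx = [gm.sample_ids.index(s) for s in samples]
    G = gm.genotypes[idx, :]
    obs = G != MISSING
    alt = np.where(obs, G, 0).sum(axis=0).astype(float)
    n = (2 * obs.sum(axis=0)).astype(float)
    return alt, n


def compute_locus_stats(gm: GenotypeMatrix, pm: PopulationMap) -> pd.DataFrame:
    """One row of diversity/differentiation statistics per locus.

    Columns: locus_id, n_west, n_east (non-missing allele counts), p_west,
    p_east (alternate-allele frequencies), pi_west, pi_east, delta_pi,
    fst, dxy, missing_fraction.  Loci unusable in either parental
    population keep their row with NaN statistics (counted in the log);
    admixed samples contribute only to ``missing_fraction``.
    """
    west = pm.samples("west")
    east = pm.samples("east")
    for pop, ss in (("west", west), ("east", east)):
        present = [s for s in ss if s in gm.sample_ids]
        if len(present) < 2:
            raise ValidationError(f"parental population '{pop}' has <2 samples in matrix")
    west = [s for s in west if s in gm.sample_ids]
    east = [s for s in east if s in gm.sample_ids]

    alt_w, n_w = _allele_counts(gm, west)
    alt_e, n_e = _allele_counts(gm, east)

    with np.errstate(invalid="ignore", divide="ignore"):
        p_w = np.divide(alt_w, n_w, out=np.full_like(alt_w, np.nan), where=n_w > 0)
        p_e = np.divide(alt_e, n_e, out=np.full_like(alt_e, np.nan), where=n_e > 0)

    usable = (n_w >= 2) & (n_e >= 2)
    n_loci = gm.n_loci
    pi_w = np.full(n_loci, np.nan)
    pi_e = np.full(n_loci, np.nan)
    fst = np.full(n_loci, np.nan)
    dxy = np.full(n_loci, np.nan)
    for i in np.flatnonzero(usable):
        pi_w[i] = site_pi(alt_w[i], n_w[i])
        pi_e[i] = site_pi(alt_e[i], n_e[i])
        fst[i] = wc_fst(alt_w[i], n_w[i], alt_e[i], n_e[i])
        dxy[i] = site_dxy(p_w[i], p_e[i])

    n_bad = int((~usable).sum())
    if n_bad:
        logger.warning("%d locus/loci unusable in a parental population (NaN stats)", n_bad)

    missing_fraction = (gm.genotypes == MISSING).mean(axis=0)
    return pd.DataFrame(
        {
            "locus_id": gm.locus_ids,
            "n_west": n_w.astype(int),
            "n_east": n_e.astype(int),
            "p_west": p_w,
            "p_east": p_e,
            "pi_west": pi_w,
            "pi_east": pi_e,
            "delta_pi": pi_e - pi_w,
            "fst": fst,
            "dxy": dxy,
            "missing_fraction": missing_fraction,
        }
    )
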