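"""Posterior-predictive simulation of F_ST and d_xy under neutral divergence.

The null model is a two-population isolation coalescent in mutational
units: within population *i* each lineage pair coalesces at rate
``2/theta_i`` (theta = 4*N*mu per site, so time is measured in expected
substitutions per site); at time ``tau`` before the present all surviving
lineages enter the ancestral population and coalesce pairwise at rate
``2/theta_anc``.  Mutations fall on the genealogy as a Poisson process
with mean (total branch length x locus length); each hit lands on a
uniform site and substitutes the current base with one of the other three
uniformly (JC69, uniform root base), so recurrent and back mutation are
possible.  One polymorphic biallelic site per locus is sampled uniformly
and summarised with the same F_ST / d_xy operators applied to the
empirical SNP panel; loci without such a site are reported as skipped, so
the biallelic-SNP ascertainment of the empirical panel is mirrored and
visible.

Simulating at parameters drawn from a posterior sample (one batch of loci
per posterior row) propagates parameter uncertainty into the null, and
drawing per-locus allele-sample sizes from the empirical coverage
distributions propagates the unevenness of RAD coverage.  Comparing the
binned empirical and simulated distributions then asks which empirical
differentiation values a strict no-selection model can explain.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import fisher_exact

from .popgen_stats import site_dxy, wc_fst

logger = logging.getLogger("hybridzone")


@dataclass
class NeutralSimConfig:
    """Settings for the posterior-predictive run.

    loci_per_sample
        Independent loci simulated per posterior row (default 100).
    locus_length
        Sites per locus (default 190, a typical RAD-locus length).
    coverage_west / coverage_east
        Either a fixed number of sampled alleles per locus or a vector of
        empirical-like allele counts resampled per locus (coverage
        distribution mode).
    """

    loci_per_sample: int = 100
    locus_length: int = 190
    coverage_west: int | Sequence[int] = 40
    coverage_east: int | Sequence[int] = 40
    seed: int = 0

    def __post_init__(self) -> None:
        if self.loci_per_sample < 1 or self.locus_length < 1:
            raise ValueError("loci_per_sample and locus_length must be >= 1")


@dataclass
class NullDistribution:
    """Simulated null (fst, dxy) pairs with provenance and skip accounting."""

    fst: np.ndarray
    dxy: np.ndarray
    posterior_row: np.ndarray  # index of the posterior draw behind each value
    n_skipped: int
    n_total: int

    def __post_init__(self) -> None:
        for v in (self.fst, self.dxy):
            if len(v) and ((v < 0).any() or (v > 1).any()):
                raise ValueError("null fst/dxy values must lie in [0,1]")


@dataclass
class BinComparison:
    """Binned empirical-vs-null contrast with per-bin Fisher exact tests."""

    bin_edges: np.ndarray
    empirical_counts: np.ndarray
    simulated_counts: np.ndarray
    fisher_p: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "bin_lo": self.bin_edges[:-1],
                "bin_hi": self.bin_edges[1:],
                "empirical_count": self.empirical_counts,
                "simulated_count": self.simulated_counts,
                "fisher_p": self.fisher_p,
            }
        )


# ---------------------------------------------------------------------------
# genealogy + mutation machinery
# ---------------------------------------------------------------------------

def _simulate_genealogy(
    rng: np.random.Generator,
    theta_west: float,
    theta_east: float,
    theta_anc: float,
    tau: float,
    n_w: int,
    n_e: int,
):
    """Two-population isolation coalescent.

    Returns ``(parent, node_time, n_tips)`` where tips 0..n_w-1 are west,
    n_w..n_w+n_e-1 east, internal nodes follow in coalescence order, and
    ``parent[root] = -1``.  Time flows backwards from 0 at the tips.
    """
    n_tips = n_w + n_e
    if n_tips < 2:
        raise ValueError("need at least 2 sampled lineages in total")
    n_nodes = 2 * n_tips - 1
    parent = np.full(n_nodes, -1, dtype=np.int64)
    node_time = np.zeros(n_nodes)
    active_w = list(range(n_w))
    active_e = list(range(n_w, n_tips))
    for theta, act, label in ((theta_west, active_w, "west"), (theta_east, active_e, "east")):
        if theta == 0 and len(act) > 1:
            raise ValueError(f"theta_{label} = 0 with {len(act)} lineages: infinite rate")

    nxt = n_tips
    t = 0.0
    # phase 1: separate populations until tau
    while t < tau and (len(active_w) > 1 or len(active_e) > 1):
        kw, ke = len(active_w), len(active_e)
        rate_w = kw * (kw - 1) / theta_west if kw > 1 else 0.0
        rate_e = ke * (ke - 1) / theta_east if ke > 1 else 0.0
        total = rate_w + rate_e
        if total == 0.0:
            break
        dt = rng.exponential(1.0 / total)
        if t + dt >= tau:
            break
        t += dt
        act = active_w if rng.random() < rate_w / total else active_e
        i, j = rng.choice(len(act), size=2, replace=False)
        a, b = act[i], act[j]
        parent[a] = parent[b] = nxt
        node_time[nxt] = t
        act.remove(a)
        act.remove(b)
        act.append(nxt)
        nxt += 1

    # phase 2: ancestral population
    pool = active_w + active_e
    if len(pool) > 1:
        if theta_anc == 0:
            raise ValueError("theta_anc = 0 with >1 surviving lineage: infinite rate")
        t = max(t, tau)
        while len(pool) > 1:
            k = len(pool)
            t += rng.exponential(theta_anc / (k * (k - 1)))
            i, j = rng.choice(k, size=2, replace=False)
            a, b = pool[i], pool[j]
            parent[a] = parent[b] = nxt
            node_time[nxt] = t
            pool.remove(a)
            pool.remove(b)
            pool.append(nxt)
            nxt += 1
    return parent, node_time, n_tips


def _drop_mutations(rng, parent, node_time, L):
    """Poisson mutations on the genealogy; returns dict site -> [(node, time, u)].

    ``u`` in {0,1,2} indexes which of the three non-current bases the
    mutation substitutes (resolved during site evaluation).
    """
    n_nodes = len(parent)
    blen = np.zeros(n_nodes)
    has_parent = parent >= 0
    blen[has_parent] = node_time[parent[has_parent]] - node_time[has_parent]
    total_len = blen.sum()
    n_mut = rng.poisson(total_len * L)
    sites: dict[int, list] = {}
    if n_mut == 0:
        return sites
    nodes = rng.choice(n_nodes, size=n_mut, p=blen / total_len)
    site_idx = rng.integers(0, L, size=n_mut)
    u = rng.integers(0, 3, size=n_mut)
    frac = rng.random(n_mut)
    for m in range(n_mut):
        nd = int(nodes[m])
        t_m = node_time[nd] + frac[m] * blen[nd]
        sites.setdefault(int(site_idx[m]), []).append((nd, t_m, int(u[m])))
    return sites


def _tip_bases(rng, parent, node_time, n_tips, muts):
    """Resolve one site's bases at the tips given its mutations."""
    n_nodes = len(parent)
    by_node: dict[int, list] = {}
    for nd, t_m, u in muts:
        by_node.setdefault(nd, []).append((t_m, u))
    base = np.empty(n_nodes, dtype=np.int8)
    base[n_nodes - 1] = rng.integers(0, 4)  # uniform root base
    # nodes were created in increasing time order -> descend root-to-tips
    for nd in range(n_nodes - 2, -1, -1):
        b = base[parent[nd]]
        if nd in by_node:
            for _, u in sorted(by_node[nd], key=lambda x: -x[0]):  # oldest first
                b = (b + 1 + u) % 4  # u-th base among the three others
        base[nd] = b
    return base[:n_tips]


def simulate_neutral_locus(
    theta_west: float,
    theta_east: float,
    theta_anc: float,
    tau: float,
    n_w: int,
    n_e: int,
    L: int = 190,
    seed: int | np.random.Generator = 0,
) -> tuple[float, float] | None:
    """Simulate one neutral locus; return (fst, dxy) at one random SNP.

    ``n_w`` / ``n_e`` are sampled allele counts per population (>= 2 each).
    Returns ``None`` when the locus yields no polymorphic biallelic site
    (the locus is "skipped", mirroring SNP-panel ascertainment).
    """
    if min(theta_west, theta_east, theta_anc, tau) < 0:
        raise ValueError("theta and tau must be >= 0")
    if n_w < 2 or n_e < 2:
        raise ValueError("need >= 2 sampled alleles per population")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    counts = _simulate_site_counts(rng, theta_west, theta_east, theta_anc, tau, n_w, n_e, L)
    if counts is None:
        return None
    count_w, count_e = counts
    fst = wc_fst(count_w, n_w, count_e, n_e)
    dxy = site_dxy(count_w / n_w, count_e / n_e)
    return float(fst), float(dxy)


def _simulate_site_counts(rng, theta_west, theta_east, theta_anc, tau, n_w, n_e, L):
    """Allele counts (count_w, count_e) of one allele at one random SNP, or None."""
    parent, node_time, n_tips = _simulate_genealogy(
        rng, theta_west, theta_east, theta_anc, tau, n_w, n_e
    )
    sites = _drop_mutations(rng, parent, node_time, L)
    candidates = []
    for s in sorted(sites):
        bases = _tip_bases(rng, parent, node_time, n_tips, sites[s])
        alleles = np.unique(bases)
        if len(alleles) == 2:
            candidates.append((bases, alleles))
    if not candidates:
        return None
    bases, alleles = candidates[int(rng.integers(len(candidates)))]
    ref = alleles[0]
    return int((bases[:n_w] == ref).sum()), int((bases[n_w:] == ref).sum())


def _draw_coverage(rng, cov) -> int:
    if np.isscalar(cov):
        return int(cov)
    cov = np.asarray(cov)
    return int(cov[rng.integers(len(cov))])


def build_null_distribution(posterior, cfg: NeutralSimConfig) -> NullDistribution:
    """Simulate ``cfg.loci_per_sample`` loci per posterior row.

    Per-locus allele-sample sizes are drawn from the configured coverage
    distributions.  Polymorphic loci contribute one (fst, dxy) pair tagged
    with its posterior row; monomorphic / non-biallelic loci are counted
    as skipped.
    """
    if len(posterior) < 1:
        raise ValueError("posterior sample set is empty")
    rng = np.random.default_rng(cfg.seed)
    fst_vals, dxy_vals, rows = [], [], []
    n_skipped = 0
    params = posterior.samples[["theta_west", "theta_east", "theta_anc", "tau"]].to_numpy()
    for r, (tw, te, ta, tau) in enumerate(params):
        for _ in range(cfg.loci_per_sample):
            n_w = _draw_coverage(rng, cfg.coverage_west)
            n_e = _draw_coverage(rng, cfg.coverage_east)
            res = simulate_neutral_locus(tw, te, ta, tau, n_w, n_e, cfg.locus_length, rng)
            if res is None:
                n_skipped += 1
            else:
                fst_vals.append(res[0])
                dxy_vals.append(res[1])
                rows.append(r)
    n_total = len(posterior) * cfg.loci_per_sample
    logger.info(
        "null distribution: %d contributed, %d skipped of %d simulated loci",
        len(fst_vals), n_skipped, n_total,
    )
    return NullDistribution(
        fst=np.asarray(fst_vals),
        dxy=np.asarray(dxy_vals),
        posterior_row=np.asarray(rows, dtype=np.int64),
        n_skipped=n_skipped,
        n_total=n_total,
    )


def compare_binned(
    empirical: np.ndarray,
    null: NullDistribution | np.ndarray,
    bin_width: float = 0.1,
    statistic: str = "fst",
) -> BinComparison:
    """Bin empirical vs simulated values on [0,1] and Fisher-test each bin.

    Bins are [0,0.1), ..., [0.9,1.0] (last bin closed).  Each bin is a
    two-sided Fisher exact test on the 2x2 table (in-bin vs out-of-bin) x
    (empirical vs simulated); a bin empty in both is recorded with p = 1.
    No multiple-testing correction is applied across bins.
    """
    emp = np.asarray(empirical, dtype=float)
    emp = emp[np.isfinite(emp)]
    sim = getattr(null, statistic) if isinstance(null, NullDistribution) else np.asarray(null)
    if len(emp) == 0 or len(sim) == 0:
        raise ValueError("both empirical and simulated vectors must be non-empty")
    n_bins = int(round(1.0 / bin_width))
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    emp_counts, _ = np.histogram(emp, bins=edges)
    sim_counts, _ = np.histogram(sim, bins=edges)
    ps = np.ones(n_bins)
    for b in range(n_bins):
        a, c = int(emp_counts[b]), int(sim_counts[b])
        if a == 0 and c == 0:
            continue
        table = [[a, len(emp) - a], [c, len(sim) - c]]
        ps[b] = fisher_exact(table, alternative="two-sided")[1]
    return BinComparison(
        bin_edges=edges,
        empirical_counts=emp_counts,
        simulated_counts=sim_counts,
        fisher_p=ps,
    )


def estimate_false_positive_rate(
    empirical: np.ndarray,
    null: NullDistribution | np.ndarray,
    range_lo: float,
    range_hi: float,
    statistic: str = "fst",
) -> float:
    """Expected neutral loci per observed locus in (range_lo, range_hi].

    The ratio of simulated to empirical mass in the range, capped at 1.
    NaN when the empirical panel has no mass there.
    """
    if not (0 <= range_lo < range_hi <= 1):
        raise ValueError("need 0 <= range_lo < range_hi <= 1")
    emp = np.asarray(empirical, dtype=float)
    emp = emp[np.isfinite(emp)]
    sim = getattr(null, statistic) if isinstance(null, NullDistribution) else np.asarray(null)
    emp_frac = ((emp > range_lo) & (emp <= range_hi)).mean()
    if emp_frac == 0:
        return float("nan")
    sim_frac = ((sim > range_lo) & (sim <= range_hi)).mean()
    return float(min(1.0, sim_frac / emp_frac))
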