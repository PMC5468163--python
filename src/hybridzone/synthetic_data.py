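"""Synthetic datasets with known truth for every pipeline stage.

The generators state a world and keep it fixed:

* Parental populations diverge under the same two-population isolation
  coalescent the posterior-predictive null uses, at the default
  parameters ``theta_west = 0.0592, theta_east = 0.217, theta_anc =
  0.0615, tau = 0.00578`` (posterior means of a SNAPP-style fit to the
  empirical system).  A configurable fraction of loci is planted as
  "divergent" by symmetrically pushing the two parental frequencies
  toward fixation.
* The admixed population is the generative inverse of the genomic-cline
  model: each gene copy is eastern with probability
  ``Phi = cline_function(h, alpha_true, beta_true)`` and the allele is
  then drawn from that parent's true frequency.
* The null admixed population redraws parental alleles at random
  (uniform 50/50 population choice per gene copy), the benchmark for
  neutral introgression; defaults n = 21 individuals, 5 replicates.
* Gene annotations link every locus to one upstream and one downstream
  gene; designated candidate sets over-sample genes linked to divergent
  loci by a configurable enrichment factor.

True parental allele frequencies come from a finite "frequency panel" of
60 coalescent alleles per population, so truth frequencies are
themselves draws from the isolation model rather than arbitrary numbers;
loci are redrawn until polymorphic, mirroring SNP-panel ascertainment.
All generators are deterministic given their seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .data_io import GenotypeMatrix, PopulationMap, PosteriorSampleSet
from .genomic_clines import cline_function
from .neutral_ppsim import _drop_mutations, _simulate_genealogy, _tip_bases

logger = logging.getLogger("hybridzone")

# posterior-mean defaults for the stated world
DEFAULT_THETA_WEST = 0.0592
DEFAULT_THETA_EAST = 0.217
DEFAULT_THETA_ANC = 0.0615
DEFAULT_TAU = 0.00578

FREQ_PANEL_ALLELES = 60  # coalescent alleles per population behind "true" frequencies
_LOCUS_LENGTH = 190

DEFAULT_CANDIDATE_SPECS: tuple[tuple[str, int, bool], ...] = (
    ("venom", 50, True),
    ("reproduction", 50, True),
    ("coloration", 50, False),
    ("nuc-mt", 50, False),
    ("nuc-oxphos", 50, False),
)


@dataclass
class SimTruth:
    """Ground truth behind a synthetic dataset.

    ``loci``: per-locus true parental allele frequencies, planted cline
    parameters (alpha_true, beta_true) and selection label
    ('neutral'/'divergent').  ``h_true``: per-admixed-individual hybrid
    index (filled by :func:`simulate_admixed`).  ``enriched_sets`` names
    the candidate sets with planted enrichment.
    """

    loci: pd.DataFrame
    locus_meta: pd.DataFrame
    seed: int
    h_true: pd.DataFrame | None = None
    enriched_sets: list[str] = field(default_factory=list)


def _coalescent_site_freqs(rng, theta_w, theta_e, theta_anc, tau, m_w, m_e, max_tries=500):
    """True (p_west, p_east) at one polymorphic biallelic coalescent site."""
    for _ in range(max_tries):
        parent, node_time, n_tips = _simulate_genealogy(
            rng, theta_w, theta_e, theta_anc, tau, m_w, m_e
        )
        sites = _drop_mutations(rng, parent, node_time, _LOCUS_LENGTH)
        candidates = []
        for s in sorted(sites):
            bases = _tip_bases(rng, parent, node_time, n_tips, sites[s])
            alleles = np.unique(bases)
            if len(alleles) == 2:
                candidates.append((bases, alleles))
        if candidates:
            bases, alleles = candidates[int(rng.integers(len(candidates)))]
            ref = alleles[int(rng.integers(2))]  # random allele orientation
            return float((bases[:m_w] == ref).mean()), float((bases[m_w:] == ref).mean())
    raise RuntimeError("no polymorphic site in max_tries coalescent draws; theta too small?")


def _boost_apart(p_w: float, p_e: float, boost: float) -> tuple[float, float]:
    """Push the two frequencies toward opposite fixation boundaries.

    The lower frequency moves a fraction ``boost`` of its remaining
    distance to 0, the higher the same fraction toward 1; monotone in
    ``boost``, with ``boost = 1`` giving reciprocal fixation.  Scaling by
    the distance to the boundary (rather than by ``min(p, 1-p)``) keeps
    planted divergence detectable even at shared-rare-allele loci, which
    dominate the isolation-model frequency spectrum.
    """
    if p_w <= p_e:
        return float(p_w * (1.0 - boost)), float(p_e + boost * (1.0 - p_e))
    pe, pw = _boost_apart(p_e, p_w, boost)
    return pw, pe


def simulate_divergent_parentals(
    n_loci: int,
    n_west: int = 24,
    n_east: int = 24,
    theta_west: float = DEFAULT_THETA_WEST,
    theta_east: float = DEFAULT_THETA_EAST,
    theta_anc: float = DEFAULT_THETA_ANC,
    tau: float = DEFAULT_TAU,
    divergent_fraction: float = 0.05,
    divergence_boost: float = 0.5,
    seed: int = 0,
) -> tuple[GenotypeMatrix, PopulationMap, SimTruth]:
    """Two parental populations with a planted fraction of divergent loci.

    Neutral loci take their true frequencies straight from the isolation
    coalescent; divergent loci additionally have their parental
    frequencies pushed apart by ``divergence_boost`` (``p -/+ boost *
    min(p, 1-p)``, clipped).  Diploid genotypes are binomial draws of two
    alleles per individual.
    """
    if n_west < 1 or n_east < 1:
        raise ValueError("need at least one individual per parental population")
    if not 0 <= divergent_fraction <= 1:
        raise ValueError("divergent_fraction must lie in [0,1]")
    rng = np.random.default_rng(seed)

    n_div = int(round(divergent_fraction * n_loci))
    div_idx = set(rng.choice(n_loci, size=n_div, replace=False).tolist()) if n_div else set()

    rows = []
    locus_ids, meta_rows = [], []
    G = np.empty((n_west + n_east, n_loci), dtype=np.int8)
    for i in range(n_loci):
        p_w, p_e = _coalescent_site_freqs(
            rng, theta_west, theta_east, theta_anc, tau, FREQ_PANEL_ALLELES, FREQ_PANEL_ALLELES
        )
        label = "divergent" if i in div_idx else "neutral"
        if label == "divergent":
            p_w, p_e = _boost_apart(p_w, p_e, divergence_boost)
        G[:n_west, i] = rng.binomial(2, p_w, size=n_west)
        G[n_west:, i] = rng.binomial(2, p_e, size=n_east)
        lid = f"contig{i:05d}:{int(rng.integers(1, _LOCUS_LENGTH + 1))}"
        locus_ids.append(lid)
        meta_rows.append((f"contig{i:05d}", int(lid.split(":")[1]), "A", "T"))
        rows.append((lid, p_w, p_e, 0.0, 0.0, label))

    sample_ids = [f"west_{j:03d}" for j in range(n_west)] + [
        f"east_{j:03d}" for j in range(n_east)
    ]
    meta = pd.DataFrame(meta_rows, columns=["chrom", "pos", "ref", "alt"], index=locus_ids)
    gm = GenotypeMatrix(sample_ids=sample_ids, locus_ids=locus_ids, genotypes=G, locus_meta=meta)
    pm = PopulationMap(
        {s: ("west" if s.startswith("west") else "east") for s in sample_ids}
    )
    truth = SimTruth(
        loci=pd.DataFrame(
            rows, columns=["locus_id", "p_west", "p_east", "alpha_true", "beta_true", "selection"]
        ),
        locus_meta=meta,
        seed=seed,
    )
    logger.info("simulated %d+%d parentals at %d loci (%d divergent)", n_west, n_east, n_loci, n_div)
    return gm, pm, truth


def default_h_grid(n_admixed: int) -> np.ndarray:
    """Uniform grid of hybrid indices on [0.2, 0.8] (a broadly admixed zone)."""
    return np.linspace(0.2, 0.8, n_admixed)


def simulate_admixed(
    truth: SimTruth,
    n_admixed: int = 21,
    h_values: Sequence[float] | None = None,
    seed: int = 0,
) -> GenotypeMatrix:
    """Admixed individuals as the generative inverse of the cline model.

    For individual j at locus i each of the two gene copies is eastern
    with probability ``Phi_ij = cline_function(h_j, alpha_true_i,
    beta_true_i)``; the allele is then drawn from that parent's true
    frequency.  ``h_values`` defaults to a uniform grid on [0.2, 0.8].
    Records ``h_true`` on the truth object.
    """
    rng = np.random.default_rng(seed)
    h = np.asarray(h_values if h_values is not None else default_h_grid(n_admixed), dtype=float)
    if len(h) != n_admixed:
        raise ValueError("h_values must have length n_admixed")
    if (h < 0).any() or (h > 1).any():
        raise ValueError("h_values must lie in [0,1]")

    loci = truth.loci
    alpha = loci["alpha_true"].to_numpy()
    beta = loci["beta_true"].to_numpy()
    p_w = loci["p_west"].to_numpy()
    p_e = loci["p_east"].to_numpy()
    phi = cline_function(h[:, None], alpha[None, :], beta[None, :])

    n_loci = len(loci)
    G = np.zeros((n_admixed, n_loci), dtype=np.int8)
    for _copy in range(2):
        east = rng.random((n_admixed, n_loci)) < phi
        p = np.where(east, p_e[None, :], p_w[None, :])
        G += (rng.random((n_admixed, n_loci)) < p).astype(np.int8)

    sample_ids = [f"adm_{j:03d}" for j in range(n_admixed)]
    truth.h_true = pd.DataFrame({"sample": sample_ids, "h_true": h})
    return GenotypeMatrix(
        sample_ids=sample_ids,
        locus_ids=list(loci["locus_id"]),
        genotypes=G,
        locus_meta=truth.locus_meta.copy(),
    )


def simulate_null_admixed(
    parental_gm: GenotypeMatrix,
    pm: PopulationMap,
    n_admixed: int = 21,
    n_replicates: int = 5,
    seed: int = 0,
) -> list[GenotypeMatrix]:
    """Null admixed populations by random draws of observed parental alleles.

    Per replicate, individual, locus and gene copy: choose a parental
    population uniformly at random, then sample one observed non-missing
    allele from that population at that locus.  This is the benchmark for
    neutral introgression (no cline structure beyond a ~0.5 hybrid
    index).  A locus with no data in either parental population is an
    error naming the locus.
    """
    from .popgen_stats import _allele_counts

    rng = np.random.default_rng(seed)
    west = [s for s in pm.samples("west") if s in parental_gm.sample_ids]
    east = [s for s in pm.samples("east") if s in parental_gm.sample_ids]
    k_w, n_w = _allele_counts(parental_gm, west)
    k_e, n_e = _allele_counts(parental_gm, east)
    for pop, n in (("west", n_w), ("east", n_e)):
        empty = np.flatnonzero(n == 0)
        if len(empty):
            raise ValueError(
                f"locus {parental_gm.locus_ids[empty[0]]!r} has all-missing {pop} parental data"
            )
    f_w = k_w / n_w
    f_e = k_e / n_e

    n_loci = parental_gm.n_loci
    out = []
    for rep in range(n_replicates):
        G = np.zeros((n_admixed, n_loci), dtype=np.int8)
        for _copy in range(2):
            from_east = rng.random((n_admixed, n_loci)) < 0.5
            p = np.where(from_east, f_e[None, :], f_w[None, :])
            G += (rng.random((n_admixed, n_loci)) < p).astype(np.int8)
        out.append(
            GenotypeMatrix(
                sample_ids=[f"null{rep}_{j:03d}" for j in range(n_admixed)],
                locus_ids=list(parental_gm.locus_ids),
                genotypes=G,
                locus_meta=parental_gm.locus_meta.copy(),
            )
        )
    return out


def make_pseudo_posterior(
    theta_west: float = DEFAULT_THETA_WEST,
    theta_east: float = DEFAULT_THETA_EAST,
    theta_anc: float = DEFAULT_THETA_ANC,
    tau: float = DEFAULT_TAU,
    n_rows: int = 375,
    jitter_cv: float = 0.1,
    seed: int = 0,
) -> PosteriorSampleSet:
    """Stand-in posterior: independent log-normal jitter around the means.

    Each column is log-normal with mean equal to the supplied value and
    coefficient of variation ``jitter_cv`` (0 gives identical rows); 375
    rows mirror a thinned post-burn-in MCMC sample.
    """
    if jitter_cv < 0:
        raise ValueError("jitter_cv must be >= 0")
    rng = np.random.default_rng(seed)
    cols = {}
    for name, m in (
        ("theta_west", theta_west),
        ("theta_east", theta_east),
        ("theta_anc", theta_anc),
        ("tau", tau),
    ):
        if jitter_cv == 0 or m == 0:
            cols[name] = np.full(n_rows, float(m))
        else:
            sigma2 = np.log1p(jitter_cv**2)
            mu = np.log(m) - sigma2 / 2.0
            cols[name] = rng.lognormal(mean=mu, sigma=np.sqrt(sigma2), size=n_rows)
    return PosteriorSampleSet(samples=pd.DataFrame(cols))


def generate_gene_annotations(
    truth: SimTruth,
    n_genes: int = 2000,
    candidate_specs: Sequence[tuple[str, int, bool]] = DEFAULT_CANDIDATE_SPECS,
    enrichment_factor: float = 1.0,
    seed: int = 0,
):
    """Synthetic locus->gene map with planted candidate-set enrichment.

    Every locus links to one upstream and one downstream gene drawn from
    a shared pool of ``n_genes``.  Candidate sets marked enriched sample
    genes linked to divergent-labelled loci with weight
    ``enrichment_factor`` (1 = uniform, independent of the labels).
    Returns ``(GeneLinkTable, [CandidateGeneSet], truth)`` with the
    planted set names recorded on the truth object.
    """
    from .data_io import CandidateGeneSet, GeneLinkTable

    rng = np.random.default_rng(seed)
    gene_pool = np.array([f"gene{i:05d}" for i in range(n_genes)])
    loci = truth.loci
    edge_rows = []
    linked_to_divergent: set[str] = set()
    for _, row in loci.iterrows():
        up, down = gene_pool[rng.choice(n_genes, size=2, replace=False)]
        evalue = float(10 ** -rng.uniform(5, 50))
        edge_rows.append((row["locus_id"], up, "up", evalue))
        edge_rows.append((row["locus_id"], down, "down", evalue))
        if row["selection"] == "divergent":
            linked_to_divergent.update((up, down))
    edges = pd.DataFrame(edge_rows, columns=["locus_id", "gene_id", "side", "evalue"])
    linked_genes = np.array(sorted(set(edges["gene_id"])))

    sets = []
    enriched_names = []
    for name, size, enriched in candidate_specs:
        w = np.ones(len(linked_genes))
        if enriched and enrichment_factor != 1.0:
            w[np.isin(linked_genes, sorted(linked_to_divergent))] = enrichment_factor
            enriched_names.append(name)
        size = min(size, len(linked_genes))
        chosen = rng.choice(linked_genes, size=size, replace=False, p=w / w.sum())
        sets.append(CandidateGeneSet(name=name, genes=set(chosen)))
    truth.enriched_sets = enriched_names
    return GeneLinkTable(edges=edges), sets, truth
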