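"""Bayesian genomic clines: hybrid index, per-locus cline parameters, outliers.

The model follows the Bayesian genomic-cline framework used for admixed
populations between two parental lineages.  Each admixed individual *j*
carries a hybrid index ``h_j`` in [0,1] (the fraction of its genome from
the **eastern** parental population); each locus *i* carries a cline
center ``alpha_i`` and cline rate ``beta_i``.  The probability that a
gene copy at locus *i* in individual *j* derives from the eastern
population is

    Phi_ij = h_j + 2 h_j (1 - h_j) (alpha_i + beta_i (2 h_j - 1))

truncated to [0,1].  With ``alpha = beta = 0`` the cline is the neutral
diagonal ``Phi = h``; positive alpha shifts ancestry toward the east at
that locus, negative toward the west.

Likelihood: an admixed genotype (alternate-allele count) is
``Binomial(2, Phi_ij * p_e_i + (1 - Phi_ij) * p_w_i)`` where ``p_w, p_e``
are the parental alternate-allele frequencies, themselves given binomial
likelihoods from the observed parental allele counts and Beta(1,1)
priors.  Sampling is Metropolis-within-Gibbs with reflected random-walk
proposals, block-updating {h}, {alpha}, {beta}, {p_w}, {p_e}; the blocks
factorise (loci conditionally independent given h; individuals given the
locus parameters), so each block accepts element-wise.

Priors: h ~ Uniform(0,1); p ~ Beta(1,1).  The locus effects are
hierarchical by default — ``alpha_i ~ Normal(0, sigma_alpha^2)`` and
``beta_i ~ Normal(0, sigma_beta^2)`` with inverse-gamma hyperpriors on
the variances, Gibbs-updated each sweep — so loci with little ancestry
information shrink toward the genomewide distribution instead of
wandering under a fixed prior (the behaviour of the genomic-cline
software this model follows, and what makes a null admixed population
yield essentially no locus effects).  Setting ``hierarchical=False``
fixes the prior standard deviations at ``prior_alpha_sd`` /
``prior_beta_sd`` instead.  Proposal steps adapt during burn-in only
(target acceptance 20-50%), keeping the post-burn-in chain a valid
fixed-kernel Markov chain.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

from .data_io import MISSING, GenotypeMatrix, PopulationMap, ValidationError
from .popgen_stats import _allele_counts

logger = logging.getLogger("hybridzone")

_EPS = 1e-9


def cline_function(h, alpha, beta):
    """Eastern-ancestry probability Phi(h; alpha, beta), truncated to [0,1].

    ``Phi = h + 2 h (1-h) (alpha + beta (2h - 1))``.  Accepts scalars or
    broadcastable arrays; Phi(0)=0 and Phi(1)=1 for any alpha, beta.
    """
    h = np.asarray(h, dtype=float)
    if np.any(h < 0) or np.any(h > 1):
        raise ValueError("hybrid index h must lie in [0,1]")
    phi = h + 2.0 * h * (1.0 - h) * (np.asarray(alpha) + np.asarray(beta) * (2.0 * h - 1.0))
    out = np.clip(phi, 0.0, 1.0)
    return float(out) if out.ndim == 0 else out


@dataclass
class ClineMCMCConfig:
    """MCMC settings (defaults: 25,000 iterations, 10% burn-in, thin 5)."""

    n_iter: int = 25_000
    burn_in: int = 2_500
    thin: int = 5
    step_h: float = 0.05
    step_alpha: float = 0.3
    step_beta: float = 0.2
    step_p: float = 0.05
    prior_alpha_sd: float = 1.0
    prior_beta_sd: float = 0.5
    hierarchical: bool = True
    hyper_a: float = 2.0  # inverse-gamma shape for the locus-effect variances
    adapt_interval: int = 100
    ess_floor: float = 100.0
    keep_draws: bool = False  # retain thinned h/alpha/beta chains on the fit

    def __post_init__(self) -> None:
        if self.burn_in >= self.n_iter:
            raise ValueError("burn_in must be smaller than n_iter")


@dataclass
class ClineFit:
    """Posterior summaries of a genomic-cline fit.

    ``hybrid_index``: one row per admixed individual (posterior mean and
    95% equal-tail interval of h).  ``loci``: one row per locus with the
    posterior median and 95% equal-tail interval of alpha and beta plus
    ``gamma_quantile`` — the CDF of a normal fitted to the genomewide
    median-alpha distribution evaluated at the locus's median alpha.
    Phi is a derived quantity: ``cline_function(h, alpha, beta)``.
    """

    hybrid_index: pd.DataFrame
    loci: pd.DataFrame
    diagnostics: dict
    seed: int
    draws: dict[str, np.ndarray] | None = None  # thinned chains if requested

    @property
    def median_alpha(self) -> np.ndarray:
        return self.loci["alpha_median"].to_numpy()


def _reflect01(x: np.ndarray) -> np.ndarray:
    y = np.mod(x, 2.0)
    return np.where(y > 1.0, 2.0 - y, y)


def fit_genomic_clines(
    admixed: GenotypeMatrix,
    parentals: GenotypeMatrix,
    pm: PopulationMap,
    mcmc: ClineMCMCConfig | None = None,
    seed: int = 0,
) -> ClineFit:
    """Sample the joint posterior over {h}, {alpha}, {beta}, {p_w}, {p_e}.

    ``admixed`` holds the admixed individuals, ``parentals`` the parental
    reference panels (assignments from ``pm``); the two sample sets must
    be disjoint and share loci (the fit runs on the intersection, in
    admixed order).  Missing genotypes contribute no likelihood.  A chain
    whose minimum effective sample size falls below ``mcmc.ess_floor``
    gets a warning in the diagnostics, not an error.
    """
    cfg = mcmc or ClineMCMCConfig()
    rng = np.random.default_rng(seed)

    overlap_samples = set(admixed.sample_ids) & set(parentals.sample_ids)
    if overlap_samples:
        raise ValidationError(f"admixed and parental samples overlap: {sorted(overlap_samples)[:5]}")
    shared = [l for l in admixed.locus_ids if l in set(parentals.locus_ids)]
    if not shared:
        raise ValidationError("admixed and parental matrices share no loci")
    adm = admixed if shared == admixed.locus_ids else admixed.subset_loci(shared)
    par = parentals if shared == parentals.locus_ids else parentals.subset_loci(shared)

    west = [s for s in pm.samples("west") if s in par.sample_ids]
    east = [s for s in pm.samples("east") if s in par.sample_ids]
    if len(west) < 2 or len(east) < 2:
        raise ValidationError("need >=2 parental samples per population")
    k_w, n_w = _allele_counts(par, west)
    k_e, n_e = _allele_counts(par, east)

    G = adm.genotypes.astype(float)
    M = (adm.genotypes != MISSING).astype(float)
    Gf = np.where(M > 0, G, 0.0)
    n_adm, n_loci = Gf.shape

    def admixed_ll(h, alpha, beta, pw, pe):
        phi = cline_function(h[:, None], alpha[None, :], beta[None, :])
        q = np.clip(phi * pe[None, :] + (1.0 - phi) * pw[None, :], _EPS, 1.0 - _EPS)
        return M * (Gf * np.log(q) + (2.0 - Gf) * np.log1p(-q))

    def parental_ll(p, k, n):
        pc = np.clip(p, _EPS, 1.0 - _EPS)
        return k * np.log(pc) + (n - k) * np.log1p(-pc)

    # initial state: conjugate-mean parental frequencies, moment-estimator h
    pw = (k_w + 1.0) / (n_w + 2.0)
    pe = (k_e + 1.0) / (n_e + 2.0)
    d = pe - pw
    denom = (M * d[None, :] ** 2).sum(axis=1)
    num = (M * d[None, :] * (Gf / 2.0 - pw[None, :])).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        h = np.where(denom > 0, num / np.maximum(denom, 1e-12), 0.5)
    h = np.clip(h, 0.02, 0.98)
    alpha = np.zeros(n_loci)
    beta = np.zeros(n_loci)
    sd_alpha = cfg.prior_alpha_sd
    sd_beta = cfg.prior_beta_sd
    # inverse-gamma hyperprior scales centred on the fixed-prior variances
    b0_alpha = cfg.prior_alpha_sd**2 * (cfg.hyper_a - 1.0)
    b0_beta = cfg.prior_beta_sd**2 * (cfg.hyper_a - 1.0)
    _SD_FLOOR = 0.01

    def _gibbs_sd(values: np.ndarray, b0: float) -> float:
        shape = cfg.hyper_a + len(values) / 2.0
        rate = b0 + float(values @ values) / 2.0
        return max(np.sqrt(1.0 / rng.gamma(shape, 1.0 / rate)), _SD_FLOOR)

    LL = admixed_ll(h, alpha, beta, pw, pe)
    pl_w = parental_ll(pw, k_w, n_w)
    pl_e = parental_ll(pe, k_e, n_e)

    steps = {
        "h": cfg.step_h, "alpha": cfg.step_alpha, "beta": cfg.step_beta,
        "pw": cfg.step_p, "pe": cfg.step_p,
    }
    acc_burn = {k: [0, 0] for k in steps}
    acc_main = {k: [0, 0] for k in steps}

    n_keep = (cfg.n_iter - cfg.burn_in) // cfg.thin
    h_draws = np.empty((n_keep, n_adm))
    a_draws = np.empty((n_keep, n_loci))
    b_draws = np.empty((n_keep, n_loci))
    sd_draws = np.empty((n_keep, 2))
    kept = 0

    for it in range(cfg.n_iter):
        burn = it < cfg.burn_in
        acc = acc_burn if burn else acc_main

        # --- h block (per-individual accept) ---
        h_prop = _reflect01(h + steps["h"] * rng.standard_normal(n_adm))
        LLp = admixed_ll(h_prop, alpha, beta, pw, pe)
        delta = (LLp - LL).sum(axis=1)
        accept = np.log(rng.random(n_adm)) < delta
        h = np.where(accept, h_prop, h)
        LL[accept, :] = LLp[accept, :]
        acc["h"][0] += int(accept.sum()); acc["h"][1] += n_adm

        # --- alpha block (per-locus accept) ---
        a_prop = alpha + steps["alpha"] * rng.standard_normal(n_loci)
        LLp = admixed_ll(h, a_prop, beta, pw, pe)
        delta = (LLp - LL).sum(axis=0) + (alpha**2 - a_prop**2) / (2 * sd_alpha**2)
        accept = np.log(rng.random(n_loci)) < delta
        alpha = np.where(accept, a_prop, alpha)
        LL[:, accept] = LLp[:, accept]
        acc["alpha"][0] += int(accept.sum()); acc["alpha"][1] += n_loci

        # --- beta block ---
        b_prop = beta + steps["beta"] * rng.standard_normal(n_loci)
        LLp = admixed_ll(h, alpha, b_prop, pw, pe)
        delta = (LLp - LL).sum(axis=0) + (beta**2 - b_prop**2) / (2 * sd_beta**2)
        accept = np.log(rng.random(n_loci)) < delta
        beta = np.where(accept, b_prop, beta)
        LL[:, accept] = LLp[:, accept]
        acc["beta"][0] += int(accept.sum()); acc["beta"][1] += n_loci

        # --- Gibbs update of the hierarchical locus-effect variances ---
        if cfg.hierarchical:
            sd_alpha = _gibbs_sd(alpha, b0_alpha)
            sd_beta = _gibbs_sd(beta, b0_beta)

        # --- parental frequency blocks ---
        for name, (p_cur, pl_cur, k, n) in (
            ("pw", (pw, pl_w, k_w, n_w)),
            ("pe", (pe, pl_e, k_e, n_e)),
        ):
            p_prop = _reflect01(p_cur + steps[name] * rng.standard_normal(n_loci))
            pl_prop = parental_ll(p_prop, k, n)
            if name == "pw":
                LLp = admixed_ll(h, alpha, beta, p_prop, pe)
            else:
                LLp = admixed_ll(h, alpha, beta, pw, p_prop)
            delta = (LLp - LL).sum(axis=0) + pl_prop - pl_cur
            accept = np.log(rng.random(n_loci)) < delta
            LL[:, accept] = LLp[:, accept]
            if name == "pw":
                pw = np.where(accept, p_prop, pw)
                pl_w = np.where(accept, pl_prop, pl_w)
            else:
                pe = np.where(accept, p_prop, pe)
                pl_e = np.where(accept, pl_prop, pl_e)
            acc[name][0] += int(accept.sum()); acc[name][1] += n_loci

        # --- burn-in-only step adaptation ---
        if burn and (it + 1) % cfg.adapt_interval == 0:
            for name in steps:
                a_cnt, tries = acc_burn[name]
                rate = a_cnt / max(tries, 1)
                if rate < 0.20:
                    steps[name] *= 0.7
                elif rate > 0.50:
                    steps[name] *= 1.4
                acc_burn[name] = [0, 0]

        if not burn and (it - cfg.burn_in) % cfg.thin == 0 and kept < n_keep:
            h_draws[kept] = h
            a_draws[kept] = alpha
            b_draws[kept] = beta
            sd_draws[kept] = (sd_alpha, sd_beta)
            kept += 1

    h_draws, a_draws, b_draws = h_draws[:kept], a_draws[:kept], b_draws[:kept]
    sd_draws = sd_draws[:kept]

    hybrid_index = pd.DataFrame(
        {
            "sample": adm.sample_ids,
            "h_mean": h_draws.mean(axis=0),
            "h_lo": np.quantile(h_draws, 0.025, axis=0),
            "h_hi": np.quantile(h_draws, 0.975, axis=0),
        }
    )
    med_alpha = np.median(a_draws, axis=0)
    loci = pd.DataFrame(
        {
            "locus_id": adm.locus_ids,
            "alpha_median": med_alpha,
            "alpha_lo": np.quantile(a_draws, 0.025, axis=0),
            "alpha_hi": np.quantile(a_draws, 0.975, axis=0),
            "beta_median": np.median(b_draws, axis=0),
            "beta_lo": np.quantile(b_draws, 0.025, axis=0),
            "beta_hi": np.quantile(b_draws, 0.975, axis=0),
            "gamma_quantile": _gamma_quantiles(med_alpha),
        }
    )

    rates = {k: v[0] / max(v[1], 1) for k, v in acc_main.items()}
    ess = _min_ess(h_draws, a_draws)
    diagnostics = {
        "acceptance_rates": rates,
        "min_ess_h": ess[0],
        "min_ess_alpha": ess[1],
        "n_draws": kept,
        "sd_alpha_mean": float(sd_draws[:, 0].mean()),
        "sd_beta_mean": float(sd_draws[:, 1].mean()),
        "ess_warning": bool(min(ess) < cfg.ess_floor),
    }
    if diagnostics["ess_warning"]:
        logger.warning(
            "cline MCMC: minimum ESS %.0f below floor %.0f; treat summaries with care",
            min(ess), cfg.ess_floor,
        )
    draws = (
        {"h": h_draws, "alpha": a_draws, "beta": b_draws, "sd": sd_draws}
        if cfg.keep_draws else None
    )
    return ClineFit(
        hybrid_index=hybrid_index, loci=loci, diagnostics=diagnostics, seed=seed, draws=draws
    )


def _min_ess(h_draws: np.ndarray, a_draws: np.ndarray) -> tuple[float, float]:
    import arviz as az

    def min_of(draws):
        ds = az.convert_to_dataset(draws[None, :, :])
        return float(np.nanmin(az.ess(ds).to_array().to_numpy()))

    return min_of(h_draws), min_of(a_draws)


def _gamma_quantiles(med_alpha: np.ndarray) -> np.ndarray:
    """Normal-CDF quantile of each median alpha in the genomewide distribution."""
    sd = float(np.std(med_alpha, ddof=1)) if len(med_alpha) > 1 else 0.0
    if sd == 0.0:
        return np.full(len(med_alpha), 0.5)
    return norm.cdf(med_alpha, loc=float(np.mean(med_alpha)), scale=sd)


def classify_excess_ancestry(fit: ClineFit, quantile: float = 0.95) -> pd.DataFrame:
    """Excess-ancestry calls per locus.

    A locus shows excess **east** ancestry when its 95% alpha interval
    excludes 0, its median alpha is positive, and the median lies above
    the 97.5th percentile of the genomewide median-alpha distribution
    (central-95% reading of the distribution tails); **west** is the
    mirror image.  ``is_gamma_outlier`` carries the gamma-quantile flags
    at the default n = 0.1.
    """
    med = fit.median_alpha
    lo_thr = np.quantile(med, (1.0 - quantile) / 2.0)
    hi_thr = np.quantile(med, 1.0 - (1.0 - quantile) / 2.0)
    ci_lo = fit.loci["alpha_lo"].to_numpy()
    ci_hi = fit.loci["alpha_hi"].to_numpy()
    east = (ci_lo > 0) & (med > 0) & (med > hi_thr)
    west = (ci_hi < 0) & (med < 0) & (med < lo_thr)
    excess = np.where(east, "east", np.where(west, "west", "none"))
    out = pd.DataFrame(
        {
            "locus_id": fit.loci["locus_id"].to_numpy(),
            "excess": excess,
            "is_gamma_outlier": gamma_outliers(fit),
        }
    )
    n_e, n_w = int(east.sum()), int(west.sum())
    logger.info("excess ancestry: %d east, %d west of %d loci", n_e, n_w, len(med))
    return out


def gamma_outliers(fit: ClineFit, n: float = 0.1, method: str = "normal") -> np.ndarray:
    """Strong outliers: gamma-quantile outside [n/2, 1 - n/2].

    The gamma-quantile of a locus is the fitted-normal CDF of its median
    alpha within the genomewide distribution (``method="normal"``,
    matching the parametric locus-effect construction) or its mid-rank
    empirical quantile (``method="rank"``); with n = 0.1 loci outside the
    central 90% are flagged.  All-identical medians flag nothing.
    """
    if len(fit.loci) < 10:
        raise ValidationError("gamma outlier classification needs >= 10 loci")
    med = fit.median_alpha
    if float(np.std(med, ddof=1)) == 0.0:
        return np.zeros(len(med), dtype=bool)
    if method == "normal":
        gq = fit.loci["gamma_quantile"].to_numpy()
    elif method == "rank":
        order = np.argsort(np.argsort(med))
        gq = (order + 0.5) / len(med)
    else:
        raise ValueError("method must be 'normal' or 'rank'")
    return (gq < n / 2.0) | (gq > 1.0 - n / 2.0)
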