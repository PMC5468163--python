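"""Shared fixtures: small genotype worlds built programmatically."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from hybridzone.data_io import GenotypeMatrix, PopulationMap
from hybridzone.synthetic_data import SimTruth

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def make_locus_meta(n_loci: int) -> pd.DataFrame:
    ids = [f"contig{i:05d}:1" for i in range(n_loci)]
    return pd.DataFrame(
        {"chrom": [f"contig{i:05d}" for i in range(n_loci)],
         "pos": 1, "ref": "A", "alt": "T"},
        index=ids,
    )


def make_parental_panel(
    p_w: np.ndarray, p_e: np.ndarray, n_west: int = 24, n_east: int = 24, seed: int = 0
) -> tuple[GenotypeMatrix, PopulationMap, SimTruth]:
    """Binomial parental genotypes at given allele frequencies (fully observed)."""
    rng = np.random.default_rng(seed)
    n_loci = len(p_w)
    meta = make_locus_meta(n_loci)
    G = np.vstack(
        [rng.binomial(2, p_w, size=(n_west, n_loci)),
         rng.binomial(2, p_e, size=(n_east, n_loci))]
    ).astype(np.int8)
    samples = [f"w{i:03d}" for i in range(n_west)] + [f"e{i:03d}" for i in range(n_east)]
    gm = GenotypeMatrix(samples, list(meta.index), G, meta)
    pm = PopulationMap({s: ("west" if s.startswith("w") else "east") for s in samples})
    truth = SimTruth(
        loci=pd.DataFrame(
            {"locus_id": list(meta.index), "p_west": p_w, "p_east": p_e,
             "alpha_true": 0.0, "beta_true": 0.0, "selection": "neutral"}
        ),
        locus_meta=meta,
        seed=seed,
    )
    return gm, pm, truth


@pytest.fixture(scope="session")
def informative_world():
    """200 strongly ancestry-informative loci (p_west=0.1, p_east=0.9)."""
    p_w = np.full(200, 0.1)
    p_e = np.full(200, 0.9)
    return make_parental_panel(p_w, p_e, seed=11)


@pytest.fixture(scope="session")
def mixed_world():
    """300 loci with a spread of differentiation levels."""
    rng = np.random.default_rng(7)
    p_w = rng.uniform(0.02, 0.98, 300)
    p_e = np.clip(p_w + rng.normal(0, 0.25, 300), 0.01, 0.99)
    return make_parental_panel(p_w, p_e, seed=13)
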