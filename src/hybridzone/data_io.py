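"""Core data containers and file input/output.

Genotypes live in a :class:`GenotypeMatrix`: a dense (samples x loci) array of
alternate-allele counts with ``-1`` marking missing calls, plus per-locus
metadata (contig, 1-based position, ref/alt alleles).  All differentiation
statistics downstream are invariant to which allele is counted, so the
alternate-allele orientation is a pure storage convention; the east/west
direction of any signal is attached later from parental allele frequencies.

Sidecar tables (population map, locus->gene links, candidate gene sets,
posterior parameter samples) are plain TSV read through pandas.
"""

from __future__ import annotations

import dataclasses
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from cyvcf2 import VCF

logger = logging.getLogger("hybridzone")

MISSING = -1  # sentinel genotype code

POPULATIONS = ("west", "east", "admixed")


class HybridzoneError(Exception):
    """Base class for package errors."""


class EmptyDatasetError(HybridzoneError):
    """No records survived reading/filtering."""


class ValidationError(HybridzoneError):
    """An input table violated its contract."""


class UnknownLocusError(ValidationError):
    """A sidecar table referenced locus ids absent from the genotype matrix."""

    def __init__(self, offenders: Sequence[str]):
        self.offenders = sorted(offenders)
        super().__init__(
            f"gene link table references {len(self.offenders)} unknown locus id(s): "
            + ", ".join(self.offenders[:10])
            + ("..." if len(self.offenders) > 10 else "")
        )


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class GenotypeMatrix:
    """Diploid genotypes as alternate-allele counts in {0,1,2}, -1 = missing.

    Parameters
    ----------
    sample_ids
        Ordered, unique sample labels (rows).
    locus_ids
        Ordered, unique locus labels (columns); one SNP per RAD locus after
        filtering.
    genotypes
        ``int8`` array of shape ``(n_samples, n_loci)``.
    locus_meta
        DataFrame indexed by locus id with columns ``chrom`` (contig),
        ``pos`` (1-based, VCF convention), ``ref``, ``alt``.
    """

    sample_ids: list[str]
    locus_ids: list[str]
    genotypes: np.ndarray
    locus_meta: pd.DataFrame

    def __post_init__(self) -> None:
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValidationError("sample ids are not unique")
        if len(set(self.locus_ids)) != len(self.locus_ids):
            raise ValidationError("locus ids are not unique")
        if self.genotypes.shape != (len(self.sample_ids), len(self.locus_ids)):
            raise ValidationError(
                f"genotype array shape {self.genotypes.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.locus_ids)} loci"
            )
        valid = np.isin(self.genotypes, (0, 1, 2, MISSING))
        if not valid.all():
            raise ValidationError("genotype codes must be in {0,1,2} or -1 (missing)")
        if list(self.locus_meta.index) != list(self.locus_ids):
            raise ValidationError("locus_meta index must equal locus_ids")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_loci(self) -> int:
        return len(self.locus_ids)

    def subset_samples(self, samples: Sequence[str]) -> "GenotypeMatrix":
        idx = [self.sample_ids.index(s) for s in samples]
        return GenotypeMatrix(
            sample_ids=list(samples),
            locus_ids=list(self.locus_ids),
            genotypes=self.genotypes[idx, :].copy(),
            locus_meta=self.locus_meta.copy(),
        )

    def subset_loci(self, loci: Sequence[str]) -> "GenotypeMatrix":
        pos = {l: i for i, l in enumerate(self.locus_ids)}
        idx = [pos[l] for l in loci]
        return GenotypeMatrix(
            sample_ids=list(self.sample_ids),
            locus_ids=list(loci),
            genotypes=self.genotypes[:, idx].copy(),
            locus_meta=self.locus_meta.loc[list(loci)].copy(),
        )


@dataclass
class PopulationMap:
    """Assignment of samples to the west / east / admixed populations."""

    assignments: dict[str, str]

    def __post_init__(self) -> None:
        bad = {p for p in self.assignments.values() if p not in POPULATIONS}
        if bad:
            raise ValidationError(f"unknown population label(s): {sorted(bad)}")

    def samples(self, population: str) -> list[str]:
        return [s for s, p in self.assignments.items() if p == population]

    def validate_for(self, gm: GenotypeMatrix, require_parental_pairs: bool = True) -> None:
        missing = [s for s in gm.sample_ids if s not in self.assignments]
        if missing:
            raise ValidationError(f"samples without population assignment: {missing[:10]}")
        if require_parental_pairs:
            for pop in ("west", "east"):
                n = sum(1 for s in gm.sample_ids if self.assignments.get(s) == pop)
                if n < 2:
                    raise ValidationError(
                        f"need at least 2 samples in parental population '{pop}', got {n}"
                    )


@dataclass
class GeneLinkTable:
    """locus id -> nearest up/downstream gene ids, with optional e-values."""

    edges: pd.DataFrame  # columns: locus_id, gene_id, side, evalue

    def genes_for(self, locus_ids: Sequence[str]) -> set[str]:
        sel = self.edges["locus_id"].isin(set(locus_ids))
        return set(self.edges.loc[sel, "gene_id"])

    @property
    def background_genes(self) -> set[str]:
        return set(self.edges["gene_id"])


@dataclass
class CandidateGeneSet:
    name: str
    genes: set[str]

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValidationError(f"candidate gene set '{self.name}' is empty")


@dataclass
class PosteriorSampleSet:
    """Posterior draws of (theta_west, theta_east, theta_anc, tau).

    theta_* are per-site scaled mutation parameters (4*N*mu) and tau the
    divergence time in expected substitutions per site, as estimated by a
    SNAPP-style two-population isolation model.
    """

    samples: pd.DataFrame  # columns theta_west, theta_east, theta_anc, tau

    COLUMNS = ("theta_west", "theta_east", "theta_anc", "tau")

    def __post_init__(self) -> None:
        missing = [c for c in self.COLUMNS if c not in self.samples.columns]
        if missing:
            raise ValidationError(f"posterior table missing column(s): {missing}")
        if len(self.samples) < 1:
            raise ValidationError("posterior table must have at least one row")
        vals = self.samples[list(self.COLUMNS)].to_numpy(dtype=float)
        if not np.isfinite(vals).all() or (vals < 0).any():
            raise ValidationError("posterior parameters must be finite and >= 0")

    def __len__(self) -> int:
        return len(self.samples)


# ---------------------------------------------------------------------------
# VCF reading / writing
# ---------------------------------------------------------------------------

def read_vcf_genotypes(vcf_path: str | Path, qual_min: float = 30.0) -> GenotypeMatrix:
    """Read biallelic SNPs with QUAL > ``qual_min`` from a VCF.

    Genotypes are coded as alternate-allele counts; any genotype with a
    missing allele (``./.`` or half calls) is stored as missing.  Records
    that are not SNPs, are not biallelic, or fail the quality floor are
    dropped.  Raises :class:`EmptyDatasetError` if nothing survives.
    """
    vcf_path = str(vcf_path)
    try:
        vcf = VCF(vcf_path, gts012=True)
    except Exception as exc:  # cyvcf2 raises bare exceptions on bad paths
        raise OSError(f"cannot read VCF {vcf_path!r}: {exc}") from exc

    sample_ids = list(vcf.samples)
    locus_ids: list[str] = []
    meta_rows = []
    geno_cols: list[np.ndarray] = []
    for v in vcf:
        if not v.is_snp or len(v.ALT) != 1:
            continue
        qual = v.QUAL
        if qual is None:
            if np.isfinite(qual_min):
                continue
        elif not qual > qual_min:
            continue
        # gts012: 0/1/2 = alt-allele count, 3 = unknown
        g = np.asarray(v.gt_types, dtype=np.int8)
        g[g == 3] = MISSING
        locus_ids.append(f"{v.CHROM}:{v.POS}")
        meta_rows.append((v.CHROM, v.POS, v.REF, v.ALT[0]))
        geno_cols.append(g)
    vcf.close()

    if not locus_ids:
        raise EmptyDatasetError(f"no biallelic SNPs with QUAL > {qual_min} in {vcf_path}")
    meta = pd.DataFrame(meta_rows, columns=["chrom", "pos", "ref", "alt"], index=locus_ids)
    gm = GenotypeMatrix(
        sample_ids=sample_ids,
        locus_ids=locus_ids,
        genotypes=np.column_stack(geno_cols),
        locus_meta=meta,
    )
    logger.info("read %d samples x %d SNPs from %s", gm.n_samples, gm.n_loci, vcf_path)
    return gm


_GT_STRINGS = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}


def write_vcf_genotypes(gm: GenotypeMatrix, vcf_path: str | Path) -> None:
    """Write a minimal VCFv4.2 with GT fields (round-trips through the reader)."""
    with open(vcf_path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=hybridzone\n")
        for chrom in pd.unique(gm.locus_meta["chrom"]):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(gm.sample_ids) + "\n")
        for j, locus in enumerate(gm.locus_ids):
            row = gm.locus_meta.loc[locus]
            gts = "\t".join(_GT_STRINGS[int(g)] for g in gm.genotypes[:, j])
            fh.write(
                f"{row['chrom']}\t{row['pos']}\t{locus}\t{row['ref']}\t{row['alt']}"
                f"\t100\tPASS\t.\tGT\t{gts}\n"
            )


# ---------------------------------------------------------------------------
# SNP filtering
# ---------------------------------------------------------------------------

def filter_snps(
    gm: GenotypeMatrix,
    pm: PopulationMap | None = None,
    maf_min: float = 0.05,
    seed: int = 0,
    per_contig: str = "random",
) -> GenotypeMatrix:
    """Thin to one SNP per contig and drop low-MAF variants.

    One variant is kept per contig (RAD locus) to reduce linkage among
    sites: a seeded uniform draw by default, or the first record with
    ``per_contig="first"``.  The minor-allele-frequency floor is computed
    over all non-missing alleles of all samples (restricted to mapped
    samples when a population map is given).  Retained loci keep their
    original order, and the operation is idempotent.
    """
    if per_contig not in ("random", "first"):
        raise ValueError("per_contig must be 'random' or 'first'")
    rng = np.random.default_rng(seed)

    contigs = gm.locus_meta["chrom"].to_numpy()
    keep_mask = np.zeros(gm.n_loci, dtype=bool)
    # stable per-contig grouping in order of first appearance
    order: dict[str, list[int]] = {}
    for i, c in enumerate(contigs):
        order.setdefault(c, []).append(i)
    for c in order:
        idxs = order[c]
        if per_contig == "first" or len(idxs) == 1:
            keep_mask[idxs[0]] = True
        else:
            keep_mask[idxs[int(rng.integers(len(idxs)))]] = True

    if pm is not None:
        rows = [i for i, s in enumerate(gm.sample_ids) if s in pm.assignments]
    else:
        rows = list(range(gm.n_samples))
    G = gm.genotypes[rows, :]
    obs = G != MISSING
    alt = np.where(obs, G, 0).sum(axis=0)
    n = 2 * obs.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.divide(alt, n, out=np.full(gm.n_loci, np.nan), where=n > 0)
    maf = np.fmin(p, 1 - p)
    keep_mask &= ~np.isnan(maf) & (maf >= maf_min)

    kept = [l for l, k in zip(gm.locus_ids, keep_mask) if k]
    if not kept:
        raise EmptyDatasetError("no SNPs survived filtering")
    logger.info("filter_snps: %d -> %d loci", gm.n_loci, len(kept))
    return gm.subset_loci(kept)


# ---------------------------------------------------------------------------
# sidecar tables
# ---------------------------------------------------------------------------

def read_population_map(path: str | Path) -> PopulationMap:
    """Read a 2-column TSV (sample, population)."""
    df = _read_tsv(path, ["sample", "population"])
    dup = df["sample"][df["sample"].duplicated()]
    if len(dup):
        raise ValidationError(f"duplicate sample(s) in population map: {list(dup)[:5]}")
    return PopulationMap(dict(zip(df["sample"], df["population"])))


def _read_tsv(path: str | Path, required: list[str]) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    except pd.errors.ParserError as exc:
        raise ValidationError(f"malformed TSV {path}: {exc}") from exc
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing column(s) {missing}")
    bad = df[required].isna().any(axis=1)
    if bad.any():
        lineno = int(np.flatnonzero(bad.to_numpy())[0]) + 2  # header is line 1
        raise ValidationError(f"{path}: malformed row at line {lineno}")
    return df


def read_sidecar_tables(
    gene_links_path: str | Path,
    candidate_sets_path: str | Path,
    posterior_path: str | Path,
    known_locus_ids: Sequence[str] | None = None,
) -> tuple[GeneLinkTable, list[CandidateGeneSet], PosteriorSampleSet]:
    """Read the gene-link, candidate-set, and posterior-sample TSVs.

    When ``known_locus_ids`` is given, gene links referencing loci outside
    that set raise :class:`UnknownLocusError` listing the offenders.
    """
    links = _read_tsv(gene_links_path, ["locus_id", "gene_id", "side"])
    bad_side = set(links["side"]) - {"up", "down"}
    if bad_side:
        raise ValidationError(f"gene link side must be 'up' or 'down', got {sorted(bad_side)}")
    if "evalue" in links.columns:
        links["evalue"] = pd.to_numeric(links["evalue"], errors="coerce")
    if known_locus_ids is not None:
        unknown = set(links["locus_id"]) - set(known_locus_ids)
        if unknown:
            raise UnknownLocusError(sorted(unknown))
    gene_links = GeneLinkTable(edges=links)

    try:
        cand_df = pd.read_csv(candidate_sets_path, sep="\t", dtype=str, comment="#")
    except pd.errors.EmptyDataError:
        cand_df = pd.DataFrame(columns=["set_name", "gene_id"])
    if len(cand_df) and not {"set_name", "gene_id"}.issubset(cand_df.columns):
        raise ValidationError(f"{candidate_sets_path}: need columns set_name, gene_id")
    candidate_sets = [
        CandidateGeneSet(name=name, genes=set(grp["gene_id"]))
        for name, grp in cand_df.groupby("set_name", sort=False)
    ]
    if not candidate_sets:
        warnings.warn("candidate set file is empty; no enrichment tests possible")
        logger.warning("candidate set file %s is empty", candidate_sets_path)

    post_df = _read_tsv(posterior_path, list(PosteriorSampleSet.COLUMNS))
    post_df = post_df.astype({c: float for c in PosteriorSampleSet.COLUMNS})
    posterior = PosteriorSampleSet(samples=post_df)
    return gene_links, candidate_sets, posterior


def write_population_map(pm: PopulationMap, path: str | Path) -> None:
    pd.DataFrame(
        {"sample": list(pm.assignments), "population": list(pm.assignments.values())}
    ).to_csv(path, sep="\t", index=False)
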