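"""Synthetic GWAS data with the exact generative structure the model assumes.

Genotypes are produced by the liability mechanism itself: rows of latent
liabilities U ~ N(0, C) are thresholded at the Hardy-Weinberg quantiles of
each SNP's allele frequency, giving LD-correlated dosages in {0,1,2}.  The
quantitative trait is linear in covariates and in the (standardised) causal
genotype signal plus N(0, tau2) noise.  Writers emit the same plain-text
formats the readers consume, so every integration test is download-free.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .io import GeneMap, GenotypeData, PhenotypeData, read_gene_map
from .latent import hwe_category_probs, latent_block, liability_thresholds
from .model import ModelConfig
from .sampler import SamplerConfig, run_block_sampler
from .inference import compute_ppa

__all__ = ["SimDesign", "SimTruth", "default_design", "correlation_matrix",
           "simulate_genotypes", "simulate_trait", "simulate_dataset",
           "beta_for_heritability", "recovery_experiment", "write_dataset"]


@dataclass
class SimDesign:
    """Study design for one synthetic data set.

    corr_spec : ('independent',), ('ar1', rho) or ('block_exchangeable', rho,
        [sizes...]) describing the liability correlation C.
    gene_layout : list of (start, end) SNP-index intervals (end exclusive).
    beta_effect : per-causal-SNP effect on the standardised dosage scale; use
        :func:`beta_for_heritability` to hit a target h2.
    signal : 'dosage' (standardised observed dosage, the default — what a
        real GWAS measures) or 'latent' (the true liability U).
    """

    n: int = 200
    p: int = 50
    maf: np.ndarray | None = None
    corr_spec: tuple = ("independent",)
    gene_layout: list[tuple[int, int]] = field(default_factory=list)
    causal_genes: tuple[int, ...] = ()
    causal_snps: tuple[int, ...] = ()
    beta_effect: float = 0.0
    eta: np.ndarray | None = None
    tau2: float = 1.0
    signal: str = "dosage"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.maf is not None:
            self.maf = np.asarray(self.maf, dtype=float)
            if self.maf.size != self.p:
                raise ValueError("maf vector length must equal p")
            if np.any((self.maf <= 0) | (self.maf > 0.5)):
                raise ValueError("maf values must lie in (0, 0.5]")
        if self.causal_genes and self.gene_layout:
            for j in self.causal_snps:
                if not any(s <= j < e for g in self.causal_genes
                           for s, e in [self.gene_layout[g]]):
                    raise ValueError(f"causal SNP {j} lies outside every causal gene")
        if self.signal not in ("dosage", "latent"):
            raise ValueError("signal must be 'dosage' or 'latent'")

    @property
    def theta_true(self) -> np.ndarray:
        t = np.zeros(self.p, dtype=np.int8)
        t[list(self.causal_snps)] = 1
        return t

    @property
    def gamma_true(self) -> np.ndarray:
        g = np.zeros(len(self.gene_layout), dtype=np.int8)
        g[list(self.causal_genes)] = 1
        return g


@dataclass
class SimTruth:
    """Realised data set plus its generating truth."""

    U_true: np.ndarray
    X: np.ndarray
    y: np.ndarray | None
    theta_true: np.ndarray
    gamma_true: np.ndarray
    maf: np.ndarray


def beta_for_heritability(h2: float, n_causal: int, tau2: float) -> float:
    """Effect size giving heritability h2 when n_causal standardised signals act additively.

    Signal variance k beta^2 against noise tau2: h2 = k b^2 / (k b^2 + tau2).
    """
    if not 0 <= h2 < 1:
        raise ValueError("h2 must lie in [0, 1)")
    if h2 == 0 or n_causal == 0:
        return 0.0
    return float(np.sqrt(h2 / (1.0 - h2) * tau2 / n_causal))


def default_design(seed: int = 0, h2: float = 0.3) -> SimDesign:
    """The reference recovery design: n=200, p=50, 10 genes of 5 SNPs,
    2 causal genes holding 5 causal SNPs, trait heritability h2 (default 0.3)
    on a unit-noise scale.  MAFs are drawn once, uniformly on (0.1, 0.5)."""
    rng = np.random.default_rng(np.random.SeedSequence([seed, 7]))
    maf = rng.uniform(0.1, 0.5, size=50)
    gene_layout = [(5 * g, 5 * g + 5) for g in range(10)]
    causal_genes = (1, 6)
    causal_snps = (5, 6, 7, 30, 31)
    return SimDesign(
        n=200, p=50, maf=maf, corr_spec=("independent",),
        gene_layout=gene_layout, causal_genes=causal_genes, causal_snps=causal_snps,
        beta_effect=beta_for_heritability(h2, len(causal_snps), 1.0),
        tau2=1.0, seed=seed,
    )


def correlation_matrix(corr_spec: tuple, p: int) -> np.ndarray:
    """Build the liability correlation matrix from a corr_spec tuple."""
    kind = corr_spec[0]
    if kind == "independent":
        return np.eye(p)
    if kind == "ar1":
        rho = float(corr_spec[1])
        if not -1 < rho < 1:
            raise ValueError("AR(1) rho must lie in (-1, 1)")
        idx = np.arange(p)
        return rho ** np.abs(idx[:, None] - idx[None, :])
    if kind == "block_exchangeable":
        rho, sizes = float(corr_spec[1]), list(corr_spec[2])
        if not -1 < rho < 1:
            raise ValueError("exchangeable rho must lie in (-1, 1)")
        if sum(sizes) != p:
            raise ValueError("block sizes must sum to p")
        C = np.eye(p)
        start = 0
        for s in sizes:
            C[start:start + s, start:start + s] = rho
            start += s
        C[np.diag_indices(p)] = 1.0
        return C
    raise ValueError(f"unknown corr_spec kind {kind!r}")


def _design_maf(design: SimDesign, rng: np.random.Generator) -> np.ndarray:
    if design.maf is not None:
        return design.maf
    return rng.uniform(0.1, 0.5, size=design.p)


def simulate_genotypes(design: SimDesign, rng: np.random.Generator) -> SimTruth:
    """Draw liabilities U ~ N(0, C) and threshold them into dosages.

    X_ij = 0, 1 or 2 as U_ij falls below t1, between t1 and t2, or above t2,
    the HWE liability thresholds of maf[j].
    """
    maf = _design_maf(design, rng)
    C = correlation_matrix(design.corr_spec, design.p)
    L = np.linalg.cholesky(C)
    U = rng.standard_normal((design.n, design.p)) @ L.T
    t1 = np.empty(design.p)
    t2 = np.empty(design.p)
    for j, q in enumerate(maf):
        th = liability_thresholds(hwe_category_probs(q))
        t1[j], t2[j] = th.t1, th.t2
    X = (U > t1[None, :]).astype(np.int8) + (U > t2[None, :]).astype(np.int8)
    return SimTruth(U_true=U, X=X, y=None, theta_true=design.theta_true,
                    gamma_true=design.gamma_true, maf=maf)


def _signal_matrix(truth: SimTruth, design: SimDesign) -> np.ndarray:
    idx = list(design.causal_snps)
    if design.signal == "latent":
        return truth.U_true[:, idx]
    S = truth.X[:, idx].astype(float)
    sd = S.std(axis=0)
    sd[sd == 0] = 1.0
    return (S - S.mean(axis=0)) / sd


def simulate_trait(truth: SimTruth, design: SimDesign, V: np.ndarray,
                   rng: np.random.Generator) -> np.ndarray:
    """y_i = v_i' eta + sum_{j causal} signal_ij * beta + N(0, tau2) noise."""
    V = np.asarray(V, dtype=float).reshape(design.n, -1)
    eta = np.zeros(V.shape[1]) if design.eta is None else np.asarray(design.eta, dtype=float)
    y = V @ eta if V.size else np.zeros(design.n)
    if design.causal_snps:
        y = y + _signal_matrix(truth, design) @ np.full(len(design.causal_snps),
                                                        design.beta_effect)
    y = y + np.sqrt(design.tau2) * rng.standard_normal(design.n)
    return y


def _gene_bed_records(design: SimDesign):
    """Genes as bp intervals consistent with SNP j sitting at position (j+1)*1000."""
    recs = []
    for g, (s, e) in enumerate(design.gene_layout):
        # cover 1-based positions (s+1)*1000 .. e*1000  ->  BED [ (s+1)*1000-1, e*1000 )
        recs.append((f"gene{g}", "1", (s + 1) * 1000 - 1, e * 1000))
    return recs


def simulate_dataset(design: SimDesign):
    """Full in-memory realisation: (GenotypeData, PhenotypeData, GeneMap, SimTruth).

    All randomness flows from design.seed through deterministic substreams.
    Positions place SNP j (0-based) at (j+1)*1000 bp on chromosome 1;
    monomorphic columns (possible at small n) are kept out of GenotypeData by
    construction of the MAF range, but a guard re-checks.
    """
    ss = np.random.SeedSequence([design.seed, 11])
    rng_geno, rng_trait = [np.random.default_rng(s) for s in ss.spawn(2)]
    truth = simulate_genotypes(design, rng_geno)
    V = np.ones((design.n, 1))
    truth.y = simulate_trait(truth, design, V, rng_trait)

    # orient to the empirical minor allele so the file round trip is exact
    f = truth.X.mean(axis=0) / 2.0
    flip = f > 0.5
    truth.X[:, flip] = 2 - truth.X[:, flip]
    emp_maf = np.minimum(f, 1 - f)
    if np.any(emp_maf == 0):
        bad = np.flatnonzero(emp_maf == 0)
        raise ValueError(f"monomorphic simulated SNPs at indices {bad[:5]}; "
                         "increase n or the MAF floor")
    geno = GenotypeData(
        X=truth.X,
        snp_ids=np.array([f"snp{j}" for j in range(design.p)], dtype=object),
        chrom=np.array(["1"] * design.p, dtype=object),
        pos=np.arange(1, design.p + 1, dtype=np.int64) * 1000,
        maf=emp_maf,
    )
    pheno = PhenotypeData(y=truth.y, V=V, covariate_names=["intercept"])
    from scipy import sparse
    rows = [j for g, (s, e) in enumerate(design.gene_layout) for j in range(s, e)]
    cols = [g for g, (s, e) in enumerate(design.gene_layout) for _ in range(s, e)]
    incidence = sparse.csr_matrix((np.ones(len(rows), dtype=np.int8), (rows, cols)),
                                  shape=(design.p, len(design.gene_layout)))
    genes = [(f"gene{g}", "1", (s + 1) * 1000, e * 1000) for g, (s, e) in
             enumerate(design.gene_layout)]
    gene_map = GeneMap(genes=genes, incidence=incidence)
    return geno, pheno, gene_map, truth


def write_dataset(design: SimDesign, outdir) -> dict:
    """Realise the design and write genotype/phenotype/gene/truth text files."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    geno, pheno, gene_map, truth = simulate_dataset(design)
    geno.to_tsv(outdir / "genotypes.tsv", snp_info_path=outdir / "snps.tsv")
    pd.DataFrame({"sample_id": np.arange(design.n), "trait": pheno.y}).to_csv(
        outdir / "phenotype.tsv", sep="\t", index=False)
    with open(outdir / "genes.bed", "w") as fh:
        for name, chrom, start0, end in _gene_bed_records(design):
            fh.write(f"{chrom}\t{start0}\t{end}\t{name}\n")
    pd.DataFrame({"snp_id": geno.snp_ids, "theta_true": truth.theta_true}).to_csv(
        outdir / "truth_snps.tsv", sep="\t", index=False)
    pd.DataFrame({"gene_id": [g[0] for g in gene_map.genes],
                  "gamma_true": truth.gamma_true}).to_csv(
        outdir / "truth_genes.tsv", sep="\t", index=False)
    return {"dir": str(outdir), "n": design.n, "p": design.p}


def recovery_experiment(design: SimDesign, model_config: ModelConfig | None = None,
                        sampler_config: SamplerConfig | None = None,
                        genotype_mode: str = "latent", shrinkage: float = 0.1,
                        out_path=None) -> dict:
    """Simulate, fit, and score recovery of the known truth.

    Returns a report with causal-SNP PPA ranks, whether all causal SNPs land
    in the top |causal| ranks, causal vs null mean gene PPA, and centroid
    accuracy.  Deterministic given the design seed and sampler seed.
    """
    if model_config is None:
        model_config = replace(ModelConfig(), tau2=design.tau2)
    if sampler_config is None:
        sampler_config = SamplerConfig(n_sweeps=1500, burn_in=500, seed=design.seed)
    geno, pheno, gene_map, truth = simulate_dataset(design)
    if genotype_mode == "latent":
        Z = latent_block(geno.X, geno.maf, shrinkage=shrinkage).Z_hat
    elif genotype_mode == "raw":
        Xf = geno.X.astype(float)
        Z = (Xf - Xf.mean(axis=0)) / Xf.std(axis=0)
    else:
        raise ValueError("genotype_mode must be 'latent' or 'raw'")
    trace = run_block_sampler(pheno.y, pheno.V, Z, gene_map, model_config, sampler_config)
    summary = compute_ppa(trace)

    order = np.argsort(-summary.snp_ppa, kind="mergesort")
    rank_of = np.empty(design.p, dtype=int)
    rank_of[order] = np.arange(1, design.p + 1)
    causal = np.asarray(design.causal_snps, dtype=int)
    null_genes = [g for g in range(len(design.gene_layout)) if g not in design.causal_genes]
    report = {
        "causal_snp_ranks": sorted(int(rank_of[j]) for j in causal),
        "all_causal_in_top_k": bool((rank_of[causal] <= len(causal)).all()),
        "causal_gene_mean_ppa": float(summary.gene_ppa[list(design.causal_genes)].mean())
            if design.causal_genes else float("nan"),
        "null_gene_mean_ppa": float(summary.gene_ppa[null_genes].mean())
            if null_genes else float("nan"),
        "mean_ppa": float(summary.snp_ppa.mean()),
        "centroid_matches_truth": bool(
            np.array_equal(summary.snp_centroid, truth.theta_true)),
        "snp_ppa": [float(v) for v in summary.snp_ppa],
        "gene_ppa": [float(v) for v in summary.gene_ppa],
        "seed": design.seed,
    }
    if out_path is not None:
        with open(out_path, "w") as fh:
            json.dump(report, fh, indent=2)
    return report
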