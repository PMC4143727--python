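"""Posterior summaries: PPA, centroid estimates and ranked reports.

The posterior probability of association (PPA) of SNP j is the posterior mean
of its inclusion indicator, psi_j = sum_s theta_j^(s) / N, and likewise for
genes.  The centroid estimator minimises posterior expected Hamming distance;
on the unconstrained space {0,1}^p it reduces to the consensus rule
theta_j = I(psi_j > 0.5) (ties at exactly 0.5 resolve to 0, matching the
strict inequality).  Because PPAs are probabilities, they are comparable
across studies without multiple-testing correction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import GeneMap, GenotypeData
from .sampler import ChainTrace

__all__ = ["PosteriorSummary", "compute_ppa", "centroid_estimate",
           "centroid_bruteforce", "rank_report"]


@dataclass
class PosteriorSummary:
    """Per-SNP and per-gene PPAs with their centroid (consensus) selections."""

    snp_ppa: np.ndarray
    gene_ppa: np.ndarray
    snp_centroid: np.ndarray
    gene_centroid: np.ndarray
    n_samples: int


def compute_ppa(trace: ChainTrace) -> PosteriorSummary:
    """PPAs as posterior means of the indicator samples, plus centroid selections."""
    if trace.n_kept == 0:
        raise ValueError("empty chain trace")
    snp_ppa = trace.theta_samples.mean(axis=0)
    gene_ppa = trace.gamma_samples.mean(axis=0) if trace.gamma_samples.size else \
        np.zeros(trace.gamma_samples.shape[1])
    return PosteriorSummary(
        snp_ppa=snp_ppa,
        gene_ppa=gene_ppa,
        snp_centroid=centroid_estimate(snp_ppa),
        gene_centroid=centroid_estimate(gene_ppa),
        n_samples=trace.n_kept,
    )


def centroid_estimate(ppa) -> np.ndarray:
    """Consensus rule: select coordinate j iff its PPA strictly exceeds 0.5."""
    ppa = np.asarray(ppa, dtype=float)
    if ppa.size and (ppa.min() < 0 or ppa.max() > 1):
        raise ValueError("PPA values must lie in [0, 1]")
    return (ppa > 0.5).astype(np.int8)


def centroid_bruteforce(ppa, max_p: int = 12):
    """Exhaustive expected-Hamming minimiser over {0,1}^p (test oracle only).

    Returns (minimiser, tie_set): all binary vectors attaining the minimum of
    E[H(theta, t)] = sum_j [ppa_j (1 - t_j) + (1 - ppa_j) t_j].
    """
    ppa = np.asarray(ppa, dtype=float)
    p = ppa.size
    if p > max_p:
        raise ValueError(f"refusing exhaustive enumeration for p={p} > {max_p}")
    best, ties = np.inf, []
    for code in range(2 ** p):
        t = np.array([(code >> j) & 1 for j in range(p)], dtype=np.int8)
        dist = float(np.sum(ppa * (1 - t) + (1 - ppa) * t))
        if dist < best - 1e-12:
            best, ties = dist, [t]
        elif dist <= best + 1e-12:
            ties.append(t)
    return ties[0], ties


def rank_report(summary: PosteriorSummary, data: GenotypeData, gene_map: GeneMap,
                top_k: int = 5) -> pd.DataFrame:
    """Top SNPs by PPA, formatted with covering genes and gene PPAs.

    Ties in PPA are broken by ascending genomic position; SNPs outside every
    gene show "--" in the gene columns.
    """
    p = data.n_snps
    gene_ids = gene_map.gene_ids()
    rows = []
    for j in range(p):
        genes = gene_map.genes_of_snp(j)
        rows.append({
            "snp_id": data.snp_ids[j],
            "chrom": data.chrom[j],
            "pos": int(data.pos[j]),
            "maf": float(data.maf[j]),
            "snp_ppa": float(summary.snp_ppa[j]),
            "genes": ",".join(gene_ids[g] for g in genes) if len(genes) else "--",
            "gene_ppa": ",".join(f"{summary.gene_ppa[g]:.3g}" for g in genes)
                        if len(genes) else "--",
        })
    df = pd.DataFrame(rows)
    df = df.sort_values(["snp_ppa", "pos"], ascending=[False, True], kind="mergesort")
    return df.head(min(top_k, p)).reset_index(drop=True)
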