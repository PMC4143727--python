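"""Shared fixtures: small gene maps and an exactly enumerable model instance."""

import itertools

import numpy as np
import pytest
from scipy import sparse
from scipy.special import logsumexp

from latentgwas.io import GeneMap
from latentgwas.model import ModelConfig, marginal_log_likelihood, theta_prior_probs


def make_gene_map(p, gene_cols):
    """GeneMap over p SNPs from a list of per-gene SNP index lists."""
    rows, cols = [], []
    for g, snps in enumerate(gene_cols):
        rows.extend(snps)
        cols.extend([g] * len(snps))
    inc = sparse.csr_matrix((np.ones(len(rows), dtype=np.int8), (rows, cols)),
                            shape=(p, len(gene_cols)))
    genes = [(f"g{g}", "1", 1, 1) for g in range(len(gene_cols))]
    return GeneMap(genes=genes, incidence=inc)


def enumerate_exact_ppa(y, V, Z, gene_map, config, xi0, xi1, alpha):
    """Exact SNP and gene PPAs by full enumeration of all (theta, gamma) states.

    Independent oracle for the MCMC sampler: weights every binary state by
    marginal likelihood (dense n x n route) times hierarchy prior.
    """
    p = Z.shape[1]
    G = gene_map.n_genes
    log_w, states = [], []
    for th in itertools.product((0, 1), repeat=p):
        th_a = np.array(th)
        ll = marginal_log_likelihood(y, V, Z, th_a, config, method="dense")
        for ga in itertools.product((0, 1), repeat=G):
            ga_a = np.array(ga)
            pj = theta_prior_probs(xi0, xi1, ga_a, gene_map)
            lp = ll
            lp += float(np.sum(np.where(th_a == 1, np.log(pj), np.log1p(-pj))))
            lp += float(np.sum(np.where(ga_a == 1, np.log(alpha), np.log1p(-alpha))))
            log_w.append(lp)
            states.append((th_a, ga_a))
    w = np.exp(np.array(log_w) - logsumexp(log_w))
    ppa_theta = sum(wi * s[0] for wi, s in zip(w, states))
    ppa_gamma = sum(wi * s[1] for wi, s in zip(w, states))
    return ppa_theta, ppa_gamma


@pytest.fixture(scope="session")
def tiny_instance():
    """n=20, p=4, G=2 instance with a spread-out posterior; used by oracle tests."""
    rng = np.random.default_rng(42)
    n, p = 20, 4
    Z = rng.standard_normal((n, p))
    V = np.ones((n, 1))
    y = 1.5 * Z[:, 1] + 0.6 * Z[:, 2] + rng.standard_normal(n)
    gene_map = make_gene_map(p, [[0, 1], [2, 3]])
    config = ModelConfig(tau2=1.0, sigma2=1.0)
    return {"y": y, "V": V, "Z": Z, "gene_map": gene_map, "config": config,
            "xi0": -4.0, "xi1": 2.0, "alpha": 0.1}
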