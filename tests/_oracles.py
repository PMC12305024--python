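"""Independent oracles shared by the unit and acceptance suites.

Everything here deliberately avoids the package's own covariance/likelihood
code paths: pairwise matrices come from dendropy, densities from scipy, mean
weights from numerical quadrature.
"""

import dendropy
import numpy as np
from scipy import integrate, stats


def dendropy_shared_times(tree):
    """Tip MRCA-time and patristic matrices computed via dendropy."""
    labels = tree.tip_labels
    dt = dendropy.Tree.get(data=tree.to_newick(), schema="newick")
    pdm = dt.phylogenetic_distance_matrix()
    taxa = {tx.label: tx for tx in dt.taxon_namespace}
    n = len(labels)
    D = np.zeros((n, n))
    for i, a in enumerate(labels):
        for j, b in enumerate(labels):
            if i < j:
                D[i, j] = D[j, i] = pdm.patristic_distance(taxa[a], taxa[b])
    depth = tree.depth
    S = depth - D / 2.0
    np.fill_diagonal(S, depth)
    return S, D


def mvn_logpdf(y, mean, cov):
    return stats.multivariate_normal(mean=mean, cov=cov).logpdf(y)


def oum_mean_by_quadrature(rmap, alpha, theta):
    """Per-tip OUM expectations by numerically integrating the decay kernel."""
    tree = rmap.tree
    times = tree.node_times()
    mean = np.zeros(tree.n_tips)
    for a, tip in enumerate(tree.tips):
        T = times[tip]
        v = tip
        while v != tree.root:
            cursor = times[tree.parent[v]]
            for d, reg in rmap.histories[v]:
                w, _ = integrate.quad(
                    lambda t: alpha * np.exp(-alpha * (T - t)), cursor, cursor + d
                )
                mean[a] += theta[reg] * w
                cursor += d
            v = tree.parent[v]
        mean[a] += theta[rmap.root_regime] * np.exp(-alpha * T)
    return mean


def ou_cov_from_matrices(S, D, alpha, sigma2):
    return sigma2 / (2 * alpha) * np.exp(-alpha * D) * (1 - np.exp(-2 * alpha * S))


def bmm_cov_oracle(rmap, sigma2):
    """Pairwise regime-time covariance from the map's node profiles."""
    tree = rmap.tree
    prof = rmap.regime_times_to_nodes()
    mrca = tree.mrca_nodes()
    n = tree.n_tips
    cov = np.zeros((n, n))
    for a in range(n):
        for b in range(n):
            node = mrca[a, b] if a != b else tree.tips[a]
            cov[a, b] = sum(sigma2[k] * t for k, t in prof[node].items())
    return cov
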