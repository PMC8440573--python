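"""Hill-number node turnover between webs, PCoA and a permutation F test.

Pairwise dissimilarity follows the two-assemblage Hill decomposition with
equal weights: gamma is the Hill number of the pooled (mean) distribution,
alpha the power mean of order (1 - q) of the two assemblage Hill numbers
(geometric mean at q = 1), beta = gamma / alpha in [1, 2], and dissimilarity
= beta - 1 in [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np

__all__ = [
    "hill_number", "node_distribution", "pairwise_dissimilarity",
    "dissimilarity_matrix", "simpson_dissimilarity", "DissimilarityMatrix",
    "pcoa", "PCoAResult", "permutation_f", "PermanovaResult",
]


def _counts(web) -> dict:
    """Node -> abundance mapping from any supported web representation."""
    if hasattr(web, "read_counts"):
        return dict(web.read_counts)
    if isinstance(web, nx.Graph):
        return {n: web.nodes[n].get("reads", 1) for n in web.nodes}
    if isinstance(web, dict):
        return dict(web)
    return {n: 1 for n in web}  # bare iterable of nodes


def hill_number(p, q: float) -> float:
    """Effective number of types of order q for a probability vector.

    q = 0 gives the richness of the support, q = 1 the exponential of Shannon
    entropy, otherwise (sum p^q)^(1/(1-q)).
    """
    if q < 0:
        raise ValueError("Hill order q must be >= 0")
    p = np.asarray(p, dtype=float)
    if p.sum() <= 0:
        raise ValueError("distribution sums to zero")
    p = p / p.sum()
    p = p[p > 0]
    if q == 0:
        return float(len(p))
    if abs(q - 1.0) < 1e-12:
        return float(np.exp(-np.sum(p * np.log(p))))
    return float(np.sum(p ** q) ** (1.0 / (1.0 - q)))


def node_distribution(web, mode: str = "presence", universe=None) -> np.ndarray:
    """Probability vector over the pooled node universe.

    ``presence`` spreads mass uniformly over present nodes; ``reads`` uses
    read-count proportions.  Absent universe nodes get 0.
    """
    counts = _counts(web)
    if not counts:
        raise ValueError("empty web has no node distribution")
    if universe is None:
        universe = sorted(counts)
    if mode == "presence":
        vals = np.array([1.0 if n in counts else 0.0 for n in universe])
    elif mode == "reads":
        vals = np.array([float(counts.get(n, 0)) for n in universe])
    else:
        raise ValueError("mode must be 'presence' or 'reads'")
    total = vals.sum()
    if total <= 0:
        raise ValueError("web contributes no mass on the universe")
    return vals / total


def pairwise_dissimilarity(web1, web2, q: float = 0,
                           mode: str = "presence") -> float:
    """Hill-beta node-turnover dissimilarity between two webs, in [0, 1]."""
    c1, c2 = _counts(web1), _counts(web2)
    if not c1 or not c2:
        raise ValueError("cannot compare empty webs")
    universe = sorted(set(c1) | set(c2))
    p1 = node_distribution(c1, mode=mode, universe=universe)
    p2 = node_distribution(c2, mode=mode, universe=universe)
    gamma = hill_number((p1 + p2) / 2.0, q)
    d1, d2 = hill_number(p1, q), hill_number(p2, q)
    if abs(q - 1.0) < 1e-12:
        alpha = float(np.sqrt(d1 * d2))
    else:
        # power mean of order (1 - q) of the assemblage Hill numbers
        alpha = float(((d1 ** (1 - q) + d2 ** (1 - q)) / 2.0) ** (1.0 / (1 - q)))
    beta = gamma / alpha
    return float(min(max(beta - 1.0, 0.0), 1.0))


def simpson_dissimilarity(web1, web2) -> float:
    """Classical Simpson (turnover-component) dissimilarity, cross-check mode."""
    a = set(_counts(web1))
    b = set(_counts(web2))
    if not a or not b:
        raise ValueError("cannot compare empty webs")
    shared = len(a & b)
    only_a, only_b = len(a - b), len(b - a)
    m = min(only_a, only_b)
    if m + shared == 0:
        return 0.0
    return m / (m + shared)


@dataclass
class DissimilarityMatrix:
    labels: list
    D: np.ndarray
    q: float

    def validate(self) -> None:
        if not np.allclose(self.D, self.D.T, atol=1e-12):
            raise ValueError("dissimilarity matrix not symmetric")
        if np.abs(np.diagonal(self.D)).max() > 1e-12:
            raise ValueError("nonzero diagonal")
        if self.D.min() < -1e-12 or self.D.max() > 1.0 + 1e-12:
            raise ValueError("entries outside [0, 1]")


def dissimilarity_matrix(webs, q: float = 0, mode: str = "presence"
                         ) -> DissimilarityMatrix:
    """All-pairs node-turnover matrix; ``webs`` maps label -> web."""
    if not isinstance(webs, dict):
        webs = {i: w for i, w in enumerate(webs)}
    labels = list(webs)
    n = len(labels)
    if n < 2:
        raise ValueError("need at least 2 webs")
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = pairwise_dissimilarity(webs[labels[i]], webs[labels[j]],
                                       q=q, mode=mode)
            D[i, j] = D[j, i] = d
    return DissimilarityMatrix(labels=labels, D=D, q=q)


@dataclass
class PCoAResult:
    coordinates: np.ndarray        # n x k, axes ordered by eigenvalue
    eigenvalues: np.ndarray        # all n eigenvalues, descending
    variance_explained: np.ndarray  # per kept axis, relative to sum of positives


def pcoa(D) -> PCoAResult:
    """Principal coordinates via Gower double-centring of -D^2/2.

    Axes with non-positive eigenvalues are dropped from the coordinates but
    all eigenvalues are reported.
    """
    D = np.asarray(D, dtype=float)
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise ValueError("D must be square")
    if not np.allclose(D, D.T, atol=1e-10):
        raise ValueError("D must be symmetric")
    n = D.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D ** 2) @ J
    evals, evecs = np.linalg.eigh((B + B.T) / 2.0)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    pos = evals > max(evals.max(), 0) * 1e-12 if evals.max() > 0 else evals > 0
    coords = evecs[:, pos] * np.sqrt(evals[pos])
    total_pos = evals[pos].sum()
    var = evals[pos] / total_pos if total_pos > 0 else evals[pos]
    return PCoAResult(coordinates=coords, eigenvalues=evals,
                      variance_explained=var)


@dataclass
class PermanovaResult:
    df_between: int
    df_within: int
    F: float
    p: float
    n_perm: int
    seed: int | None


def _pseudo_f(d2: np.ndarray, codes: np.ndarray, n_groups: int) -> float:
    n = d2.shape[0]
    ss_total = d2[np.triu_indices(n, 1)].sum() / n
    ss_within = 0.0
    for g in range(n_groups):
        idx = np.flatnonzero(codes == g)
        if idx.size < 1:
            raise ValueError("empty group in permutation test")
        if idx.size > 1:
            sub = d2[np.ix_(idx, idx)]
            ss_within += sub[np.triu_indices(idx.size, 1)].sum() / idx.size
    ss_between = ss_total - ss_within
    df_b = n_groups - 1
    df_w = n - n_groups
    if ss_within <= 0:
        return np.inf if ss_between > 0 else 0.0
    return (ss_between / df_b) / (ss_within / df_w)


def permutation_f(D, grouping, n_perm: int = 999, seed: int | None = None
                  ) -> PermanovaResult:
    """Permutation pseudo-F test of a grouping factor on a distance matrix.

    Sums of squared dissimilarities partitioned as in one-way PERMANOVA;
    p = (1 + #{perm F >= observed F}) / (1 + n_perm).
    """
    D = np.asarray(D, dtype=float)
    labels = np.asarray(list(grouping))
    n = D.shape[0]
    if labels.shape[0] != n:
        raise ValueError("grouping length must match D")
    _, codes = np.unique(labels, return_inverse=True)
    n_groups = int(codes.max()) + 1
    if n_groups < 2:
        raise ValueError("need at least 2 groups")
    d2 = D ** 2
    f_obs = _pseudo_f(d2, codes, n_groups)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(codes)
        if _pseudo_f(d2, perm, n_groups) >= f_obs:
            count += 1
    return PermanovaResult(
        df_between=n_groups - 1, df_within=n - n_groups,
        F=float(f_obs), p=(1 + count) / (1 + n_perm),
        n_perm=n_perm, seed=seed,
    )
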