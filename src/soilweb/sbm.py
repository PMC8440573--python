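"""Directed Bernoulli stochastic block model fitted by variational EM.

Trophic groups are inferred by fitting the standard directed Bernoulli SBM
(no self-loops, binary adjacency) to the metaweb and selecting the number of
groups Q with the Integrated Complete-data Likelihood criterion:

    ICL(Q) = max_z log p(A, z | alpha_hat, pi_hat)
             - Q^2/2 * log(n(n-1)) - (Q-1)/2 * log n

The E-step is coordinate ascent on the node responsibilities (one row at a
time, which makes the ELBO provably non-decreasing); the M-step uses the
closed forms alpha_q = mean(tau_.q) and
pi_qr = sum_{i!=j} tau_iq tau_jr A_ij / sum_{i!=j} tau_iq tau_jr.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

log = logging.getLogger(__name__)

_EPS = 1e-12
_PCLIP = 1e-10


def _as_adjacency(a) -> np.ndarray:
    A = np.asarray(a, dtype=float)
    if A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise ValueError("adjacency must be square")
    if not np.isin(A, (0.0, 1.0)).all():
        raise ValueError("adjacency must be binary")
    if np.diagonal(A).any():
        raise ValueError("self-loops are not allowed")
    return A


@dataclass
class SBMFit:
    Q: int
    tau: np.ndarray          # n x Q, rows on the simplex
    alpha: np.ndarray        # Q group proportions
    pi: np.ndarray           # Q x Q connection probabilities (exact ratios)
    elbo_trace: list[float]
    icl: float = float("nan")
    converged: bool = False
    merged_groups: bool = False
    icl_table: list[tuple[int, float]] = field(default_factory=list)

    @property
    def elbo(self) -> float:
        return self.elbo_trace[-1]

    def hard_assignment(self) -> np.ndarray:
        return np.argmax(self.tau, axis=1)

    def to_dict(self) -> dict:
        return {
            "Q": int(self.Q),
            "alpha": self.alpha.tolist(),
            "pi": self.pi.tolist(),
            "elbo": float(self.elbo),
            "icl": float(self.icl),
            "converged": bool(self.converged),
            "merged_groups": bool(self.merged_groups),
            "icl_table": [[int(q), float(v)] for q, v in self.icl_table],
            "tau": self.tau.tolist(),
        }


def init_assignments(adjacency, Q: int, strategy: str = "spectral",
                     seed: int | None = None) -> np.ndarray:
    """Initial responsibility matrix.

    ``spectral`` runs k-means on the concatenated in/out neighbourhood
    profiles [A | A^T]; ``random`` draws rows uniformly on the simplex.  Hard
    labels are softened (0.9 on the winner) so no log(0) appears at step one.
    """
    A = _as_adjacency(adjacency)
    n = A.shape[0]
    if Q > n:
        raise ValueError(f"Q={Q} exceeds n={n}")
    if Q == 1:
        return np.ones((n, 1))
    rng = np.random.default_rng(seed)
    if strategy == "spectral":
        from sklearn.cluster import KMeans

        profiles = np.hstack([A, A.T])
        km = KMeans(n_clusters=Q, n_init=10,
                    random_state=int(rng.integers(2**31 - 1)))
        import warnings

        from sklearn.exceptions import ConvergenceWarning

        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            labels = km.fit_predict(profiles)
        tau = np.full((n, Q), 0.01 / (Q - 1))
        tau[np.arange(n), labels] = 0.99
        return tau
    if strategy == "random":
        # random hard labels, softened: near-uniform rows collapse to a
        # single block on small graphs, hard draws break the symmetry
        labels = rng.integers(0, Q, size=n)
        tau = np.full((n, Q), 0.01 / (Q - 1))
        tau[np.arange(n), labels] = 0.99
        return tau
    raise ValueError(f"unknown init strategy {strategy!r}")


def _log_pi(pi: np.ndarray):
    p = np.clip(pi, _PCLIP, 1.0 - _PCLIP)
    return np.log(p), np.log1p(-p)


def _elbo(A, tau, alpha, pi) -> float:
    lp, lm = _log_pi(pi)
    la = np.log(np.clip(alpha, _EPS, None))
    ent = float(np.sum(tau * (la[None, :] - np.log(np.clip(tau, _EPS, None)))))
    # sum over ordered pairs i != j of tau_iq tau_jr [A lp_qr + (1-A) lm_qr];
    # A has a zero diagonal so T1 needs no correction, the pair mass does
    T1 = tau.T @ A @ tau
    pair = (tau.sum(0)[:, None] * tau.sum(0)[None, :]) - (tau.T @ tau)
    like = float(np.sum(T1 * lp) + np.sum((pair - T1) * lm))
    return ent + like


def _update_tau_row(i, A, tau, la, lp, lm):
    """Closed-form optimum of row i given all other rows (coordinate ascent)."""
    a_out = A[i, :]
    a_in = A[:, i]
    w_out1 = a_out @ tau - a_out[i] * tau[i]
    w_in1 = a_in @ tau - a_in[i] * tau[i]
    tot = tau.sum(axis=0) - tau[i]
    w_out0 = tot - w_out1
    w_in0 = tot - w_in1
    logit = (
        la
        + lp @ w_out1 + lm @ w_out0          # edges/non-edges out of i
        + lp.T @ w_in1 + lm.T @ w_in0        # edges/non-edges into i
    )
    logit -= logit.max()
    t = np.exp(logit)
    return t / t.sum()


def _m_step(A, tau):
    n = A.shape[0]
    alpha = tau.mean(axis=0)
    T1 = tau.T @ A @ tau
    pair = (tau.sum(0)[:, None] * tau.sum(0)[None, :]) - (tau.T @ tau)
    with np.errstate(invalid="ignore", divide="ignore"):
        pi = np.where(pair > _EPS, T1 / np.maximum(pair, _EPS), 0.0)
    return alpha, np.clip(pi, 0.0, 1.0)


def vem_fit(adjacency, Q: int, tau0=None, tol: float = 1e-6,
            max_iter: int = 500, seed: int | None = None) -> SBMFit:
    """Variational EM for the directed Bernoulli SBM at fixed Q.

    One iteration = a full sweep of row-wise tau updates followed by the
    closed-form M-step; the recorded ELBO trace is non-decreasing.  Groups
    whose total responsibility mass drops below 1e-10 are merged away
    (Q reduced, flagged on the fit).
    """
    A = _as_adjacency(adjacency)
    n = A.shape[0]
    if tau0 is None:
        tau0 = init_assignments(A, Q, strategy="spectral", seed=seed)
    tau = np.asarray(tau0, dtype=float).copy()
    if tau.shape != (n, Q):
        raise ValueError(f"tau0 must be {n}x{Q}")
    if not np.allclose(tau.sum(axis=1), 1.0, atol=1e-8):
        raise ValueError("tau0 rows must sum to 1")
    merged = False
    alpha, pi = _m_step(A, tau)
    trace = [_elbo(A, tau, alpha, pi)]
    converged = False
    M = 1.0 - A
    np.fill_diagonal(M, 0.0)
    for _ in range(max_iter):
        la = np.log(np.clip(alpha, _EPS, None))
        lp, lm = _log_pi(pi)
        # fast path: simultaneous matrix-form update of every row; kept only
        # if the ELBO does not decrease, otherwise redo the sweep as strict
        # row-by-row coordinate ascent (provably monotone)
        logit = (la[None, :]
                 + A @ tau @ lp.T + M @ tau @ lm.T
                 + A.T @ tau @ lp + M.T @ tau @ lm)
        logit -= logit.max(axis=1, keepdims=True)
        cand = np.exp(logit)
        cand /= cand.sum(axis=1, keepdims=True)
        a_c, p_c = _m_step(A, cand)
        if _elbo(A, cand, a_c, p_c) >= trace[-1] - 1e-9:
            tau = cand
        else:
            for i in range(n):
                tau[i] = _update_tau_row(i, A, tau, la, lp, lm)
        # merge degenerate groups before the M-step
        mass = tau.sum(axis=0)
        if (mass < 1e-10).any() and tau.shape[1] > 1:
            keep = mass >= 1e-10
            if keep.sum() == 0:
                keep[np.argmax(mass)] = True
            tau = tau[:, keep]
            tau = tau / tau.sum(axis=1, keepdims=True)
            merged = True
            log.info("vem_fit: merged %d empty group(s), Q -> %d",
                     int((~keep).sum()), tau.shape[1])
        alpha, pi = _m_step(A, tau)
        trace.append(_elbo(A, tau, alpha, pi))
        if abs(trace[-1] - trace[-2]) < tol:
            converged = True
            break
    return SBMFit(Q=tau.shape[1], tau=tau, alpha=alpha, pi=pi,
                  elbo_trace=trace, converged=converged, merged_groups=merged)


def complete_data_loglik(adjacency, labels) -> float:
    """Max complete-data log-likelihood of a hard assignment.

    Evaluated at the MLE (alpha, pi) implied by the labels; empty groups and
    degenerate blocks contribute 0 via the 0*log(0) = 0 convention.
    """
    A = _as_adjacency(adjacency)
    n = A.shape[0]
    z = np.asarray(labels, dtype=int)
    groups = np.unique(z)
    ll = 0.0
    counts = {q: int((z == q).sum()) for q in groups}
    for q in groups:
        ll += counts[q] * np.log(counts[q] / n)
    for q in groups:
        for r in groups:
            mask_q = z == q
            mask_r = z == r
            m = counts[q] * counts[r] - (counts[q] if q == r else 0)
            if m == 0:
                continue
            e = float(A[np.ix_(mask_q, mask_r)].sum())
            p = e / m
            if 0.0 < p < 1.0:
                ll += e * np.log(p) + (m - e) * np.log1p(-p)
    return float(ll)


def refine_labels(adjacency, labels, Q: int, max_passes: int = 10):
    """Kernighan-Lin-style polish of a hard assignment.

    Each pass makes a sequence of forced best single-node moves (each node
    moves at most once per pass, moves may temporarily worsen the objective)
    and keeps the best labeling seen; passes repeat while they improve.  This
    crosses the shallow valleys that trap mean-field updates on small sparse
    graphs.  Returns ``(labels, complete_data_loglik)``.
    """
    A = _as_adjacency(adjacency)
    z = np.asarray(labels, dtype=int).copy()
    n = len(z)
    best_z, best_c = z.copy(), complete_data_loglik(A, z)
    for _ in range(max_passes):
        work = z.copy()
        moved: set[int] = set()
        pass_best_c, pass_best_z = best_c, best_z.copy()
        for _ in range(n):
            cand = None
            for i in range(n):
                if i in moved:
                    continue
                old = work[i]
                for q in range(Q):
                    if q == old:
                        continue
                    work[i] = q
                    c = complete_data_loglik(A, work)
                    if cand is None or c > cand[0]:
                        cand = (c, i, q)
                work[i] = old
            if cand is None:
                break
            c, i, q = cand
            work[i] = q
            moved.add(i)
            if c > pass_best_c + 1e-12:
                pass_best_c, pass_best_z = c, work.copy()
        if pass_best_c > best_c + 1e-12:
            best_c, best_z = pass_best_c, pass_best_z
            z = best_z.copy()
        else:
            break
    return best_z, best_c


def icl_score(fit: SBMFit, adjacency) -> float:
    """ICL of a fit: hard-assignment complete-data likelihood minus penalty."""
    A = _as_adjacency(adjacency)
    n = A.shape[0]
    z = fit.hard_assignment()
    Q = fit.Q
    ll = complete_data_loglik(A, z)
    penalty = 0.5 * Q * Q * np.log(n * (n - 1)) + 0.5 * (Q - 1) * np.log(n)
    return float(ll - penalty)


def select_Q(adjacency, Q_range=range(1, 9), restarts: int = 10,
             seed: int | None = None, tol: float = 1e-6,
             max_iter: int = 500, refine_max_n: int = 40) -> SBMFit:
    """Best-ICL fit over a grid of group counts with multiple restarts.

    For each Q the best-ELBO fit over one spectral and ``restarts - 1`` random
    initializations is scored; on small graphs (n <= ``refine_max_n``) the
    hard assignment is additionally polished with ``refine_labels`` and VEM is
    warm-restarted from the improved labeling.  Ties in ICL go to the smallest
    Q.  The winning fit carries the full (Q, ICL) table.
    """
    A = _as_adjacency(adjacency)
    n = A.shape[0]
    Qs = [q for q in Q_range if 1 <= q <= n]
    if not Qs:
        raise ValueError("empty Q_range")
    rng = np.random.default_rng(seed)
    best_fit = None
    table: list[tuple[int, float]] = []
    for Q in sorted(Qs):
        best_q = None
        strategies = ["spectral"] + ["random"] * max(restarts - 1, 0)
        for strat in strategies:
            tau0 = init_assignments(A, Q, strategy=strat,
                                    seed=int(rng.integers(2**31 - 1)))
            fit = vem_fit(A, Q, tau0=tau0, tol=tol, max_iter=max_iter)
            if best_q is None or fit.elbo > best_q.elbo:
                best_q = fit
        if Q > 1 and n <= refine_max_n and best_q.Q == Q:
            z = best_q.hard_assignment()
            z_ref, c_ref = refine_labels(A, z, Q)
            if c_ref > complete_data_loglik(A, z) + 1e-12:
                tau0 = np.full((n, Q), 0.01 / (Q - 1))
                tau0[np.arange(n), z_ref] = 0.99
                warm = vem_fit(A, Q, tau0=tau0, tol=tol, max_iter=max_iter)
                if warm.elbo > best_q.elbo:
                    best_q = warm
        best_q.icl = icl_score(best_q, A)
        table.append((Q, best_q.icl))
        if best_fit is None or best_q.icl > best_fit.icl + 1e-12:
            best_fit = best_q
    best_fit.icl_table = table
    return best_fit


@dataclass
class GroupMetaweb:
    """Group-level metaweb: Q nodes, pi-weighted edges, hard memberships."""

    membership: dict[str, int]
    pi: np.ndarray
    alpha: np.ndarray
    group_guild: dict[int, str] = field(default_factory=dict)

    @property
    def Q(self) -> int:
        return len(self.alpha)

    def graph(self, threshold: float = 0.0):
        import networkx as nx

        g = nx.DiGraph()
        g.add_nodes_from(range(self.Q))
        for q in range(self.Q):
            for r in range(self.Q):
                if self.pi[q, r] > threshold:
                    g.add_edge(q, r, weight=float(self.pi[q, r]))
        return g


def group_metaweb(fit: SBMFit, node_ids, guilds: dict[str, str] | None = None
                  ) -> GroupMetaweb:
    """Collapse a fitted SBM to the trophic-group metaweb.

    Memberships are argmax responsibilities; group-pair edge weights are the
    fitted pi; the guild label of each group is the majority guild of its
    members when guild annotations are supplied.
    """
    node_ids = list(node_ids)
    if len(node_ids) != fit.tau.shape[0]:
        raise ValueError("node_ids length does not match fit")
    z = fit.hard_assignment()
    membership = {node: int(q) for node, q in zip(node_ids, z)}
    group_guild: dict[int, str] = {}
    if guilds:
        for q in range(fit.Q):
            members = [n for n in node_ids if membership[n] == q]
            labels = [guilds[n] for n in members if n in guilds]
            if labels:
                vals, counts = np.unique(labels, return_counts=True)
                group_guild[q] = str(vals[np.argmax(counts)])
    return GroupMetaweb(membership=membership, pi=fit.pi.copy(),
                        alpha=fit.alpha.copy(), group_guild=group_guild)
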