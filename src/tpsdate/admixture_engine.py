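"""Maximum-likelihood admixture estimation by EM.

Implements the binomial admixture model: individual *i*'s genotype at SNP
*j* is Binomial(2, f_ij) with f_ij = sum_k q_ik p_kj, where Q rows are
mixing proportions on the simplex and P holds per-component allele
frequencies. Two modes mirror the standard workflow:

* unsupervised — Q and P estimated jointly;
* supervised — labelled reference individuals' Q rows are pinned to unit
  vectors, which fixes each component's meaning; unlabelled rows are the
  projections of interest. With P fixed the per-sample subproblem is
  concave, so per-sample projections are order-independent.

EM is used instead of a quasi-Newton optimizer: it is slower but monotone
in the log-likelihood on every step, which the tests assert directly.
Missing genotypes are dropped from all sums (no imputation). P is clamped
to [1e-6, 1 - 1e-6] so the likelihood stays finite for genotypes sampled
outside a component's support.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .io_formats import MISSING, GenotypeMatrix

__all__ = [
    "P_CLAMP",
    "AdmixtureFit",
    "loglikelihood",
    "em_step",
    "fit_unsupervised",
    "fit_supervised",
    "project_samples",
]

#: Allele-frequency box clamp keeping the likelihood finite.
P_CLAMP: float = 1e-6

_SIMPLEX_ATOL = 1e-5


@dataclass
class AdmixtureFit:
    """Result of an EM fit."""

    Q: np.ndarray            # (n_samples, K) mixing fractions
    P: np.ndarray            # (K, n_snps) allele frequencies
    loglik: float
    n_iter: int
    converged: bool
    seed: int
    loglik_trace: np.ndarray = field(default_factory=lambda: np.empty(0))
    sample_ids: list[str] | None = None


def _as_calls(G) -> np.ndarray:
    if isinstance(G, GenotypeMatrix):
        return G.calls
    return np.asarray(G)


def _check_state(G: np.ndarray, Q: np.ndarray, P: np.ndarray) -> None:
    n, m = G.shape
    if Q.shape[0] != n or P.shape[1] != m or Q.shape[1] != P.shape[0]:
        raise ValueError(
            f"dimension mismatch: G{G.shape}, Q{Q.shape}, P{P.shape}"
        )
    rowsum = Q.sum(axis=1)
    if not np.allclose(rowsum, 1.0, atol=_SIMPLEX_ATOL):
        bad = int(np.argmax(np.abs(rowsum - 1.0)))
        raise ValueError(f"Q row {bad} off the simplex (sum {rowsum[bad]:.6g})")
    if (Q < -_SIMPLEX_ATOL).any() or (Q > 1 + _SIMPLEX_ATOL).any():
        raise ValueError("Q entries outside [0, 1]")


def loglikelihood(G, Q: np.ndarray, P: np.ndarray) -> float:
    """Binomial admixture log-likelihood over non-missing genotype cells.

    ``sum_ij g_ij ln(f_ij) + (2 - g_ij) ln(1 - f_ij)`` with
    ``f = Q @ P``; cells with missing genotype contribute nothing, so an
    all-missing matrix scores 0.
    """
    G = _as_calls(G)
    _check_state(G, Q, P)
    mask = G != MISSING
    if not mask.any():
        return 0.0
    F = np.clip(Q @ P, P_CLAMP, 1.0 - P_CLAMP)
    g = np.where(mask, G, 0).astype(float)
    ll = g * np.log(F) + (2.0 - g) * np.log1p(-F)
    return float(ll[mask].sum())


def em_step(
    G,
    Q: np.ndarray,
    P: np.ndarray,
    update_P: bool = True,
    frozen_rows: Iterable[int] | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """One EM step; never decreases the log-likelihood.

    Responsibilities split each observed allele count between components in
    proportion to q_ik p_kj (counted allele) and q_ik (1 - p_kj) (other
    allele). Q rows listed in ``frozen_rows`` are left untouched (supervised
    references); their responsibilities still inform the P update. With
    ``update_P`` false, P is returned unchanged (pure projection step).
    """
    G = _as_calls(G)
    _check_state(G, Q, P)
    mask = G != MISSING
    M = mask.sum(axis=1)
    if (M == 0).any():
        bad = int(np.argmax(M == 0))
        raise ValueError(f"sample index {bad} has no observed genotypes")

    g = np.where(mask, G, 0).astype(float)
    two_minus_g = np.where(mask, 2.0 - g, 0.0)
    F = np.clip(Q @ P, P_CLAMP, 1.0 - P_CLAMP)
    Rg = g / F                      # zero where missing (g = 0 there)
    Rb = two_minus_g / (1.0 - F)

    Q_new = Q * (Rg @ P.T + Rb @ (1.0 - P).T) / (2.0 * M)[:, None]
    # guard tiny float drift off the simplex
    Q_new /= Q_new.sum(axis=1, keepdims=True)
    if frozen_rows is not None:
        idx = np.fromiter(frozen_rows, dtype=int)
        if idx.size:
            Q_new[idx] = Q[idx]

    if update_P:
        A = P * (Q.T @ Rg)          # expected counted-allele counts
        B = (1.0 - P) * (Q.T @ Rb)  # expected other-allele counts
        denom = A + B
        with np.errstate(invalid="ignore", divide="ignore"):
            P_new = np.where(denom > 0, A / np.maximum(denom, 1e-300), P)
        P_new = np.clip(P_new, P_CLAMP, 1.0 - P_CLAMP)
    else:
        P_new = P
    return Q_new, P_new


def _iterate(
    G: np.ndarray,
    Q: np.ndarray,
    P: np.ndarray,
    *,
    update_P: bool,
    frozen_rows: Sequence[int] | None,
    tol: float,
    max_iter: int,
    seed: int,
) -> AdmixtureFit:
    trace = [loglikelihood(G, Q, P)]
    converged = False
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        Q, P = em_step(G, Q, P, update_P=update_P, frozen_rows=frozen_rows)
        ll = loglikelihood(G, Q, P)
        trace.append(ll)
        prev = trace[-2]
        if abs(ll - prev) <= tol * max(abs(prev), 1.0):
            converged = True
            break
    return AdmixtureFit(
        Q=Q,
        P=P,
        loglik=trace[-1],
        n_iter=n_iter,
        converged=converged,
        seed=seed,
        loglik_trace=np.asarray(trace),
    )


def fit_unsupervised(
    G,
    K: int,
    seed: int = 0,
    tol: float = 1e-6,
    max_iter: int = 500,
) -> AdmixtureFit:
    """Joint estimation of Q and P for ``K`` components.

    Q is initialised from a seeded flat Dirichlet; P from the per-SNP
    observed frequency plus uniform jitter. Non-convergence within
    ``max_iter`` returns the best state with ``converged=False`` rather
    than raising.
    """
    calls = _as_calls(G)
    n, m = calls.shape
    if K < 1:
        raise ValueError("K must be >= 1")
    if n < K:
        raise ValueError(f"need at least K={K} samples, got {n}")
    rng = np.random.default_rng(seed)
    Q0 = rng.dirichlet(np.ones(K), size=n)
    mask = calls != MISSING
    with np.errstate(invalid="ignore"):
        freq = np.where(mask, calls, 0).sum(axis=0) / np.maximum(
            2.0 * mask.sum(axis=0), 1.0
        )
    P0 = freq[None, :] + rng.uniform(-0.1, 0.1, size=(K, m))
    P0 = np.clip(P0, P_CLAMP, 1.0 - P_CLAMP)
    fit = _iterate(
        calls, Q0, P0, update_P=True, frozen_rows=None,
        tol=tol, max_iter=max_iter, seed=seed,
    )
    if isinstance(G, GenotypeMatrix):
        fit.sample_ids = list(G.sample_ids)
    return fit


def fit_supervised(
    G_all,
    labels: Mapping[int, int] | Mapping[str, int],
    K: int,
    seed: int = 0,
    tol: float = 1e-6,
    max_iter: int = 300,
    p_from_labels_only: bool = False,
) -> AdmixtureFit:
    """Supervised projection against components fixed by labelled samples.

    ``labels`` maps sample (row index, or sample id for a
    :class:`GenotypeMatrix`) to a component index in ``[0, K)``. Labelled
    rows' Q are frozen at unit vectors and P is initialised from their
    empirical frequencies. By default the P update uses labelled *and*
    unlabelled responsibilities (full EM); ``p_from_labels_only`` keeps P at
    its label-derived initialisation, which with ~15 references per
    component is near-identical and slightly faster.
    """
    calls = _as_calls(G_all)
    n, m = calls.shape
    if isinstance(G_all, GenotypeMatrix) and labels and isinstance(
        next(iter(labels.keys())), str
    ):
        id_to_row = {sid: i for i, sid in enumerate(G_all.sample_ids)}
        labels = {id_to_row[sid]: k for sid, k in labels.items()}

    label_rows = np.fromiter(labels.keys(), dtype=int)
    label_comps = np.fromiter(labels.values(), dtype=int)
    for k in range(K):
        if not (label_comps == k).any():
            raise ValueError(f"component {k} has no labelled samples")

    mask = calls != MISSING
    M = mask.sum(axis=1)
    if (M == 0).any():
        bad = int(np.argmax(M == 0))
        name = G_all.sample_ids[bad] if isinstance(G_all, GenotypeMatrix) else bad
        raise ValueError(f"sample {name} has no observed genotypes")

    # symmetric init: keeps the fit equivariant to label permutation and
    # invariant to sample order (the Q subproblem is concave given P)
    Q0 = np.full((n, K), 1.0 / K)
    Q0[label_rows] = np.eye(K)[label_comps]

    # per-component empirical frequencies from labelled samples
    P0 = np.empty((K, m))
    g0 = np.where(mask, calls, 0).astype(float)
    for k in range(K):
        rows = label_rows[label_comps == k]
        counts = g0[rows].sum(axis=0)
        denom = 2.0 * mask[rows].sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            pk = np.where(denom > 0, counts / np.maximum(denom, 1.0), 0.5)
        P0[k] = pk
    P0 = np.clip(P0, P_CLAMP, 1.0 - P_CLAMP)

    fit = _iterate(
        calls, Q0, P0,
        update_P=not p_from_labels_only,
        frozen_rows=label_rows,
        tol=tol, max_iter=max_iter, seed=seed,
    )
    if isinstance(G_all, GenotypeMatrix):
        fit.sample_ids = list(G_all.sample_ids)
    return fit


def project_samples(
    G,
    P: np.ndarray,
    seed: int = 0,
    tol: float = 1e-6,
    max_iter: int = 300,
) -> AdmixtureFit:
    """Estimate Q for new samples against a fixed P.

    The per-sample subproblem is concave, so EM converges to the global
    projection independently of sample order.
    """
    calls = _as_calls(G)
    n = calls.shape[0]
    K = P.shape[0]
    Q0 = np.full((n, K), 1.0 / K)
    fit = _iterate(
        calls, Q0, np.clip(P, P_CLAMP, 1.0 - P_CLAMP),
        update_P=False, frozen_rows=None,
        tol=tol, max_iter=max_iter, seed=seed,
    )
    if isinstance(G, GenotypeMatrix):
        fit.sample_ids = list(G.sample_ids)
    return fit
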