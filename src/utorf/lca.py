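"""Latent class analysis of binned locus features.

A latent class model supposes the loci are a finite mixture of K
subpopulations; within a class the categorical indicators are independent,
with class-specific level probabilities rho[j][k][l] and mixing weights pi.
The model is fit by EM from many random restarts; the number of classes is
chosen by minimizing BIC (with AIC reported) among models that converged to
a unique top likelihood — a K whose restarts tie at the top with distinct
parameter sets signals under-identification and is excluded. Each locus is
assigned to its modal posterior class.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

_RHO_FLOOR = 1e-10


@dataclass(frozen=True)
class BinningRules:
    """Default discretization of the continuous locus features.

    Bin edges are half-open on the right (the printed bin boundaries overlap
    at 0.2/0.8 and 20/50; we resolve them as [lo, hi)).
    """

    phastcons_edges: Tuple[float, ...] = (0.0, 0.2, 0.8, 1.0)
    length_edges: Tuple[float, ...] = (0.0, 20.0, 50.0, float("inf"))
    tpm_cut: float = 0.1
    specificity_cut: float = 0.8


def bin_features(
    raw: pd.DataFrame, rules: BinningRules = BinningRules()
) -> pd.DataFrame:
    """Map raw per-locus features to categorical indicators.

    Recognized columns (others pass through unchanged if already
    categorical/integer): ``phastcons`` -> {0: [0,0.2), 1: [0.2,0.8),
    2: [0.8,1.0]}; ``length_aa`` -> {0: short <20, 1: medium [20,50),
    2: long >=50}; ``max_tpm`` -> {0: <=cut, 1: >cut}; ``tissue_tau`` and
    ``stage_tau`` -> {0: <=cut, 1: >cut}. Rows with any missing value are
    flagged via the returned frame's NaN cells; callers drop them before
    fitting.
    """
    out = pd.DataFrame(index=raw.index)
    for col in raw.columns:
        x = raw[col]
        if col == "phastcons":
            if ((x < 0) | (x > 1)).any():
                raise ValueError("phastCons score out of [0, 1]")
            out[col] = np.where(
                x.isna(), np.nan, np.digitize(x.fillna(0), rules.phastcons_edges[1:-1])
            )
        elif col == "length_aa":
            if (x < 0).any():
                raise ValueError("negative length")
            out[col] = np.where(
                x.isna(), np.nan, np.digitize(x.fillna(0), rules.length_edges[1:-1])
            )
        elif col == "max_tpm":
            if (x < 0).any():
                raise ValueError("negative TPM")
            out[col] = np.where(x.isna(), np.nan, (x > rules.tpm_cut).astype(float))
        elif col in ("tissue_tau", "stage_tau"):
            if ((x < 0) | (x > 1)).any():
                raise ValueError("tau out of [0, 1]")
            out[col] = np.where(
                x.isna(), np.nan, (x > rules.specificity_cut).astype(float)
            )
        else:
            out[col] = x.astype(float)
    return out


@dataclass
class LcaModel:
    """A fitted latent class model."""

    K: int
    pi: np.ndarray  # (K,)
    rho: List[np.ndarray]  # per indicator j: (K, L_j)
    log_likelihood: float
    n_params: int
    aic: float
    bic: float
    n_obs: int
    converged: bool
    n_distinct_optima: int
    columns: Tuple[str, ...] = ()


def _encode_table(table: pd.DataFrame) -> Tuple[np.ndarray, List[int]]:
    if table.isna().any().any():
        raise ValueError("table has missing values; exclude those rows first")
    X = table.to_numpy()
    X = X.astype(int)
    levels = [int(X[:, j].max()) + 1 for j in range(X.shape[1])]
    if (X < 0).any():
        raise ValueError("negative level codes")
    return X, levels


def _onehots(X: np.ndarray, levels: List[int]) -> List[np.ndarray]:
    return [np.eye(L)[X[:, j]] for j, L in enumerate(levels)]


def _log_components(
    pi: np.ndarray, rho: List[np.ndarray], onehots: List[np.ndarray]
) -> np.ndarray:
    """log(pi_k) + sum_j log rho_j[k, x_nj], shape (n, K)."""
    n = onehots[0].shape[0]
    lp = np.tile(np.log(pi), (n, 1))
    for oh, r in zip(onehots, rho):
        lp += oh @ np.log(np.clip(r, _RHO_FLOOR, None)).T
    return lp


def log_likelihood(
    pi: np.ndarray, rho: List[np.ndarray], table: pd.DataFrame
) -> float:
    """Mixture log-likelihood at given parameters (independent oracle for the
    value reported by :func:`fit_lca`)."""
    X, levels = _encode_table(table)
    lp = _log_components(pi, rho, _onehots(X, levels))
    m = lp.max(axis=1, keepdims=True)
    return float((m[:, 0] + np.log(np.exp(lp - m).sum(axis=1))).sum())


def _em_once(
    onehots: List[np.ndarray],
    levels: List[int],
    K: int,
    rng: Optional[np.random.Generator],
    tol: float,
    max_iter: int,
    init: Optional[Tuple[np.ndarray, List[np.ndarray]]] = None,
) -> Tuple[np.ndarray, List[np.ndarray], float, bool]:
    if init is not None:
        pi, rho = init[0].copy(), [r.copy() for r in init[1]]
    else:
        assert rng is not None
        pi = np.full(K, 1.0 / K)
        rho = [rng.dirichlet(np.ones(L), size=K) for L in levels]
    prev = -np.inf
    converged = False
    for _ in range(max_iter):
        lp = _log_components(pi, rho, onehots)
        m = lp.max(axis=1, keepdims=True)
        w = np.exp(lp - m)
        denom = w.sum(axis=1, keepdims=True)
        resp = w / denom
        ll = float((m[:, 0] + np.log(denom[:, 0])).sum())
        # EM ascent invariant: the log-likelihood never decreases.
        if ll < prev - 1e-9:
            raise RuntimeError("EM log-likelihood decreased")
        if ll - prev < tol:
            prev = ll
            converged = True
            break
        prev = ll
        pi = resp.mean(axis=0)
        pi = np.clip(pi, _RHO_FLOOR, None)
        pi /= pi.sum()
        rho = []
        for oh in onehots:
            r = resp.T @ oh
            r = np.clip(r, _RHO_FLOOR, None)
            rho.append(r / r.sum(axis=1, keepdims=True))
    return pi, rho, prev, converged


def _sorted_params(pi: np.ndarray, rho: List[np.ndarray]) -> np.ndarray:
    order = np.argsort(-pi, kind="stable")
    return np.concatenate([pi[order]] + [r[order].ravel() for r in rho])


def n_parameters(K: int, levels: Sequence[int]) -> int:
    return (K - 1) + K * sum(L - 1 for L in levels)


def fit_lca(
    table: pd.DataFrame,
    K: int,
    n_restarts: int = 100,
    tol: float = 1e-8,
    max_iter: int = 5000,
    seed: int = 0,
) -> LcaModel:
    """Fit a K-class latent class model by EM from random restarts.

    Restarts draw conditionals from a flat Dirichlet with uniform mixing.
    Each restart runs a bounded burn-in; only the top restarts by burn-in
    log-likelihood are polished to full convergence (the standard short-run
    EM strategy). The best log-likelihood is returned; polished restarts
    tying at the top with materially different parameters are recorded as
    distinct optima (an under-identification signal). Class labels are
    ordered by decreasing pi for reporting stability.
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    X, levels = _encode_table(table)
    n_patterns = len({tuple(row) for row in X})
    if K > n_patterns:
        raise ValueError(
            f"K={K} exceeds the {n_patterns} distinct response patterns"
        )
    onehots = _onehots(X, levels)
    n = X.shape[0]
    rng = np.random.default_rng(seed)
    burn_iter = min(100, max_iter)
    short: List[Tuple[float, np.ndarray, List[np.ndarray]]] = []
    for _ in range(n_restarts):
        pi, rho, ll, _ = _em_once(onehots, levels, K, rng, tol, burn_iter)
        short.append((ll, pi, rho))
    short.sort(key=lambda t: -t[0])
    n_polish = min(len(short), max(5, n_restarts // 10))
    tops: List[Tuple[float, np.ndarray]] = []
    best: Optional[Tuple[np.ndarray, List[np.ndarray], float, bool]] = None
    for _, pi0, rho0 in short[:n_polish]:
        pi, rho, ll, conv = _em_once(
            onehots, levels, K, None, tol, max_iter, init=(pi0, rho0)
        )
        tops.append((ll, _sorted_params(pi, rho)))
        if best is None or ll > best[2]:
            best = (pi, rho, ll, conv)
    assert best is not None
    pi, rho, ll, conv = best
    order = np.argsort(-pi, kind="stable")
    pi = pi[order]
    rho = [r[order] for r in rho]
    # count distinct parameter sets among restarts tied at the top likelihood
    tied = [p for l, p in tops if abs(l - ll) < 1e-4]
    distinct = 1
    ref = _sorted_params(pi, rho)
    for p in tied:
        if np.max(np.abs(p - ref)) > 1e-2:
            distinct += 1
            break
    npar = n_parameters(K, levels)
    return LcaModel(
        K=K,
        pi=pi,
        rho=rho,
        log_likelihood=ll,
        n_params=npar,
        aic=-2.0 * ll + 2.0 * npar,
        bic=-2.0 * ll + npar * np.log(n),
        n_obs=n,
        converged=conv,
        n_distinct_optima=distinct,
        columns=tuple(table.columns),
    )


def information_criteria(model: LcaModel, n: Optional[int] = None) -> Dict[str, float]:
    """AIC = -2 logL + 2 p; BIC = -2 logL + p ln n."""
    n = model.n_obs if n is None else n
    return {
        "AIC": -2.0 * model.log_likelihood + 2.0 * model.n_params,
        "BIC": -2.0 * model.log_likelihood + model.n_params * float(np.log(n)),
    }


def select_classes(models: Mapping[int, LcaModel]) -> Tuple[int, pd.DataFrame]:
    """Choose K by minimal BIC among converged, uniquely identified models.

    Models that failed to converge or whose restarts tied at the top with
    distinct parameter sets are excluded. Returns the chosen K and a report
    table (per K: logL, AIC, BIC, eligibility)."""
    rows = []
    eligible: Dict[int, LcaModel] = {}
    for K in sorted(models):
        m = models[K]
        ok = m.converged and m.n_distinct_optima == 1
        rows.append(
            {
                "K": K,
                "logL": m.log_likelihood,
                "AIC": m.aic,
                "BIC": m.bic,
                "converged": m.converged,
                "n_distinct_optima": m.n_distinct_optima,
                "eligible": ok,
            }
        )
        if ok:
            eligible[K] = m
    if not eligible:
        raise ValueError("no converged, uniquely identified model")
    report = pd.DataFrame(rows).set_index("K")
    chosen = min(eligible, key=lambda K: eligible[K].bic)
    report["chosen"] = report.index == chosen
    aic_choice = min(eligible, key=lambda K: eligible[K].aic)
    report.attrs["aic_agrees"] = aic_choice == chosen
    return chosen, report


@dataclass
class PosteriorAssignment:
    posteriors: pd.DataFrame  # rows = loci, columns = class indices
    modal_class: pd.Series  # argmax posterior; ties -> lowest class index


def posterior_assign(model: LcaModel, table: pd.DataFrame) -> PosteriorAssignment:
    """Bayes-rule posterior class membership per row plus modal assignment."""
    X, levels = _encode_table(table)
    for j, L in enumerate(levels):
        if model.rho[j].shape[1] < L:
            raise ValueError(f"column {table.columns[j]!r} has unseen levels")
    onehots = [np.eye(model.rho[j].shape[1])[X[:, j]] for j in range(X.shape[1])]
    lp = _log_components(model.pi, model.rho, onehots)
    m = lp.max(axis=1, keepdims=True)
    w = np.exp(lp - m)
    post = w / w.sum(axis=1, keepdims=True)
    posteriors = pd.DataFrame(post, index=table.index)
    modal = pd.Series(np.argmax(post, axis=1), index=table.index, name="modal_class")
    return PosteriorAssignment(posteriors=posteriors, modal_class=modal)


def align_labels(true_labels: np.ndarray, predicted: np.ndarray, K: int) -> np.ndarray:
    """Greedy best label permutation mapping predicted classes onto true
    classes (for parameter-recovery checks)."""
    from itertools import permutations

    best_perm = None
    best_hits = -1
    for perm in permutations(range(K)):
        mapped = np.array([perm[p] for p in predicted])
        hits = int((mapped == true_labels).sum())
        if hits > best_hits:
            best_hits, best_perm = hits, perm
    return np.array([best_perm[p] for p in predicted])
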