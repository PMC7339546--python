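"""Two-state beta-binomial hidden Markov model for methylome segmentation.

Observations are (methylated, total) read-count pairs along ordered CpG
sites or tiled windows.  Each state emits counts from a beta-binomial
distribution, which absorbs the extra-binomial dispersion of bisulfite
data; state 0 is always the low-methylation state (HMR or PMD) and state 1
the highly methylated background.

Fitting is Baum-Welch with a method-of-moments M-step for the emission
parameters: the posterior-weighted mean and variance of per-site
methylation fractions determine each state's mean and intra-class
correlation.  A moments update is not guaranteed to increase the
likelihood, so any update that would decrease it (beyond numerical slack)
is rejected and the fit stops at the previous parameters; the recorded
log-likelihood trace is therefore non-decreasing by construction.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.special import betaln, gammaln

_EPS = 1e-300


@dataclass(frozen=True, slots=True)
class BetaBinomialEmission:
    alpha: float
    beta: float

    def __post_init__(self) -> None:
        if self.alpha <= 0 or self.beta <= 0:
            raise ValueError("alpha and beta must be positive")

    @property
    def mean(self) -> float:
        return self.alpha / (self.alpha + self.beta)

    @property
    def icc(self) -> float:
        """Intra-class correlation (overdispersion), 1/(alpha+beta+1)."""
        return 1.0 / (self.alpha + self.beta + 1.0)

    @classmethod
    def from_moments(cls, mean: float, icc: float) -> "BetaBinomialEmission":
        mean = float(np.clip(mean, 1e-4, 1 - 1e-4))
        icc = float(np.clip(icc, 1e-6, 0.5))
        conc = 1.0 / icc - 1.0
        return cls(mean * conc, (1.0 - mean) * conc)

    def logpmf(self, meth: np.ndarray, total: np.ndarray) -> np.ndarray:
        m = np.asarray(meth, dtype=np.float64)
        n = np.asarray(total, dtype=np.float64)
        return (gammaln(n + 1) - gammaln(m + 1) - gammaln(n - m + 1)
                + betaln(m + self.alpha, n - m + self.beta)
                - betaln(self.alpha, self.beta))


@dataclass(frozen=True, slots=True)
class HMMModel:
    initial: np.ndarray        # (2,)
    transition: np.ndarray     # (2, 2), rows sum to 1
    emissions: tuple[BetaBinomialEmission, BetaBinomialEmission]

    def __post_init__(self) -> None:
        t = np.asarray(self.transition, dtype=float)
        if t.shape != (2, 2) or not np.allclose(t.sum(axis=1), 1.0, atol=1e-8):
            raise ValueError("transition rows must sum to 1")
        if self.emissions[0].mean >= self.emissions[1].mean:
            raise ValueError("state 0 mean must be below state 1 mean")

    @classmethod
    def default(cls, mean0: float = 0.1, mean1: float = 0.8,
                icc: float = 0.1, self_prob: float = 0.99) -> "HMMModel":
        q = 1.0 - self_prob
        return cls(
            initial=np.array([0.5, 0.5]),
            transition=np.array([[self_prob, q], [q, self_prob]]),
            emissions=(BetaBinomialEmission.from_moments(mean0, icc),
                       BetaBinomialEmission.from_moments(mean1, icc)),
        )

    def emission_probs(self, meth: np.ndarray, total: np.ndarray) -> np.ndarray:
        """(T, 2) matrix of emission probabilities (linear scale, rescaled)."""
        logb = np.stack([e.logpmf(meth, total) for e in self.emissions], axis=1)
        logb -= logb.max(axis=1, keepdims=True)
        return np.exp(logb)


def forward_backward(model: HMMModel, meth: np.ndarray, total: np.ndarray
                     ) -> tuple[np.ndarray, np.ndarray, float]:
    """Scaled forward-backward on one chain.

    Returns (gamma, xi_sum, loglik): gamma is the (T, 2) posterior state
    matrix, xi_sum the (2, 2) matrix of expected transition counts, and
    loglik the exact log-likelihood of the chain.  Emission probabilities
    are rescaled per site, which cancels in the posteriors but not in the
    log-likelihood, where the scale is added back.
    """
    logb = np.stack([e.logpmf(meth, total) for e in model.emissions], axis=1)
    offset = logb.max(axis=1)
    b = np.exp(logb - offset[:, None])
    T = len(b)
    a00, a01 = model.transition[0]
    a10, a11 = model.transition[1]

    alpha = np.empty((T, 2))
    scale = np.empty(T)
    f0 = model.initial[0] * b[0, 0]
    f1 = model.initial[1] * b[0, 1]
    c = f0 + f1
    scale[0] = c
    alpha[0] = f0 / c, f1 / c
    bl = b.tolist()
    al0, al1 = alpha[0, 0], alpha[0, 1]
    scl = scale
    for t in range(1, T):
        bt0, bt1 = bl[t]
        f0 = (al0 * a00 + al1 * a10) * bt0
        f1 = (al0 * a01 + al1 * a11) * bt1
        c = f0 + f1
        if c <= 0:
            c = _EPS
        al0, al1 = f0 / c, f1 / c
        alpha[t, 0], alpha[t, 1] = al0, al1
        scl[t] = c

    beta = np.empty((T, 2))
    beta[-1] = 1.0, 1.0
    bb0 = bb1 = 1.0
    xi = np.zeros((2, 2))
    for t in range(T - 2, -1, -1):
        bt0, bt1 = bl[t + 1]
        c = scl[t + 1]
        g0 = bt0 * bb0
        g1 = bt1 * bb1
        nb0 = (a00 * g0 + a01 * g1) / c
        nb1 = (a10 * g0 + a11 * g1) / c
        beta[t, 0], beta[t, 1] = nb0, nb1
        at0, at1 = alpha[t, 0], alpha[t, 1]
        xi[0, 0] += at0 * a00 * g0 / c
        xi[0, 1] += at0 * a01 * g1 / c
        xi[1, 0] += at1 * a10 * g0 / c
        xi[1, 1] += at1 * a11 * g1 / c
        bb0, bb1 = nb0, nb1

    gamma = alpha * beta
    gamma /= gamma.sum(axis=1, keepdims=True)
    loglik = float(np.log(scale).sum() + offset.sum())
    return gamma, xi, loglik


@dataclass(slots=True)
class FitResult:
    model: HMMModel
    loglik_trace: list[float]
    converged: bool
    n_iter: int
    degenerate: bool  # one state holds < 0.5% of posterior mass


def fit_two_state_hmm(chains: Sequence[tuple[np.ndarray, np.ndarray]],
                      init: HMMModel | None = None,
                      tol: float = 1e-4, max_iter: int = 100,
                      seed: int = 17) -> FitResult:
    """Baum-Welch over a set of observation chains sharing one model.

    ``chains`` is a sequence of (meth, total) array pairs, one per
    uninterrupted run of sites (chains are broken at coverage deserts
    upstream).  ``tol`` is the relative log-likelihood change declaring
    convergence.  ``seed`` is reserved for randomized restarts and kept for
    reproducibility of any future use; the default fit is deterministic.
    """
    del seed  # deterministic single-start fit
    model = init or HMMModel.default()
    chains = [(np.asarray(m, dtype=np.int64), np.asarray(n, dtype=np.int64))
              for m, n in chains if np.asarray(n).sum() > 0]
    if not chains:
        raise ValueError("no informative chains to fit")

    trace: list[float] = []
    converged = False
    gamma_mass = np.array([0.5, 0.5])
    n_iter = 0
    for it in range(max_iter):
        n_iter = it + 1
        # E-step
        total_ll = 0.0
        init_acc = np.zeros(2)
        xi_acc = np.zeros((2, 2))
        wsum = np.zeros(2)          # sum of posterior weights
        wp = np.zeros(2)            # weighted sum of fractions
        wp2 = np.zeros(2)           # weighted sum of squared fractions
        winv = np.zeros(2)          # weighted sum of 1/n
        gammas = []
        for meth, total in chains:
            gamma, xi, ll = forward_backward(model, meth, total)
            total_ll += ll
            init_acc += gamma[0]
            xi_acc += xi
            ok = total > 0
            frac = np.zeros(len(meth))
            frac[ok] = meth[ok] / total[ok]
            for k in (0, 1):
                w = gamma[ok, k]
                wsum[k] += w.sum()
                wp[k] += (w * frac[ok]).sum()
                wp2[k] += (w * frac[ok] ** 2).sum()
                winv[k] += (w / total[ok]).sum()
            gammas.append(gamma)

        if trace and total_ll < trace[-1] - 1e-8:
            # moments update overshot: reject it and stop at previous params
            model = prev_model
            converged = True
            break
        trace.append(total_ll)
        gamma_mass = wsum / wsum.sum()
        if len(trace) >= 2:
            prev, cur = trace[-2], trace[-1]
            if abs(cur - prev) <= tol * (abs(prev) + 1e-12):
                converged = True
                break
        # M-step
        prev_model = model
        new_init = init_acc / init_acc.sum()
        rows = xi_acc.sum(axis=1, keepdims=True)
        new_trans = np.where(rows > 0, xi_acc / np.maximum(rows, _EPS),
                             model.transition)
        new_trans = np.clip(new_trans, 1e-6, 1 - 1e-6)
        new_trans /= new_trans.sum(axis=1, keepdims=True)
        ems = []
        for k in (0, 1):
            if wsum[k] < 1e-6:
                ems.append(model.emissions[k])
                continue
            mu = wp[k] / wsum[k]
            var = max(wp2[k] / wsum[k] - mu ** 2, 0.0)
            mean_inv_n = winv[k] / wsum[k]
            denom = max(1.0 - mean_inv_n, 1e-6)
            pq = max(mu * (1 - mu), 1e-6)
            icc = (var / pq - mean_inv_n) / denom
            ems.append(BetaBinomialEmission.from_moments(mu, icc))
        if ems[0].mean > ems[1].mean:
            ems = [ems[1], ems[0]]
            new_trans = new_trans[::-1, ::-1]
            new_init = new_init[::-1]
        try:
            model = HMMModel(new_init, new_trans, (ems[0], ems[1]))
        except ValueError:
            model = prev_model
            converged = True
            break
        if np.isinf(tol):
            # caller asked for a single E-step: return the initialization
            model = prev_model
            converged = True
            break

    degenerate = bool(gamma_mass.min() < 0.005)
    return FitResult(model, trace, converged, n_iter, degenerate)


def posterior_decode(model: HMMModel, meth: np.ndarray, total: np.ndarray
                     ) -> tuple[np.ndarray, np.ndarray]:
    """Per-site MAP state and the log-odds for state 0 (hypo state)."""
    gamma, _, _ = forward_backward(model, meth, total)
    g0 = np.clip(gamma[:, 0], 1e-12, 1 - 1e-12)
    logodds = np.log(g0) - np.log1p(-g0)
    return (gamma[:, 0] > 0.5).astype(np.int8) ^ 1, logodds


def decode_state_runs(states: np.ndarray, state: int
                      ) -> list[tuple[int, int]]:
    """Half-open index runs where ``states == state``."""
    hits = np.asarray(states) == state
    if not hits.any():
        return []
    d = np.diff(hits.astype(np.int8))
    starts = list(np.where(d == 1)[0] + 1)
    ends = list(np.where(d == -1)[0] + 1)
    if hits[0]:
        starts.insert(0, 0)
    if hits[-1]:
        ends.append(len(hits))
    return list(zip(starts, ends))
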