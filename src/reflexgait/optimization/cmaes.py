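"""Covariance Matrix Adaptation Evolution Strategy.

A self-contained (mu/mu_w, lambda)-CMA-ES with rank-one and rank-mu
covariance updates and cumulative step-size adaptation (the standard
Hansen formulation).  Sampling is driven by a seeded Generator, so a
given (seed, problem) yields a bit-identical candidate sequence.
"""

from __future__ import annotations

import numpy as np


class CMAES:
    def __init__(self, x0: np.ndarray, sigma: float, lam: int | None = None,
                 seed: int = 0, scales: np.ndarray | None = None):
        x0 = np.asarray(x0, dtype=float)
        n = x0.size
        if lam is None:
            lam = 4 + int(3 * np.log(n))
        if lam < 2:
            raise ValueError("population size must be >= 2")
        mu = lam // 2
        w = np.log(mu + 0.5) - np.log(np.arange(1, mu + 1))
        w /= w.sum()
        self.n, self.lam, self.mu, self.w = n, lam, mu, w
        self.mueff = 1.0 / np.sum(w ** 2)
        self.cc = (4 + self.mueff / n) / (n + 4 + 2 * self.mueff / n)
        self.cs = (self.mueff + 2) / (n + self.mueff + 5)
        self.c1 = 2 / ((n + 1.3) ** 2 + self.mueff)
        self.cmu = min(1 - self.c1,
                       2 * (self.mueff - 2 + 1 / self.mueff)
                       / ((n + 2) ** 2 + self.mueff))
        self.damps = 1 + 2 * max(0.0, np.sqrt((self.mueff - 1) / (n + 1)) - 1) \
            + self.cs
        self.chi_n = np.sqrt(n) * (1 - 1 / (4 * n) + 1 / (21 * n ** 2))
        self.mean = x0.copy()
        self.sigma = float(sigma)
        # per-coordinate scales seed the covariance, playing the role of
        # the unit-scaled search space (sigma stays dimensionless)
        if scales is None:
            self.C = np.eye(n)
        else:
            s = np.asarray(scales, dtype=float)
            if s.shape != (n,) or np.any(s <= 0):
                raise ValueError("scales must be positive, one per coordinate")
            self.C = np.diag(s ** 2)
        self.pc = np.zeros(n)
        self.ps = np.zeros(n)
        self.rng = np.random.default_rng(seed)
        self.generation = 0
        self.best_x = x0.copy()
        self.best_f = np.inf
        self._z = None
        self._y = None

    def ask(self) -> np.ndarray:
        """Sample lambda candidates; shape (lam, n)."""
        d, B = np.linalg.eigh(self.C)
        d = np.sqrt(np.maximum(d, 1e-20))
        self._z = self.rng.standard_normal((self.lam, self.n))
        self._y = self._z @ np.diag(d) @ B.T
        return self.mean + self.sigma * self._y

    def tell(self, fitness: np.ndarray):
        f = np.asarray(fitness, dtype=float)
        order = np.argsort(f)
        if f[order[0]] < self.best_f:
            self.best_f = float(f[order[0]])
            self.best_x = self.mean + self.sigma * self._y[order[0]]
        ysel = self._y[order[: self.mu]]
        ymean = self.w @ ysel
        self.mean = self.mean + self.sigma * ymean

        # step-size path (C^{-1/2} y)
        d, B = np.linalg.eigh(self.C)
        d = np.sqrt(np.maximum(d, 1e-20))
        cinv_y = B @ ((B.T @ ymean) / d)
        self.ps = (1 - self.cs) * self.ps \
            + np.sqrt(self.cs * (2 - self.cs) * self.mueff) * cinv_y
        hsig = (np.linalg.norm(self.ps)
                / np.sqrt(1 - (1 - self.cs) ** (2 * (self.generation + 1)))
                / self.chi_n) < 1.4 + 2 / (self.n + 1)
        self.pc = (1 - self.cc) * self.pc \
            + hsig * np.sqrt(self.cc * (2 - self.cc) * self.mueff) * ymean
        rank1 = np.outer(self.pc, self.pc)
        rankmu = (ysel * self.w[:, None]).T @ ysel
        dh = (1 - hsig) * self.cc * (2 - self.cc)
        self.C = (1 - self.c1 - self.cmu) * self.C \
            + self.c1 * (rank1 + dh * self.C) + self.cmu * rankmu
        self.C = (self.C + self.C.T) / 2
        self.sigma *= np.exp((self.cs / self.damps)
                             * (np.linalg.norm(self.ps) / self.chi_n - 1))
        self.generation += 1


def minimize(fun, x0, sigma, lam=None, max_gen=200, seed=0, tol=0.0,
             callback=None):
    """Convenience loop; returns (best_x, best_f, history of gen bests)."""
    es = CMAES(x0, sigma, lam=lam, seed=seed)
    history = []
    for g in range(max_gen):
        X = es.ask()
        f = np.array([fun(x) for x in X])
        es.tell(f)
        history.append(es.best_f)
        if callback is not None:
            callback(es, g)
        if tol > 0 and es.best_f <= tol:
            break
    return es.best_x, es.best_f, history
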