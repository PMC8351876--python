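"""Minimal (mu/mu_w, lambda) CMA-ES with cumulative step-size adaptation.

Standard covariance-matrix-adaptation evolution strategy (rank-one plus
rank-mu covariance update, CSA step-size control) with an ask/tell
interface.  Dimensions here are tiny (2-4 parameters), so the full
eigendecomposition is done every generation.
"""

from __future__ import annotations

import numpy as np

__all__ = ["CMAES"]


class CMAES:
    """Ask/tell CMA-ES minimizer.

    Parameters
    ----------
    x0 : initial mean.
    sigma0 : initial global step size (in the units of ``x0``).
    popsize : number of candidates per generation; default ``4 + 3 ln n``.
    seed : RNG seed (int or sequence of ints).
    """

    def __init__(self, x0, sigma0: float, popsize: int | None = None, seed=0):
        self.mean = np.asarray(x0, dtype=float).copy()
        n = self.mean.size
        self.n = n
        self.sigma = float(sigma0)
        self.lam = int(popsize) if popsize else 4 + int(3 * np.log(n))
        self.mu = self.lam // 2
        w = np.log(self.mu + 0.5) - np.log(np.arange(1, self.mu + 1))
        self.w = w / w.sum()
        self.mueff = 1.0 / np.sum(self.w ** 2)

        self.cc = (4 + self.mueff / n) / (n + 4 + 2 * self.mueff / n)
        self.cs = (self.mueff + 2) / (n + self.mueff + 5)
        self.c1 = 2 / ((n + 1.3) ** 2 + self.mueff)
        self.cmu = min(
            1 - self.c1,
            2 * (self.mueff - 2 + 1 / self.mueff) / ((n + 2) ** 2 + self.mueff),
        )
        self.ds = 1 + 2 * max(0.0, np.sqrt((self.mueff - 1) / (n + 1)) - 1) + self.cs
        self.chiN = np.sqrt(n) * (1 - 1 / (4 * n) + 1 / (21 * n ** 2))

        self.pc = np.zeros(n)
        self.ps = np.zeros(n)
        self.C = np.eye(n)
        self.gen = 0
        root = list(seed) if isinstance(seed, (list, tuple)) else [int(seed)]
        self.rng = np.random.default_rng(root)
        self._y: np.ndarray | None = None

    def ask(self) -> np.ndarray:
        """Sample ``popsize`` candidate points (rows)."""
        d2, b = np.linalg.eigh(self.C)
        d = np.sqrt(np.maximum(d2, 1e-30))
        self._b, self._d = b, d
        z = self.rng.standard_normal((self.lam, self.n))
        self._y = z @ (b * d).T  # y_i = B D z_i
        return self.mean + self.sigma * self._y

    def tell(self, fitness) -> None:
        """Update the distribution from the fitness of the last ask()."""
        if self._y is None:
            raise RuntimeError("tell() called before ask()")
        fitness = np.asarray(fitness, dtype=float)
        order = np.argsort(fitness)
        ysel = self._y[order[: self.mu]]
        yw = self.w @ ysel
        self.mean = self.mean + self.sigma * yw

        invsqrt = self._b @ np.diag(1.0 / self._d) @ self._b.T
        self.ps = (1 - self.cs) * self.ps + np.sqrt(
            self.cs * (2 - self.cs) * self.mueff
        ) * (invsqrt @ yw)
        self.gen += 1
        hsig = (
            np.linalg.norm(self.ps)
            / np.sqrt(1 - (1 - self.cs) ** (2 * self.gen))
            / self.chiN
            < 1.4 + 2 / (self.n + 1)
        )
        self.pc = (1 - self.cc) * self.pc + hsig * np.sqrt(
            self.cc * (2 - self.cc) * self.mueff
        ) * yw
        rank_mu = ysel.T @ (ysel * self.w[:, None])
        self.C = (
            (1 - self.c1 - self.cmu) * self.C
            + self.c1
            * (np.outer(self.pc, self.pc) + (1 - hsig) * self.cc * (2 - self.cc) * self.C)
            + self.cmu * rank_mu
        )
        self.C = (self.C + self.C.T) / 2  # keep symmetric under round-off
        self.sigma *= np.exp(
            (self.cs / self.ds) * (np.linalg.norm(self.ps) / self.chiN - 1)
        )
        self._y = None
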