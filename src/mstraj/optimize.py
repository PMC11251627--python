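"""Sequential model-based (Bayesian) hyperparameter search.

A Gaussian-process surrogate with the expected-improvement acquisition,
in the spirit of classic SMBO tools: a handful of seeded exploratory
draws, then each further trial maximizes expected improvement over a
random candidate pool under a Matern-5/2 GP fitted to the unit-cube
encoding of the search space (log-scaled axes where the spec says so).

The search is fully deterministic given its seed, and caller-supplied
initial points (e.g. a library's default configuration) are evaluated
first, so the returned best trial can never be worse than them.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.stats import norm
from sklearn.exceptions import ConvergenceWarning
from sklearn.gaussian_process import GaussianProcessRegressor
from sklearn.gaussian_process.kernels import Matern

import warnings


@dataclass(frozen=True)
class ParamSpec:
    name: str
    low: float
    high: float
    log: bool = False
    integer: bool = False

    def to_unit(self, value: float) -> float:
        lo, hi = (math.log(self.low), math.log(self.high)) if self.log else (self.low, self.high)
        v = math.log(value) if self.log else value
        return (v - lo) / (hi - lo)

    def from_unit(self, u: float) -> float:
        u = min(1.0, max(0.0, u))
        lo, hi = (math.log(self.low), math.log(self.high)) if self.log else (self.low, self.high)
        v = lo + u * (hi - lo)
        if self.log:
            v = math.exp(v)
        if self.integer:
            v = int(round(v))
            v = int(min(self.high, max(self.low, v)))
        return v


@dataclass
class Trial:
    params: dict
    loss: float
    failed: bool = False


def _encode(space: list[ParamSpec], params: dict) -> np.ndarray:
    return np.array([p.to_unit(params[p.name]) for p in space])


def _decode(space: list[ParamSpec], u: np.ndarray) -> dict:
    return {p.name: p.from_unit(float(x)) for p, x in zip(space, u)}


def bayes_minimize(
    objective,
    space: list[ParamSpec],
    budget: int,
    seed: int = 0,
    init_points: list[dict] | None = None,
    n_random: int | None = None,
    candidate_pool: int = 256,
) -> tuple[dict, float, list[Trial]]:
    """Minimize ``objective(params) -> loss`` over ``space``.

    Returns ``(best_params, best_loss, trials)``.  A trial whose
    objective raises is recorded with infinite loss and the search
    continues; if every trial fails the first initial point (or first
    random draw) is returned with ``inf`` loss.
    """
    if budget < 1:
        raise ValueError("budget must be >= 1")
    rng = np.random.default_rng(seed)
    trials: list[Trial] = []

    def run(params: dict) -> None:
        try:
            loss = float(objective(params))
            if not np.isfinite(loss):
                raise ValueError("non-finite loss")
            trials.append(Trial(params, loss))
        except Exception:
            trials.append(Trial(params, float("inf"), failed=True))

    queue = list(init_points or [])
    if n_random is None:
        n_random = max(4, budget // 3)
    while len(trials) < budget and queue:
        run(queue.pop(0))
    while len(trials) < budget and len(trials) < n_random + len(init_points or []):
        run(_decode(space, rng.random(len(space))))

    while len(trials) < budget:
        ok = [t for t in trials if not t.failed]
        if len(ok) < 2:
            run(_decode(space, rng.random(len(space))))
            continue
        X = np.array([_encode(space, t.params) for t in ok])
        y = np.array([t.loss for t in ok])
        y_std = y.std()
        y_norm = (y - y.mean()) / (y_std if y_std > 0 else 1.0)
        gp = GaussianProcessRegressor(
            kernel=Matern(length_scale=np.full(len(space), 0.3), nu=2.5),
            alpha=1e-6, normalize_y=False, random_state=seed,
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            gp.fit(X, y_norm)
        cand = rng.random((candidate_pool, len(space)))
        mu, sigma = gp.predict(cand, return_std=True)
        best = y_norm.min()
        sigma = np.maximum(sigma, 1e-12)
        imp = best - mu
        z = imp / sigma
        ei = imp * norm.cdf(z) + sigma * norm.pdf(z)
        run(_decode(space, cand[int(np.argmax(ei))]))

    finite = [t for t in trials if not t.failed]
    if not finite:
        return trials[0].params, float("inf"), trials
    best_trial = min(finite, key=lambda t: t.loss)
    return best_trial.params, best_trial.loss, trials


#: Search space for the boosted-tree learner.
XGB_SPACE: list[ParamSpec] = [
    ParamSpec("max_depth", 2, 10, integer=True),
    ParamSpec("learning_rate", 1e-3, 0.3, log=True),
    ParamSpec("n_estimators", 50, 600, integer=True),
    ParamSpec("min_child_weight", 1, 10, integer=True),
    ParamSpec("subsample", 0.5, 1.0),
    ParamSpec("colsample_bytree", 0.5, 1.0),
    ParamSpec("gamma", 1e-8, 5.0, log=True),
    ParamSpec("reg_alpha", 1e-8, 5.0, log=True),
    ParamSpec("reg_lambda", 1e-2, 5.0, log=True),
]
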