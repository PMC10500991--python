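"""One-boundary detection drift-diffusion model fit by quantile G² minimization.

The model has three parameters: bound ``a`` (response caution), drift ``v``
(evidence units per second) and nondecision time ``t0`` (seconds), with the
within-trial diffusion coefficient fixed at s=1. First-passage times of the
accumulator follow a shifted Wald (inverse-Gaussian) law; trials whose
accumulator has not reached the bound by the deadline are misses. Observed
RTs are summarized by the quantiles {0.1, 0.3, 0.5, 0.7, 0.9}, giving six
contiguous response intervals (edges 0, the five quantile cuts, and the
deadline) with observed proportions 0.1/0.2/0.2/0.2/0.2/0.1 of responders,
plus one miss bin; parameters minimize

    G² = 2 Σ_i O_i ln(O_i / E_i)

over those bins with a modified Powell search from a small multi-start
grid. Expected frequencies telescope through the first-passage CDF, so
ΣO = ΣE = n_total holds exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.special import ndtr

from decispeed.containers import SubjectBehavior

RESPONSE_QUANTILES = (0.1, 0.3, 0.5, 0.7, 0.9)
#: Observed proportions implied by the quantile cuts (six response intervals).
OBSERVED_PROPORTIONS = (0.1, 0.2, 0.2, 0.2, 0.2, 0.1)
#: Floor applied to expected frequencies so ln() stays finite.
E_FLOOR = 1e-10


@dataclass
class DdmFit:
    """Fitted parameters plus goodness-of-fit bookkeeping."""

    a: float
    v: float
    t0: float
    g2: float = np.nan
    converged: bool = False
    n_starts_used: int = 0

    def __post_init__(self) -> None:
        if self.a <= 0:
            raise ValueError("bound a must be positive")
        if self.t0 < 0:
            raise ValueError("nondecision time t0 must be non-negative")


@dataclass
class QuantileBins:
    """Observed/expected frequencies over the RT intervals plus a miss bin."""

    cutpoints: np.ndarray  # five RT quantile cuts, seconds
    observed: np.ndarray  # six response frequencies + one miss frequency
    expected: Optional[np.ndarray] = None
    n_total: int = 0

    def __post_init__(self) -> None:
        self.cutpoints = np.asarray(self.cutpoints, dtype=float)
        self.observed = np.asarray(self.observed, dtype=float)
        if self.cutpoints.size != 5 or self.observed.size != 7:
            raise ValueError("expected 5 cutpoints and 7 observed frequencies")


def wald_pdf(rt: np.ndarray | float, a: float, v: float, t0: float) -> np.ndarray:
    """Shifted-Wald first-passage density; zero at or below ``t0``.

    f(t) = a / sqrt(2 pi (t-t0)^3) * exp(-(a - v (t-t0))^2 / (2 (t-t0)))
    """
    rt = np.asarray(rt, dtype=float)
    t = rt - t0
    out = np.zeros_like(t)
    pos = t > 0
    tp = t[pos]
    out[pos] = a / np.sqrt(2.0 * np.pi * tp**3) * np.exp(-((a - v * tp) ** 2) / (2.0 * tp))
    return out if out.ndim else float(out)


def wald_cdf(rt: np.ndarray | float, a: float, v: float, t0: float) -> np.ndarray:
    """Shifted-Wald first-passage CDF via the standard normal-CDF expression.

    F(t) = Phi((v t' - a)/sqrt(t')) + exp(2 a v) Phi(-(v t' + a)/sqrt(t'))
    with t' = t - t0; for v > 0, F(inf) = 1.
    """
    rt = np.asarray(rt, dtype=float)
    t = rt - t0
    out = np.zeros_like(t)
    pos = t > 0
    tp = t[pos]
    sq = np.sqrt(tp)
    term1 = ndtr((v * tp - a) / sq)
    # exp(2av) can overflow for large a*v; pair it with the log of the tiny
    # normal tail instead of multiplying the raw values.
    log_tail = _log_ndtr(-(v * tp + a) / sq)
    term2 = np.exp(2.0 * a * v + log_tail)
    out[pos] = np.clip(term1 + term2, 0.0, 1.0)
    return out if out.ndim else float(out)


def _log_ndtr(x: np.ndarray) -> np.ndarray:
    from scipy.special import log_ndtr

    return log_ndtr(x)


def simulate_ddm(
    a: float,
    v: float,
    t0: float,
    n: int,
    deadline_ms: float = 1800.0,
    seed: int | np.random.Generator | None = None,
    method: str = "wald",
    dt: float = 0.001,
) -> SubjectBehavior:
    """Simulate ``n`` detection trials from the one-boundary diffusion.

    ``method='wald'`` samples first-passage times from the closed-form
    inverse-Gaussian law; ``method='euler'`` runs an Euler–Maruyama path
    simulation at step ``dt`` seconds (the independent oracle). Trials whose
    passage time exceeds the deadline are recorded as misses.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    deadline_s = deadline_ms / 1000.0
    if method == "wald":
        rt_s = t0 + _sample_wald(a, v, n, rng)
    elif method == "euler":
        rt_s = t0 + _sample_euler(a, v, n, deadline_s, dt, rng)
    else:
        raise ValueError(f"unknown method {method!r}")
    responded = rt_s < deadline_s
    rt_ms = np.where(responded, rt_s * 1000.0, np.nan)
    trials = pd.DataFrame(
        {
            "rt_ms": rt_ms,
            "responded": responded,
            "hemifield": np.where(np.arange(n) % 2 == 0, "left", "right"),
            "direction": np.where((np.arange(n) // 2) % 2 == 0, "up", "down"),
            "iti_s": np.tile([1.8, 2.8, 3.8], n // 3 + 1)[:n],
        }
    )
    return SubjectBehavior(trials=trials)


def _sample_wald(a: float, v: float, n: int, rng: np.random.Generator) -> np.ndarray:
    # IG(mean = a/v, shape = a^2) via the Michael–Schucany–Haas transform.
    mu = a / v
    lam = a * a
    nu = rng.standard_normal(n)
    y = nu * nu
    x = mu + (mu * mu * y) / (2.0 * lam) - (mu / (2.0 * lam)) * np.sqrt(
        4.0 * mu * lam * y + mu * mu * y * y
    )
    z = rng.uniform(size=n)
    return np.where(z <= mu / (mu + x), x, mu * mu / x)


def _sample_euler(
    a: float, v: float, n: int, deadline_s: float, dt: float, rng: np.random.Generator
) -> np.ndarray:
    """Euler–Maruyama with a Brownian-bridge crossing check per step.

    The bridge correction (probability exp(-2(a-x0)(a-x1)/dt) of an
    excursion above the bound inside a step) removes the O(sqrt(dt))
    first-passage bias of the naive end-of-step comparison.
    """
    n_steps = int(np.ceil(deadline_s / dt)) + 1
    x = np.zeros(n, dtype=float)
    rt = np.full(n, np.inf)
    alive = np.ones(n, dtype=bool)
    sqrt_dt = np.sqrt(dt)
    for step in range(1, n_steps + 1):
        idx = np.flatnonzero(alive)
        if idx.size == 0:
            break
        x0 = x[idx]
        x1 = x0 + v * dt + sqrt_dt * rng.standard_normal(idx.size)
        crossed = x1 >= a
        not_crossed = ~crossed
        if not_crossed.any():
            gap = (a - x0[not_crossed]) * (a - x1[not_crossed])
            p_bridge = np.exp(-2.0 * gap / dt)
            crossed[not_crossed] = rng.uniform(size=int(not_crossed.sum())) < p_bridge
        hit = idx[crossed]
        rt[hit] = step * dt
        alive[hit] = False
        x[idx] = x1
    return rt


def bin_observed(behavior: SubjectBehavior, deadline_ms: float = 1800.0) -> QuantileBins:
    """Observed-side quantile bins: six response intervals plus the miss count."""
    rts = behavior.rts / 1000.0
    n_resp = rts.size
    if n_resp < 10:
        raise ValueError(f"need >= 10 responded trials, got {n_resp}")
    cuts = np.quantile(rts, RESPONSE_QUANTILES)
    if np.any(np.diff(cuts) <= 0):
        raise ValueError("degenerate RT quantiles (ties across cutpoints)")
    n_miss = behavior.n_trials - n_resp
    observed = np.array([p * n_resp for p in OBSERVED_PROPORTIONS] + [n_miss], dtype=float)
    return QuantileBins(cutpoints=cuts, observed=observed, n_total=behavior.n_trials)


def expected_frequencies(
    a: float, v: float, t0: float, bins: QuantileBins, deadline_ms: float = 1800.0
) -> QuantileBins:
    """Fill the expected side: E_i from successive CDF differences.

    Response-bin edges are 0, the five cutpoints, and the deadline; the miss
    bin gets the mass beyond the deadline. Expected counts are floored at
    ``E_FLOOR`` so the G² logarithm is finite everywhere.
    """
    deadline_s = deadline_ms / 1000.0
    edges = np.concatenate([[0.0], bins.cutpoints, [deadline_s]])
    cdf = wald_cdf(edges, a, v, t0)
    probs = np.diff(cdf)
    miss_prob = 1.0 - cdf[-1]
    expected = bins.n_total * np.concatenate([probs, [miss_prob]])
    expected = np.maximum(expected, E_FLOOR)
    return QuantileBins(
        cutpoints=bins.cutpoints,
        observed=bins.observed,
        expected=expected,
        n_total=bins.n_total,
    )


def g_square(bins: QuantileBins) -> float:
    """G² = 2 Σ O_i ln(O_i / E_i); bins with O_i = 0 contribute nothing."""
    if bins.expected is None:
        raise ValueError("bins carry no expected frequencies")
    o = bins.observed
    e = np.maximum(np.asarray(bins.expected, dtype=float), E_FLOOR)
    nz = o > 0
    return float(2.0 * np.sum(o[nz] * np.log(o[nz] / e[nz])))


def _default_start_grid(rts_s: np.ndarray) -> list[tuple[float, float, float]]:
    rt_min = float(np.min(rts_s))
    rt_mean = float(np.mean(rts_s))
    t0s = [0.25 * rt_min, 0.5 * rt_min, 0.85 * rt_min]
    a_s = [1.0, 2.0, 3.5]
    starts = []
    for a0 in a_s:
        for t00 in t0s:
            # drift implied by the Wald mean a/v = mean decision time
            dt_mean = max(rt_mean - t00, 0.02)
            for scale in (0.6, 1.0, 1.6):
                starts.append((a0, scale * a0 / dt_mean, t00))
    return starts


def fit_ddm(
    behavior: SubjectBehavior,
    deadline_ms: float = 1800.0,
    init_grid: Optional[Sequence[tuple[float, float, float]]] = None,
) -> DdmFit:
    """Fit (a, v, t0) by Powell minimization of G² from a multi-start grid.

    ``t0`` is bounded above by the minimum observed RT; ``a`` and ``v`` are
    kept positive through box bounds. Returns the best of all starts.
    """
    bins = bin_observed(behavior, deadline_ms)
    rts_s = behavior.rts / 1000.0
    rt_min = float(np.min(rts_s))
    starts = list(init_grid) if init_grid is not None else _default_start_grid(rts_s)

    def objective(theta: np.ndarray) -> float:
        a, v, t0 = theta
        if a <= 0 or v <= 0 or t0 < 0 or t0 >= rt_min:
            return 1e12
        return g_square(expected_frequencies(a, v, t0, bins, deadline_ms))

    # feasibility is enforced by the penalty inside the objective; scipy's
    # Powell line search behaves poorly with explicit box bounds here
    best: Optional[optimize.OptimizeResult] = None
    n_used = 0
    for start in starts:
        n_used += 1
        try:
            res = optimize.minimize(
                objective,
                np.asarray(start, dtype=float),
                method="Powell",
                options={"xtol": 1e-6, "ftol": 1e-8, "maxiter": 2000},
            )
        except Exception:
            continue
        if best is None or res.fun < best.fun:
            best = res
    if best is None or not np.isfinite(best.fun):
        raise RuntimeError(
            f"DDM fit failed from all {n_used} starts (n={behavior.n_trials})"
        )
    a, v, t0 = (float(x) for x in best.x)
    return DdmFit(a=a, v=v, t0=t0, g2=float(best.fun), converged=bool(best.success), n_starts_used=n_used)


def fit_table(
    behaviors: dict[str, SubjectBehavior], deadline_ms: float = 1800.0
) -> pd.DataFrame:
    """Per-subject fits as a TSV-ready table (a, v, t0, g2, converged)."""
    rows = []
    for sid, beh in behaviors.items():
        fit = fit_ddm(beh, deadline_ms)
        rows.append(
            {
                "subject_id": sid,
                "a": fit.a,
                "v": fit.v,
                "t0": fit.t0,
                "g2": fit.g2,
                "converged": fit.converged,
            }
        )
    return pd.DataFrame(rows)
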