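"""Segmented log-linear trend estimation ("joinpoint" analysis).

An annual rate series is modelled as a continuous piecewise-linear function
of calendar year on the log scale:

    ln r(y) = a + b0 * y + sum_k c_k * max(0, y - tau_k)

The hinge terms guarantee the joined-straight-lines constraint by
construction.  Candidate change-point years (joinpoints) are searched
exhaustively over integer interior years with a minimum number of
observations per segment, and the model (including "no joinpoint") is chosen
by BIC, or optionally by a sequential Monte-Carlo permutation test on
residuals.  Each segment's slope b is reported as an annual percentage
change APC = 100 * (exp(b) - 1).

This is a self-contained approximation in the joinpoint-regression family:
unweighted least squares on log rates, integer-year joinpoints, and
information-criterion model selection.  It does not compute joinpoint
confidence intervals.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd

__all__ = ["SegmentedTrendFit", "fit_fixed_joinpoints", "select_joinpoints"]

_RSS_FLOOR = 1e-12  # treats numerically exact fits as ties, favouring parsimony


@dataclass
class SegmentedTrendFit:
    """A fitted continuous piecewise log-linear trend."""

    years: np.ndarray
    joinpoint_years: tuple[int, ...]
    coefficients: np.ndarray  # (a, b0, c_1..c_k) in the hinge basis
    segment_slopes: np.ndarray  # slope of ln(rate) per segment
    apc_per_segment: np.ndarray  # 100 * (exp(slope) - 1)
    rss: float
    selection_scores: dict = field(default_factory=dict)

    @property
    def n_segments(self) -> int:
        return len(self.joinpoint_years) + 1

    def predict(self, years) -> np.ndarray:
        """Fitted rates (natural scale) at the given years."""
        x = _design(np.asarray(years, dtype=float), self.joinpoint_years)
        return np.exp(x @ self.coefficients)

    def summary(self) -> str:
        lines = [
            f"segments: {self.n_segments}  joinpoints: "
            + (", ".join(map(str, self.joinpoint_years)) or "none"),
            f"rss (log scale): {self.rss:.6g}",
        ]
        bounds = [int(self.years.min()), *self.joinpoint_years, int(self.years.max())]
        for k, (lo, hi) in enumerate(zip(bounds, bounds[1:])):
            lines.append(
                f"  {lo}-{hi}: slope {self.segment_slopes[k]:+.4f}  "
                f"APC {self.apc_per_segment[k]:+.2f}%"
            )
        return "\n".join(lines)


def _design(years: np.ndarray, taus) -> np.ndarray:
    cols = [np.ones_like(years), years]
    for tau in taus:
        cols.append(np.maximum(0.0, years - tau))
    return np.column_stack(cols)


def _prepare(series) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(series, pd.DataFrame):
        years = series["year"].to_numpy(dtype=float)
        rates = series["rate_per_1000py"].to_numpy(dtype=float)
    else:
        years, rates = series
        years = np.asarray(years, dtype=float)
        rates = np.asarray(rates, dtype=float)
    order = np.argsort(years)
    years, rates = years[order], rates[order]
    if np.any(rates <= 0):
        bad = years[rates <= 0].astype(int).tolist()
        raise ValueError(
            f"nonpositive rate(s) at year(s) {bad}: offset or drop them before the log fit"
        )
    return years, rates


def fit_fixed_joinpoints(series, joinpoint_years=()) -> SegmentedTrendFit:
    """Least-squares fit of ln(rate) with the given joinpoint years fixed.

    ``series`` is either a rate-series DataFrame (columns ``year`` and
    ``rate_per_1000py``) for a single stratum, or a ``(years, rates)`` pair.
    Requires at least two observations per segment and strictly positive
    rates.
    """
    years, rates = _prepare(series)
    taus = tuple(sorted(int(t) for t in joinpoint_years))
    if any(t <= years.min() or t >= years.max() for t in taus):
        raise ValueError(f"joinpoints {taus} must be interior to [{years.min()}, {years.max()}]")
    if len(set(taus)) != len(taus):
        raise ValueError("joinpoint years must be distinct")
    bounds = [-np.inf, *taus, np.inf]
    for lo, hi in zip(bounds, bounds[1:]):
        if np.sum((years > lo) & (years <= hi)) < 2:
            raise ValueError(f"segment ({lo}, {hi}] has fewer than 2 observations")
    x = _design(years, taus)
    y = np.log(rates)
    beta, *_ = np.linalg.lstsq(x, y, rcond=None)
    resid = y - x @ beta
    rss = float(resid @ resid)
    slopes = np.cumsum(np.concatenate([[beta[1]], beta[2:]]))
    return SegmentedTrendFit(
        years=years.astype(int),
        joinpoint_years=taus,
        coefficients=beta,
        segment_slopes=slopes,
        apc_per_segment=100.0 * (np.exp(slopes) - 1.0),
        rss=rss,
    )


def _candidate_sets(years: np.ndarray, max_joinpoints: int, min_per_segment: int):
    interior = [int(y) for y in years[1:-1]]
    yield ()
    for k in range(1, max_joinpoints + 1):
        for taus in combinations(interior, k):
            bounds = [years.min() - 1, *taus, years.max()]
            sizes = [
                int(np.sum((years > lo) & (years <= hi)))
                for lo, hi in zip(bounds, bounds[1:])
            ]
            if min(sizes) >= min_per_segment:
                yield taus


def _bic(rss: float, n: int, k_joinpoints: int) -> float:
    # parameters: intercept + base slope + (location, slope change) per joinpoint
    p = 2 + 2 * k_joinpoints
    return n * np.log(max(rss, _RSS_FLOOR) / n) + p * np.log(n)


def select_joinpoints(
    series,
    max_joinpoints: int = 4,
    method: str = "bic",
    seed: int | None = None,
    min_per_segment: int = 2,
    n_permutations: int = 499,
    alpha: float = 0.05,
) -> SegmentedTrendFit:
    """Grid-search joinpoint selection over integer interior years.

    ``method="bic"`` (default) scores every admissible joinpoint combination
    by BIC and returns the best fit (ties break towards fewer joinpoints).
    ``method="permutation"`` adds joinpoints sequentially while a Monte-Carlo
    permutation test on the simpler model's residuals rejects at ``alpha``;
    deterministic given ``seed``.
    """
    years, rates = _prepare(series)
    required = 2 * (max_joinpoints + 1) + 1
    if len(years) < required:
        raise ValueError(
            f"series of length {len(years)} is too short for {max_joinpoints} "
            f"joinpoint(s); at least {required} observations are required"
        )
    if method == "bic":
        best = None
        scores = {}
        for taus in _candidate_sets(years, max_joinpoints, min_per_segment):
            fit = fit_fixed_joinpoints((years, rates), taus)
            score = _bic(fit.rss, len(years), len(taus))
            scores.setdefault(len(taus), []).append((score, taus))
            key = (round(score, 12), len(taus))
            if best is None or key < best[0]:
                best = (key, fit)
        fit = best[1]
        fit.selection_scores = {
            k: min(v)[0] for k, v in sorted(scores.items())
        }
        return fit
    if method == "permutation":
        rng = np.random.default_rng(seed)
        current = _best_for_k(years, rates, 0, min_per_segment)
        scores = {}  # p-value for adding the (k+1)-th joinpoint
        k = 0
        while k < max_joinpoints:
            try:
                nxt = _best_for_k(years, rates, k + 1, min_per_segment)
            except ValueError:
                break
            obs = (current.rss - nxt.rss) / max(nxt.rss, _RSS_FLOOR)
            fitted = np.log(current.predict(years))
            resid = np.log(rates) - fitted
            exceed = 0
            for _ in range(n_permutations):
                perm = fitted + rng.permutation(resid)
                r = np.exp(perm)
                null = _best_for_k(years, r, k, min_per_segment)
                alt = _best_for_k(years, r, k + 1, min_per_segment)
                stat = (null.rss - alt.rss) / max(alt.rss, _RSS_FLOOR)
                if stat >= obs:
                    exceed += 1
            pval = (1 + exceed) / (1 + n_permutations)
            scores[k + 1] = pval
            if pval < alpha:
                current, k = nxt, k + 1
            else:
                break
        current.selection_scores = scores
        return current
    raise ValueError(f"unknown method {method!r}; expected 'bic' or 'permutation'")


def _best_for_k(years, rates, k: int, min_per_segment: int) -> SegmentedTrendFit:
    best = None
    found = False
    for taus in _candidate_sets(years, k, min_per_segment):
        if len(taus) != k:
            continue
        found = True
        fit = fit_fixed_joinpoints((years, rates), taus)
        if best is None or fit.rss < best.rss:
            best = fit
    if not found:
        raise ValueError(f"no admissible joinpoint set of size {k}")
    return best
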