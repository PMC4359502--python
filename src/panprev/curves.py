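"""Pan/core gene accumulation curves, Heaps-law fits and openness.

The pan-genome curve counts distinct families seen in the first k genomes
of a permutation; the core curve counts families shared by all first k.
Medians and standard deviations are taken across permutations of the
genome addition order (all n! orders are enumerated when n ≤ 7, otherwise
seeded uniform random permutations are sampled).

Two regression models are fitted to the median points:

* pan genome, power law (Heaps-law regime):  y = A·x^B + C
  openness: 0 < B < 1 → open; B < 0 → closed; otherwise undetermined.
* core genome, exponential decay:  y = A·e^(B·x) + C, asymptote C for B < 0.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Literal, Optional, Sequence

import numpy as np
from scipy.optimize import least_squares

from .panmatrix import PanMatrix


class FittingError(RuntimeError):
    """Nonlinear fit failed to converge after all restarts."""


@dataclass
class CurvePoint:
    x: int
    y_values: np.ndarray
    y_median: float
    y_sd: float


@dataclass
class FitResult:
    model: Literal["power_law", "exponential"]
    A: float
    B: float
    C: float
    r_squared: float
    identifiable: bool = True

    def predict(self, x: np.ndarray | float) -> np.ndarray | float:
        if self.model == "power_law":
            return self.A * np.power(x, self.B) + self.C
        return self.A * np.exp(self.B * np.asarray(x, dtype=float)) + self.C


def accumulate(
    matrix: PanMatrix,
    n_permutations: int = 1000,
    seed: int = 0,
    orders: Optional[Sequence[Sequence[str]]] = None,
) -> tuple[list[CurvePoint], list[CurvePoint], float]:
    """Accumulation curves over genome addition orders.

    Returns ``(pan_curve, core_curve, mean_new_genes_per_added_genome)``.
    ``orders`` may supply explicit genome orderings (e.g. niche-ordered
    plots); otherwise all n! permutations are enumerated when n ≤ 7 and
    ``n_permutations`` seeded uniform permutations are sampled above that.
    """
    if orders is None and n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    genomes = matrix.genomes
    n = len(genomes)
    vals = matrix.values()  # families × genomes
    col = {g: j for j, g in enumerate(genomes)}

    if orders is not None:
        perms = [[col[g] for g in order] for order in orders]
        for order in orders:
            if sorted(order) != sorted(genomes):
                raise ValueError("each order must be a permutation of the genome ids")
    elif n <= 7:
        perms = [list(p) for p in itertools.permutations(range(n))]
    else:
        rng = np.random.default_rng(seed)
        perms = [list(rng.permutation(n)) for _ in range(n_permutations)]

    pan_counts = np.empty((len(perms), n), dtype=np.int64)
    core_counts = np.empty((len(perms), n), dtype=np.int64)
    for i, perm in enumerate(perms):
        sub = vals[:, perm]
        pan_counts[i] = np.logical_or.accumulate(sub, axis=1).sum(axis=0)
        core_counts[i] = np.logical_and.accumulate(sub, axis=1).sum(axis=0)

    def points(counts: np.ndarray) -> list[CurvePoint]:
        return [
            CurvePoint(
                x=k + 1,
                y_values=counts[:, k].copy(),
                y_median=float(np.median(counts[:, k])),
                y_sd=float(np.std(counts[:, k])),
            )
            for k in range(n)
        ]

    if n >= 2:
        increments = np.diff(pan_counts, axis=1)
        mean_new = float(increments.mean())
    else:
        mean_new = 0.0
    return points(pan_counts), points(core_counts), mean_new


def _fit(
    model: Literal["power_law", "exponential"],
    x: np.ndarray,
    y: np.ndarray,
    p0: np.ndarray,
    restarts: int = 20,
    seed: int = 0,
) -> FitResult:
    if model == "power_law":
        def residuals(p: np.ndarray) -> np.ndarray:
            with np.errstate(over="ignore", invalid="ignore"):
                r = p[0] * np.power(x, p[1]) + p[2] - y
            return np.nan_to_num(r, nan=1e150, posinf=1e150, neginf=-1e150)
    else:
        def residuals(p: np.ndarray) -> np.ndarray:
            with np.errstate(over="ignore", invalid="ignore"):
                r = p[0] * np.exp(np.clip(p[1] * x, -700, 700)) + p[2] - y
            return np.nan_to_num(r, nan=1e150, posinf=1e150, neginf=-1e150)

    # keep the exponent in a numerically sane window; data exponents in
    # this problem are O(1) (Heaps exponents and decay rates)
    b_lim = 10.0 if model == "power_law" else 50.0
    bounds = (
        np.array([-np.inf, -b_lim, -np.inf]),
        np.array([np.inf, b_lim, np.inf]),
    )
    rng = np.random.default_rng(seed)
    best = None
    start = np.clip(p0.astype(float), bounds[0] + 1e-9, bounds[1] - 1e-9)
    good_enough = 1e-20 + 1e-16 * float(np.sum(y**2))
    stagnant = 0
    for attempt in range(restarts + 1):
        try:
            sol = least_squares(
                residuals, start, bounds=bounds,
                xtol=1e-10, ftol=1e-10, gtol=1e-10, max_nfev=5000,
            )
        except Exception:
            sol = None
        if sol is not None and sol.success:
            ssr = float(2 * sol.cost)
            if best is None or ssr < best[0] * (1 - 1e-8):
                best = (ssr, sol.x)
                stagnant = 0
            else:
                stagnant += 1
            # restarts exist to rescue non-convergence; once converged
            # solutions stop improving, further jittered starts are waste
            if best[0] <= good_enough or stagnant >= 2:
                break
        else:
            stagnant += 1
        scale = np.where(np.abs(p0) > 1e-9, np.abs(p0), 1.0)
        start = np.clip(
            p0 + rng.normal(scale=0.5 * scale, size=3),
            bounds[0] + 1e-9,
            bounds[1] - 1e-9,
        )
    if best is None:
        raise FittingError(
            f"{model} fit did not converge after {restarts} restarts "
            f"(n={len(x)} points, initial guess {p0.tolist()})"
        )
    ssr, params = best
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    identifiable = True
    if ss_tot == 0.0:
        # flat data: any A≈0 / B≈0 combination fits; flag as degenerate
        r2 = 1.0 if ssr < 1e-12 else 0.0
        identifiable = False
    else:
        r2 = 1.0 - ssr / ss_tot
    return FitResult(model, float(params[0]), float(params[1]), float(params[2]), r2,
                     identifiable)


def _xy(points: Sequence[CurvePoint]) -> tuple[np.ndarray, np.ndarray]:
    x = np.array([p.x for p in points], dtype=float)
    y = np.array([p.y_median for p in points], dtype=float)
    if len(points) < 4:
        raise ValueError("need at least 4 points to fit a 3-parameter model")
    return x, y


def fit_power_law(points: Sequence[CurvePoint]) -> FitResult:
    """Least-squares fit of y = A·x^B + C to the median curve."""
    x, y = _xy(points)
    p0 = np.array([y[-1] - y[0], 0.5, y[0]])
    return _fit("power_law", x, y, np.array([p0[0], p0[1], p0[2]]))


def fit_exponential(points: Sequence[CurvePoint]) -> FitResult:
    """Least-squares fit of y = A·e^(B·x) + C to the median curve."""
    x, y = _xy(points)
    p0 = np.array([y[0] - y[-1], -1.0, y[-1]])
    return _fit("exponential", x, y, p0)


def classify_openness(fit: FitResult) -> Literal["open", "closed", "undetermined"]:
    """Heaps-law verdict from the power-law exponent."""
    if fit.model != "power_law":
        raise ValueError("openness is defined on the power-law (pan) fit")
    if 0.0 < fit.B < 1.0:
        return "open"
    if fit.B < 0.0:
        return "closed"
    return "undetermined"


def extrapolate(fit: FitResult, at: int | Literal["asymptote"]) -> float:
    """Model value at x = ``at``, or the exponential asymptote C.

    The asymptote is only defined for a decaying exponential (B < 0).
    Callers round for display; full precision is returned.
    """
    if at == "asymptote":
        if fit.model != "exponential" or fit.B >= 0:
            raise ValueError("asymptote requires an exponential fit with B < 0")
        return fit.C
    return float(fit.predict(float(at)))
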