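"""Decision-boundary fitting by differential evolution.

The boundary (slope, intercept) is fitted by minimizing the sum, over scans
and calcifications, of absolute differences between the Agatston scores of
the calcium-preserving VNC images and reference scores (e.g. from true
non-contrast calcium CT of the same insert).  Differential evolution runs
within box bounds for up to ``max_iterations`` generations and terminates
early once the relative improvement of the best objective drops below
``rel_tol`` over a sliding window of generations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import differential_evolution

from .phantom import SpectralVolume
from .scoring import ScoringConfig, score_volume
from .spectral import DecisionBoundary, trueca_image

__all__ = ["OptimizationSettings", "ScanCase", "FitResult", "objective", "fit_boundary"]


@dataclass(frozen=True)
class OptimizationSettings:
    """Differential-evolution hyperparameters and stopping rule."""

    bounds_slope: tuple[float, float] = (0.0, 10.0)
    bounds_intercept: tuple[float, float] = (-10000.0, 0.0)
    max_iterations: int = 1000
    rel_tol: float = 0.001
    population_size: int = 30
    mutation: tuple[float, float] = (0.5, 1.0)
    recombination: float = 0.7
    seed: int = 0
    window: int = 20

    def __post_init__(self) -> None:
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")
        if not 0 < self.rel_tol < 1:
            raise ValueError("rel_tol must be in (0, 1)")
        if self.population_size < 4:
            raise ValueError("population_size must be >= 4")
        if self.window < 1:
            raise ValueError("window must be >= 1")


@dataclass
class ScanCase:
    """One spectral scan with its manifest and per-calcification references.

    ``reference`` maps manifest region names to reference 3 mm-equivalent
    Agatston scores; every referenced name must appear in the manifest.
    """

    volume: SpectralVolume
    manifest: list[dict]
    reference: dict[str, float]

    def __post_init__(self) -> None:
        names = {m["name"] for m in self.manifest}
        missing = set(self.reference) - names
        if missing:
            raise ValueError(f"reference names missing from manifest: {sorted(missing)}")


@dataclass
class FitResult:
    boundary: DecisionBoundary
    trace: list[float]
    n_iterations: int
    objective: float
    converged: bool


def objective(
    boundary: DecisionBoundary,
    cases: list[ScanCase],
    config: ScoringConfig = ScoringConfig(),
) -> float:
    """Sum of absolute per-calcification Agatston errors across scans."""
    if not cases:
        raise ValueError("at least one scan is required")
    total = 0.0
    for case in cases:
        if not case.reference:
            raise ValueError("each scan needs at least one referenced calcification")
        image = trueca_image(case.volume, boundary)
        report = score_volume(
            image,
            case.volume.spacing,
            config,
            manifest=case.manifest,
            origin=case.volume.origin,
        )
        scored = report.by_name()
        for name, ref in case.reference.items():
            total += abs(scored[name].agatston_3mm - ref)
    return total


def fit_boundary(
    cases: list[ScanCase],
    settings: OptimizationSettings = OptimizationSettings(),
    config: ScoringConfig = ScoringConfig(),
) -> FitResult:
    """Seeded differential evolution over (slope, intercept).

    Returns the best boundary together with the per-generation best-objective
    trace (non-increasing by construction).  Stops at ``max_iterations`` or
    when the best objective improved by less than ``rel_tol`` (relative) over
    the last ``window`` generations.
    """
    if not cases:
        raise ValueError("at least one scan is required")

    def fun(x: np.ndarray) -> float:
        return objective(DecisionBoundary(float(x[0]), float(x[1])), cases, config)

    trace: list[float] = []

    def callback(xk: np.ndarray, convergence: float = 0.0) -> bool:
        value = fun(xk)
        trace.append(min(value, trace[-1]) if trace else value)
        if len(trace) > settings.window:
            before = trace[-1 - settings.window]
            if before <= 0:
                return True
            if (before - trace[-1]) / before < settings.rel_tol:
                return True
        return False

    # scipy's popsize is a per-parameter multiplier (2 parameters here).
    popsize = max(2, math.ceil(settings.population_size / 2))
    result = differential_evolution(
        fun,
        bounds=[settings.bounds_slope, settings.bounds_intercept],
        maxiter=settings.max_iterations,
        popsize=popsize,
        mutation=settings.mutation,
        recombination=settings.recombination,
        seed=settings.seed,
        tol=0.0,
        atol=0.0,
        polish=False,
        updating="immediate",
        callback=callback,
    )
    best = DecisionBoundary(float(result.x[0]), float(result.x[1]))
    final = float(result.fun)
    if trace:
        trace[-1] = min(trace[-1], final)
    else:
        trace.append(final)
    return FitResult(
        boundary=best,
        trace=trace,
        n_iterations=len(trace),
        objective=final,
        converged=bool(result.success) or len(trace) < settings.max_iterations,
    )
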