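"""Detection power of cell-by-cell comparison against diffuse cell loss.

A single specular micrograph samples only a few hundred of the roughly
380,000 cells of a whole corneal endothelium, yet a cell-by-cell comparison
of an aligned patch is extraordinarily sensitive to diffuse (randomly
distributed) cell loss: a single damaged or missing cell inside the patch
breaks the cell-by-cell identity and is detected. The chance of catching at
least one damaged cell when drawing n cells without replacement from a
population of N with D damaged is hypergeometric:

    P(detect) = 1 - C(N - D, n) / C(N, n)

This module provides the corneal cell-count model behind N, a Monte-Carlo
estimate of P(detect) with its closed-form cross-check, a grid search for
the smallest detectable damage fraction, and — for contrast — the cohort
size a conventional two-sample t-test on cell densities would need to rule
out the same loss.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.stats import hypergeom
from statsmodels.stats.power import TTestIndPower

from .errors import InvalidParameterError


@dataclass(frozen=True)
class CorneaModel:
    """Spherical-cap cornea: a hemisphere of the white-to-white diameter with
    uniform endothelial cell density."""

    white_to_white: float = 11.0  # mm, horizontal corneal diameter
    density: float = 2000.0  # cells / mm^2
    geometry: str = "hemisphere"  # or "disc" (flat disc of the same diameter)

    def __post_init__(self) -> None:
        if self.white_to_white <= 0 or self.density < 0:
            raise InvalidParameterError("white_to_white must be > 0 and density >= 0")
        if self.geometry not in ("hemisphere", "disc"):
            raise InvalidParameterError("geometry must be 'hemisphere' or 'disc'")


@dataclass(frozen=True)
class PowerConfig:
    population: int = 380_000
    sample: int = 300
    damage_fraction: float = 0.01
    reps: int = 1000
    seed: int = 0
    detect_prob_target: float = 0.95

    def __post_init__(self) -> None:
        if not (0 <= self.damage_fraction <= 1):
            raise InvalidParameterError("damage_fraction must be in [0, 1]")
        if self.sample > self.population or self.sample < 0:
            raise InvalidParameterError("need 0 <= sample <= population")
        if self.reps < 1:
            raise InvalidParameterError("reps must be >= 1")


@dataclass(frozen=True)
class TTestDesign:
    delta: float = 20.0  # cells/mm^2, true mean loss to rule out
    sd: float = 200.0  # cells/mm^2, between-eye density standard deviation
    alpha: float = 0.05
    power: float = 0.95
    sides: str = "two"  # "one" | "two"

    def __post_init__(self) -> None:
        if self.sd <= 0 or self.delta <= 0:
            raise InvalidParameterError("delta and sd must be > 0")
        if not (0 < self.alpha < 1 and 0 < self.power < 1):
            raise InvalidParameterError("alpha and power must be in (0, 1)")
        if self.power <= self.alpha:
            raise InvalidParameterError("power must exceed alpha")
        if self.sides not in ("one", "two"):
            raise InvalidParameterError("sides must be 'one' or 'two'")


@dataclass(frozen=True)
class CellCount:
    exact: float
    rounded: int  # to the nearest 10,000


@dataclass(frozen=True)
class DetectionEstimate:
    probability: float  # Monte-Carlo detection fraction
    standard_error: float  # binomial SE of the fraction
    closed_form: float  # hypergeometric P(>= 1 damaged drawn)
    n_detected: int
    config: PowerConfig


def corneal_cell_count(model: CorneaModel | None = None) -> CellCount:
    """Total endothelial cell count under the geometric cornea model.

    The hemisphere of diameter w has surface area 2*pi*(w/2)^2; times the
    density this gives ~380,000 cells at the defaults (11 mm, 2000/mm^2).
    The flat-disc geometry (pi*(w/2)^2) is exposed for comparison — it gives
    half the hemisphere count.
    """
    if model is None:
        model = CorneaModel()
    r = model.white_to_white / 2
    area = 2 * math.pi * r**2 if model.geometry == "hemisphere" else math.pi * r**2
    exact = area * model.density
    return CellCount(exact=exact, rounded=int(round(exact / 10_000) * 10_000))


def hypergeom_detect_prob(population: int, damaged: int, sample: int) -> float:
    """Closed-form P(at least one damaged cell in a sample drawn without
    replacement)."""
    if damaged <= 0 or sample <= 0:
        return 0.0
    if damaged >= population or sample >= population - damaged + 1:
        return 1.0
    return float(1.0 - hypergeom.pmf(0, population, damaged, sample))


def detection_probability(cfg: PowerConfig | None = None) -> DetectionEstimate:
    """Monte-Carlo detection probability of diffuse damage in a sampled patch.

    Each replicate draws ``sample`` cells without replacement from a
    population containing round(damage_fraction x population) damaged cells
    and detects iff at least one damaged cell is drawn (one damaged cell
    inside the aligned patch breaks the cell-by-cell identity). The number
    of damaged cells per draw follows the hypergeometric law exactly, so the
    replicate draws that count directly. The closed-form probability is
    returned alongside as a cross-check.
    """
    if cfg is None:
        cfg = PowerConfig()
    damaged = int(round(cfg.damage_fraction * cfg.population))
    rng = np.random.default_rng(cfg.seed)
    if damaged == 0 or cfg.sample == 0:
        hits = np.zeros(cfg.reps, dtype=bool)
    else:
        draws = rng.hypergeometric(damaged, cfg.population - damaged, cfg.sample,
                                   size=cfg.reps)
        hits = draws >= 1
    p_hat = float(np.mean(hits))
    se = float(np.sqrt(p_hat * (1 - p_hat) / cfg.reps))
    closed = hypergeom_detect_prob(cfg.population, damaged, cfg.sample)
    return DetectionEstimate(
        probability=p_hat, standard_error=se, closed_form=closed,
        n_detected=int(np.sum(hits)), config=cfg,
    )


def detection_threshold(
    population: int = 380_000,
    sample: int = 300,
    target: float = 0.95,
    grid: float = 0.001,
) -> float | None:
    """Smallest damage fraction on the grid detectable with probability >= target.

    Scans damage fractions grid, 2*grid, ... 1 and returns the first whose
    closed-form hypergeometric detection probability reaches the target;
    ``None`` if no grid value does (the explicit not-reachable result).
    """
    if not (0 < target < 1):
        raise InvalidParameterError("target must be in (0, 1)")
    if grid <= 0:
        raise InvalidParameterError("grid must be > 0")
    k = 1
    while True:
        frac = k * grid
        if frac > 1 + 1e-12:
            return None
        frac = min(frac, 1.0)
        damaged = int(round(frac * population))
        if hypergeom_detect_prob(population, damaged, sample) >= target:
            return frac
        if frac >= 1.0:
            return None
        k += 1


def cohort_ttest_total_n(design: TTestDesign | None = None) -> int:
    """Total patients for a two-sample t-test to show the designed density loss.

    Solves the noncentral-t power equation for the per-group sample size
    (statsmodels' exact solver, normal-approximation start) and returns
    2 x ceil(n per group). At the defaults — ruling out a 20 cells/mm^2 loss
    (1% of a 2000 cells/mm^2 baseline) with sd 200, alpha 0.05 two-sided and
    95% power — this exceeds 5000 patients, the reason density comparisons
    cannot certify endothelial stability in ordinary trials.
    """
    if design is None:
        design = TTestDesign()
    alternative = "two-sided" if design.sides == "two" else "larger"
    solver = TTestIndPower()
    es = design.delta / design.sd
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        n = solver.solve_power(
            effect_size=es, alpha=design.alpha, power=design.power,
            ratio=1.0, alternative=alternative,
        )
    n = float(np.atleast_1d(n)[0])
    per_group = math.ceil(n) if math.isfinite(n) and n >= 2 else 2

    from scipy.stats import norm

    z_alpha = norm.ppf(1 - design.alpha / (2 if design.sides == "two" else 1))

    def achieved(nobs: int) -> float:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            p = float(solver.power(effect_size=es, nobs1=nobs, alpha=design.alpha,
                                   ratio=1.0, alternative=alternative))
        if math.isnan(p):  # noncentral-t overflows at extreme noncentrality
            p = float(norm.cdf(es * math.sqrt(nobs / 2) - z_alpha))
        return p

    # the root finder can fail near its lower bound (very large effects);
    # walk to the smallest per-group n that actually reaches the power
    while per_group > 2 and achieved(per_group - 1) >= design.power:
        per_group -= 1
    while achieved(per_group) < design.power:
        per_group += 1
    return 2 * per_group
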