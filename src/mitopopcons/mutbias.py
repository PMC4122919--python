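"""Replication-driven mutation-rate covariate and its removal from polymorphism.

Mammalian mtDNA replicates asymmetrically: leading (heavy-strand) synthesis
starts at the origin O_H and proceeds around the circle; lagging
(light-strand) synthesis starts at O_L, only once the leading fork has passed
it, and runs in the opposite direction.  While waiting for the lagging fork,
the displaced parental heavy strand sits single-stranded and mutates faster.
The duration of single-strandedness, D_ssH, is therefore a per-site
mutation-rate covariate that must be removed before polymorphism can be read
as a signal of selection.

The correction fits a Poisson generalized linear model with the per-site
number of segregating alleles as response and D_ssH as predictor; the model
residuals are "mutation-adjusted polymorphism" used for partial correlation
with divergence.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import statsmodels.api as sm

from .constraint_stats import CorrelationResult, spearman

__all__ = [
    "ReplicationModel",
    "GlmFit",
    "compute_dssh",
    "dssh_track",
    "fit_poisson_glm",
    "residual_partial_correlation",
]


@dataclass
class ReplicationModel:
    """Strand-displacement replication geometry on a circular genome.

    Fork speeds are equal and taken as one base per time unit, so D_ssH is in
    base-pair-time units.  ``leading_direction`` is the direction of leading
    synthesis from ``origin_h`` (+1 = increasing coordinate).
    ``control_region`` intervals (half-open) are excluded from D_ssH analyses.
    ``minor_arc`` selects how sites between O_L and O_H (in leading direction)
    are treated: "wrap" applies the wrap-around formula, "exclude" marks them
    undefined.
    """

    genome_length: int
    origin_h: int
    origin_l: int
    leading_direction: int = 1
    control_region: list[tuple[int, int]] = field(default_factory=list)
    minor_arc: str = "wrap"

    def __post_init__(self) -> None:
        L = self.genome_length
        if not (0 <= self.origin_h < L and 0 <= self.origin_l < L):
            raise ValueError("origins must lie inside the genome")
        if self.origin_h == self.origin_l:
            raise ValueError("origins must be distinct")
        if self.leading_direction not in (1, -1):
            raise ValueError("leading_direction must be +1 or -1")
        if self.minor_arc not in ("wrap", "exclude"):
            raise ValueError("minor_arc must be 'wrap' or 'exclude'")

    def in_control_region(self, site: int) -> bool:
        return any(s <= site < e for s, e in self.control_region)

    @property
    def origin_distance(self) -> int:
        """Leading-strand distance from O_H to O_L."""
        return (self.leading_direction * (self.origin_l - self.origin_h)) % self.genome_length


def compute_dssh(model: ReplicationModel, site: int) -> float:
    """Single-strandedness duration of one site under unit fork speeds.

    Let d be the leading-strand distance from O_H to the site and D the
    leading distance from O_H to O_L.  A major-arc site (d <= D) becomes
    single-stranded when the leading fork passes it (time d) and is rescued
    by the lagging fork, which starts at O_L at time D and travels back, at
    time D + (D - d); hence D_ssH = 2(D - d).  A minor-arc site at d = D + y
    is passed by the leading fork at time D + y but the lagging fork, going
    the other way round, reaches it at time D + (L - y); if the lagging fork
    arrives first the site is never single-stranded, giving
    D_ssH = max(L - 2y, 0).
    """
    L = model.genome_length
    if not (0 <= site < L):
        raise ValueError(f"site {site} outside genome 0..{L - 1}")
    if model.in_control_region(site):
        raise ValueError(f"site {site} lies inside the omitted control region")
    d = (model.leading_direction * (site - model.origin_h)) % L
    D = model.origin_distance
    if d <= D:
        return float(2 * (D - d))
    if model.minor_arc == "exclude":
        return float("nan")
    y = d - D
    return float(max(L - 2 * y, 0))


def dssh_track(model: ReplicationModel) -> np.ndarray:
    """D_ssH per site; NaN inside the control region (and on an excluded minor arc)."""
    L = model.genome_length
    d = (model.leading_direction * (np.arange(L) - model.origin_h)) % L
    D = model.origin_distance
    values = np.where(d <= D, 2.0 * (D - d), np.maximum(L - 2.0 * (d - D), 0.0))
    if model.minor_arc == "exclude":
        values = np.where(d <= D, values, np.nan)
    for s, e in model.control_region:
        values[s:e] = np.nan
    return values


@dataclass
class GlmFit:
    """A fitted Poisson log-link regression of allele counts on D_ssH."""

    intercept: float
    slope: float | None
    fitted: np.ndarray
    residuals: np.ndarray
    residual_type: str
    iterations: int
    deviance: float
    deviance_history: list[float]
    converged: bool


def fit_poisson_glm(
    counts,
    covariate,
    residual_type: str = "deviance",
    tol: float = 1e-8,
    max_iter: int = 100,
) -> GlmFit:
    """Poisson log-link GLM of per-site counts on a single covariate.

    Fitted by iteratively reweighted least squares until the relative
    deviance change drops below ``tol``.  ``residual_type`` selects deviance
    (default), Pearson or response residuals.  A constant covariate leaves
    the slope unidentified; an intercept-only model is fitted with a warning.
    """
    counts = np.asarray(counts, dtype=float)
    covariate = np.asarray(covariate, dtype=float)
    if counts.shape != covariate.shape:
        raise ValueError("counts and covariate must have equal length")
    if not np.isfinite(covariate).all():
        raise ValueError("covariate contains non-finite values")
    if (counts < 0).any() or not np.allclose(counts, np.round(counts)):
        raise ValueError("counts must be non-negative integers")
    if residual_type not in ("deviance", "pearson", "response"):
        raise ValueError(f"unknown residual type {residual_type!r}")

    constant = np.ptp(covariate) == 0
    if constant:
        warnings.warn(
            "constant covariate: slope unidentified, fitting intercept-only model",
            stacklevel=2,
        )
        design = np.ones((len(counts), 1))
    else:
        design = sm.add_constant(covariate)

    model = sm.GLM(counts, design, family=sm.families.Poisson())
    result = model.fit(maxiter=max_iter, tol=tol, scale=1.0)
    if not result.converged:
        raise RuntimeError(
            f"IRLS did not converge in {max_iter} iterations; "
            f"deviance trace: {list(result.fit_history['deviance'])}"
        )
    residuals = {
        "deviance": result.resid_deviance,
        "pearson": result.resid_pearson,
        "response": result.resid_response,
    }[residual_type]
    # drop the evaluation at the starting values: the monotonicity contract
    # covers the IRLS iterates themselves
    history = [float(d) for d in result.fit_history["deviance"] if np.isfinite(d)][1:]
    return GlmFit(
        intercept=float(result.params[0]),
        slope=None if constant else float(result.params[1]),
        fitted=np.asarray(result.fittedvalues, dtype=float),
        residuals=np.asarray(residuals, dtype=float),
        residual_type=residual_type,
        iterations=int(result.fit_history["iteration"]),
        deviance=float(result.deviance),
        deviance_history=history,
        converged=bool(result.converged),
    )


def residual_partial_correlation(fit: GlmFit, scores) -> CorrelationResult:
    """Spearman correlation between GLM residuals and a divergence score.

    This is the partial polymorphism–divergence correlation after removing
    the D_ssH mutational gradient.  Scores must be aligned to the sites used
    in the fit (control-region sites already excluded).
    """
    scores = np.asarray(scores, dtype=float)
    if scores.shape != fit.residuals.shape:
        raise ValueError("scores not aligned to fitted sites")
    return spearman(fit.residuals, scores)
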