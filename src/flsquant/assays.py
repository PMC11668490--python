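"""Non-imaging assay arithmetic: sedimentation densitometry and ELISA curves.

Co-sedimentation densitometry summarizes how much of a protein pellets
with F-actin: each gel band (pellet and supernatant) is background-
corrected by subtracting the mean of strips sampled above and below it,
and the pellet fraction is

    pellet / (pellet + supernatant) × 100.

ELISA dose-response data are fitted with the four-parameter logistic
(variable-slope) model

    R(x) = bottom + (top - bottom) / (1 + (ec50 / x)^hill),

whose EC50 is the concentration at half-maximal response.  The fit is
unweighted least squares over all replicate points, multi-started over a
grid of initial EC50s and Hill slopes so that a poor single start cannot
masquerade as non-convergence.  Affinity changes between two conditions
are summarized as EC50 fold changes with a CI propagated on the log
scale.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.optimize import least_squares

__all__ = [
    "BandMeasurement",
    "pellet_fraction",
    "BindingCurve",
    "FoldChange",
    "four_pl",
    "fit_binding_curve",
    "ec50_fold_change",
    "simulate_binding_responses",
]


# ---------------------------------------------------------------------------
# densitometry
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class BandMeasurement:
    """One gel band intensity with its local background strips."""

    intensity: float
    background_strips: tuple[float, ...] = ()  # typically two above + two below

    def corrected(self) -> float:
        if self.intensity < 0 or any(s < 0 for s in self.background_strips):
            raise ValueError("band intensities must be non-negative")
        bg = float(np.mean(self.background_strips)) if self.background_strips else 0.0
        value = self.intensity - bg
        if value < 0:
            warnings.warn(
                f"background ({bg:.3g}) exceeds band intensity "
                f"({self.intensity:.3g}); clipping to 0"
            )
            value = 0.0
        return value


def pellet_fraction(pellet: BandMeasurement, supernatant: BandMeasurement) -> float:
    """Background-corrected percentage of protein in the pellet.

    Returns NaN (with a warning) when both corrected intensities are
    zero, in which case the fraction is undefined.
    """
    p = pellet.corrected()
    s = supernatant.corrected()
    if p + s == 0:
        warnings.warn("both corrected band intensities are zero; fraction undefined")
        return float("nan")
    return 100.0 * p / (p + s)


# ---------------------------------------------------------------------------
# binding curves
# ---------------------------------------------------------------------------


def four_pl(
    x: np.ndarray, bottom: float, top: float, ec50: float, hill: float
) -> np.ndarray:
    """Four-parameter logistic response at concentrations ``x``."""
    x = np.asarray(x, dtype=float)
    return bottom + (top - bottom) / (1.0 + (ec50 / x) ** hill)


@dataclass
class BindingCurve:
    bottom: float
    top: float
    ec50: float
    hill: float
    converged: bool
    rss: float  # residual sum of squares
    n: int
    se_log10_ec50: float  # standard error of log10(EC50)
    flags: tuple[str, ...] = ()

    def response_at(self, x) -> np.ndarray:
        return four_pl(x, self.bottom, self.top, self.ec50, self.hill)


def _fit_once(
    logc: np.ndarray, y: np.ndarray, theta0: np.ndarray
) -> tuple[np.ndarray, float, bool, np.ndarray]:
    """One least-squares run in (bottom, top, log10_ec50, hill) space."""

    def resid(theta):
        bottom, top, log_ec50, hill = theta
        with np.errstate(over="ignore"):  # extreme hill during exploration
            denom = 1.0 + 10.0 ** (hill * (log_ec50 - logc))
        return bottom + (top - bottom) / denom - y

    res = least_squares(resid, theta0, method="lm", max_nfev=5000)
    return res.x, float(np.sum(res.fun**2)), res.success, res.jac


def fit_binding_curve(
    concentrations: Sequence[float], responses: Sequence[float]
) -> BindingCurve:
    """Unweighted 4PL fit of (concentration, response) points.

    Replicates are passed as repeated concentrations.  At least four
    distinct positive concentrations are required.  Non-convergence is
    reported in ``converged`` and ``flags`` rather than silently
    defaulted; a non-positive fitted Hill slope on ascending data is
    flagged ``hill_nonpositive``.
    """
    x = np.asarray(concentrations, dtype=float)
    y = np.asarray(responses, dtype=float)
    if x.shape != y.shape:
        raise ValueError("concentrations and responses must align")
    if np.any(x <= 0):
        raise ValueError("concentrations must be strictly positive")
    if not np.all(np.isfinite(y)):
        raise ValueError("responses must be finite")
    if np.unique(x).size < 4:
        raise ValueError("need at least four distinct concentrations")

    logc = np.log10(x)
    lo, hi = float(y.min()), float(y.max())
    span = hi - lo if hi > lo else max(abs(hi), 1.0)
    starts = []
    for q in (0.2, 0.4, 0.5, 0.6, 0.8):
        log_ec50 = np.quantile(logc, q)
        for hill in (0.5, 1.0, 2.0):
            starts.append(np.array([lo, hi, log_ec50, hill]))

    best = None
    for theta0 in starts:
        try:
            theta, rss, ok, jac = _fit_once(logc, y, theta0)
        except Exception:  # numerical failure of one start is not fatal
            continue
        if not np.all(np.isfinite(theta)):
            continue
        if best is None or rss < best[1] - 1e-12 * (1 + best[1]):
            best = (theta, rss, ok, jac)
    if best is None:
        return BindingCurve(
            bottom=np.nan, top=np.nan, ec50=np.nan, hill=np.nan,
            converged=False, rss=np.nan, n=len(y), se_log10_ec50=np.nan,
            flags=("no_convergence",),
        )

    theta, rss, ok, jac = best
    bottom, top, log_ec50, hill = theta
    flags = []
    if not ok:
        flags.append("no_convergence")
    if hill <= 0:
        flags.append("hill_nonpositive")
    if top < bottom:
        # the 4PL is symmetric under (bottom<->top, hill->-hill)
        bottom, top, hill = top, bottom, -hill
        flags.append("reparameterized")

    # parameter covariance from the Gauss-Newton approximation
    dof = max(1, len(y) - 4)
    se_log = np.nan
    try:
        jtj = jac.T @ jac
        cov = np.linalg.inv(jtj) * (rss / dof)
        se_log = float(np.sqrt(cov[2, 2]))
    except np.linalg.LinAlgError:
        flags.append("singular_covariance")
    return BindingCurve(
        bottom=float(bottom),
        top=float(top),
        ec50=float(10.0**log_ec50),
        hill=float(hill),
        converged=ok,
        rss=rss,
        n=len(y),
        se_log10_ec50=se_log,
        flags=tuple(flags),
    )


@dataclass(frozen=True)
class FoldChange:
    value: float
    ci_low: float
    ci_high: float
    flags: tuple[str, ...] = ()


def ec50_fold_change(
    curve_a: BindingCurve, curve_b: BindingCurve, confidence: float = 0.95
) -> FoldChange:
    """EC50(a) / EC50(b) with a log-scale error-propagated CI.

    Fit flags on either curve are propagated into the result.
    """
    from scipy import stats

    flags = tuple(
        f"a:{f}" for f in curve_a.flags) + tuple(f"b:{f}" for f in curve_b.flags
    )
    fold = curve_a.ec50 / curve_b.ec50
    se = np.sqrt(
        np.nan_to_num(curve_a.se_log10_ec50, nan=0.0) ** 2
        + np.nan_to_num(curve_b.se_log10_ec50, nan=0.0) ** 2
    )
    z = stats.norm.ppf(0.5 + confidence / 2)
    log_fold = np.log10(fold)
    return FoldChange(
        value=float(fold),
        ci_low=float(10.0 ** (log_fold - z * se)),
        ci_high=float(10.0 ** (log_fold + z * se)),
        flags=flags,
    )


def simulate_binding_responses(
    concentrations: Sequence[float],
    bottom: float,
    top: float,
    ec50: float,
    hill: float,
    noise_frac: float = 0.0,
    replicates: int = 1,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Replicated 4PL responses with Gaussian noise (fraction of the span)."""
    if rng is None:
        rng = np.random.default_rng()
    x = np.repeat(np.asarray(concentrations, dtype=float), replicates)
    y = four_pl(x, bottom, top, ec50, hill)
    if noise_frac > 0:
        y = y + rng.normal(0.0, noise_frac * abs(top - bottom), size=y.shape)
    return x, y
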