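"""Posterior contrasts: power ratios with pointwise credible envelopes.

Group and meal comparisons are linear functionals of the fixed-effect
functions beta_p(x).  Because responses are log power, a difference of
condition-cell means is a log power *ratio*: its pointwise 95% credible
band excludes 0 (ratio 1) exactly where the two conditions differ
credibly.  No extra multiple-comparison adjustment is applied -- the GP
prior over locations is the model's smoothing/correlation mechanism.

Weights are assembled from condition-cell means (via the stored design
coding) rather than raw coefficients, so contrasts are invariant to the
coding scheme.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .design import fixed_row
from .model import PosteriorDraws

__all__ = ["ContrastResult", "contrast", "cell_weights", "meal_effect",
           "group_difference", "meal_by_group_interaction"]


@dataclass
class ContrastResult:
    """Draws and pointwise credible band of one log-ratio curve/surface."""

    log_ratio_draws: np.ndarray      # (n_draws, n_points)
    band: np.ndarray                 # (2, n_points): lower, upper
    significant: np.ndarray          # bool (n_points,)
    level: float = 0.95
    name: str = ""
    meta: dict = field(default_factory=dict)

    @property
    def median(self) -> np.ndarray:
        return np.median(self.log_ratio_draws, axis=0)

    @property
    def ratio_band(self) -> np.ndarray:
        """Band on the ratio scale (reference line at 1)."""
        return np.exp(self.band)


def contrast(draws, weights, level: float = 0.95, name: str = "",
             method: str = "quantile") -> ContrastResult:
    """Linear contrast of the fixed-effect functions.

    ``draws`` is a :class:`PosteriorDraws` or a (n_draws, P, n_points)
    beta array (e.g. refined); ``weights`` is a length-P vector.  The band
    is the pointwise central ``level`` interval (equal-tailed quantiles by
    default; ``method="hpd"`` uses highest-density intervals), and a point
    is significant when its band excludes log-ratio 0.
    """
    beta = draws.beta if isinstance(draws, PosteriorDraws) else \
        np.asarray(draws, float)
    weights = np.asarray(weights, float)
    if weights.shape != (beta.shape[1],):
        raise ValueError(
            f"weight vector has length {weights.shape}, expected "
            f"({beta.shape[1]},) fixed-effect columns")
    if not 0 < level < 1:
        raise ValueError("level must be in (0, 1)")
    lr = np.einsum("dpk,p->dk", beta, weights)
    alpha = 100.0 * (1.0 - level) / 2.0
    if method == "quantile":
        band = np.percentile(lr, [alpha, 100.0 - alpha], axis=0)
    elif method == "hpd":
        import arviz as az
        hdi = az.hdi(lr[None, :, :], hdi_prob=level)
        band = np.asarray(hdi).T
    else:
        raise ValueError(f"unknown interval method {method!r}")
    sig = (band[0] > 0) | (band[1] < 0)
    return ContrastResult(lr, band, sig, level=level, name=name)


def cell_weights(draws: PosteriorDraws, plus: list[dict],
                 minus: list[dict]) -> np.ndarray:
    """Weight vector for sum(cell means in plus) - sum(in minus)."""
    if draws.dm is None:
        raise ValueError("draws carry no design matrices")
    w = np.zeros(draws.beta.shape[1])
    for cell in plus:
        w += fixed_row(draws.dm, **cell)
    for cell in minus:
        w -= fixed_row(draws.dm, **cell)
    return w


def _base_cell(draws: PosteriorDraws, **fixed) -> dict:
    """Fill unspecified standard factors with their reference level."""
    cell = dict(fixed)
    obs = draws.dm.obs if draws.dm is not None else None
    for col, ref in (("group", "healthy"), ("region", "descending"),
                     ("meal", "preprandial")):
        if col not in cell and obs is not None and col in obs.columns:
            cell[col] = ref
    return cell


def meal_effect(draws: PosteriorDraws, group: str = "healthy",
                region: str | None = None, level: float = 0.95,
                beta=None) -> ContrastResult:
    """Postprandial vs preprandial log power ratio within one group."""
    kw = {"group": group}
    if region is not None:
        kw["region"] = region
    post = _base_cell(draws, meal="postprandial", **kw)
    pre = _base_cell(draws, meal="preprandial", **kw)
    w = cell_weights(draws, [post], [pre])
    target = beta if beta is not None else draws
    return contrast(target, w, level=level,
                    name=f"meal_effect[{group}"
                         + (f",{region}]" if region else "]"))


def group_difference(draws: PosteriorDraws, meal: str = "postprandial",
                     region: str | None = None, level: float = 0.95,
                     beta=None) -> ContrastResult:
    """Patients vs healthy log power ratio within one meal period."""
    kw = {"meal": meal}
    if region is not None:
        kw["region"] = region
    pat = _base_cell(draws, group="patient", **kw)
    hea = _base_cell(draws, group="healthy", **kw)
    w = cell_weights(draws, [pat], [hea])
    target = beta if beta is not None else draws
    return contrast(target, w, level=level,
                    name=f"group_difference[{meal}"
                         + (f",{region}]" if region else "]"))


def meal_by_group_interaction(draws: PosteriorDraws,
                              region: str | None = None,
                              level: float = 0.95, beta=None
                              ) -> ContrastResult:
    """Difference of meal effects: (patient post - pre) - (healthy
    post - pre); tests whether the meal response differs between groups."""
    kw = {"region": region} if region is not None else {}
    cells_p = [_base_cell(draws, group="patient", meal="postprandial", **kw),
               _base_cell(draws, group="healthy", meal="preprandial", **kw)]
    cells_m = [_base_cell(draws, group="patient", meal="preprandial", **kw),
               _base_cell(draws, group="healthy", meal="postprandial", **kw)]
    w = cell_weights(draws, cells_p, cells_m)
    target = beta if beta is not None else draws
    return contrast(target, w, level=level, name="meal_by_group_interaction")
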