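"""Design matrices for the functional mixed model from formula notation.

The mean formula follows the familiar mixed-model syntax, e.g.
``"group*region*meal + (region*meal|subject)"``: the unparenthesized part
becomes the fixed-effect matrix X (treatment coding, references healthy /
descending / preprandial) and each ``(expr|factor)`` term becomes a block
of the random-effect matrix Z -- one block of ``expr``-columns per level of
``factor``, block-diagonal over levels.  The scale formula (e.g.
``"group*region*meal + nchan"``) builds W the same way; numeric predictors
such as the channel count are standardized to zero mean / unit sd across
observations.  With no random scale terms U is empty (the "U = 0" design:
no repeated measurements, so within-subject scale variation is not
identifiable).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from patsy import PatsyError, dmatrix

__all__ = ["DesignMatrices", "build_design_matrices", "fixed_row"]

_FACTOR_LEVELS = {
    "group": ["healthy", "patient"],
    "region": ["descending", "sigmoid"],
    "meal": ["preprandial", "postprandial"],
}

_BAR_RE = re.compile(r"\(\s*([^()|]+)\|\s*([^()|]+)\s*\)")


@dataclass
class DesignMatrices:
    """X (fixed mean), Z (random mean), W (fixed log-scale), U (random
    log-scale) with column labels and the subject blocking of Z."""

    X: np.ndarray
    Z: np.ndarray
    W: np.ndarray
    U: np.ndarray
    x_labels: list[str]
    z_labels: list[str]
    w_labels: list[str]
    u_labels: list[str]
    groups: list[str] = field(default_factory=list)      # Z block levels
    effects_per_group: int = 0                           # Z block width
    x_design_info: object | None = None
    obs: pd.DataFrame | None = None

    @property
    def n_obs(self) -> int:
        return self.X.shape[0]


def _split_formula(formula: str):
    """Separate fixed part from (expr|group) random terms."""
    random_terms = [(expr.strip(), grp.strip())
                    for expr, grp in _BAR_RE.findall(formula)]
    fixed = _BAR_RE.sub("", formula)
    fixed = re.sub(r"\+\s*(\+|$)", r"\1", fixed).strip().rstrip("+").strip()
    return fixed or "1", random_terms


def _with_levels(obs: pd.DataFrame) -> pd.DataFrame:
    """Order the standard factors so reference levels are healthy /
    descending / preprandial under treatment coding."""
    obs = obs.copy()
    for col, levels in _FACTOR_LEVELS.items():
        if col in obs.columns and set(obs[col].unique()) <= set(levels):
            present = [lv for lv in levels if lv in set(obs[col])]
            obs[col] = pd.Categorical(obs[col], categories=present)
    return obs


def _standardize_numeric(obs: pd.DataFrame, formula: str) -> pd.DataFrame:
    obs = obs.copy()
    for col in obs.columns:
        if (re.search(rf"\b{re.escape(col)}\b", formula)
                and pd.api.types.is_numeric_dtype(obs[col])):
            v = obs[col].to_numpy(float)
            sd = v.std()
            obs[col] = (v - v.mean()) / sd if sd > 0 else v * 0.0
    return obs


def _dmatrix(formula: str, obs: pd.DataFrame):
    try:
        dm = dmatrix(formula, obs, return_type="dataframe",
                     NA_action="raise")
    except PatsyError as e:
        raise ValueError(f"cannot build design matrix for {formula!r}: {e}")
    return dm.to_numpy(), list(dm.columns), dm.design_info


def build_design_matrices(obs: pd.DataFrame,
                          mean_formula: str = "group*region*meal"
                                              " + (region*meal|subject)",
                          scale_formula: str = "group*region*meal + nchan",
                          ) -> DesignMatrices:
    """Build X, Z, W, U from an observation table and two formulas."""
    obs = _with_levels(obs)
    N = len(obs)

    fixed_mean, rand_mean = _split_formula(mean_formula)
    fixed_scale, rand_scale = _split_formula(scale_formula)

    X, x_labels, x_info = _dmatrix(fixed_mean, obs)

    obs_std = _standardize_numeric(obs, fixed_scale)
    W, w_labels, _ = _dmatrix(fixed_scale, obs_std)

    def build_random(terms):
        if not terms:
            return np.zeros((N, 0)), [], [], 0
        if len(terms) > 1:
            raise ValueError("only one (expr|group) term is supported")
        expr, grp = terms[0]
        if grp not in obs.columns:
            raise ValueError(f"grouping factor {grp!r} not in table")
        R, r_labels, _ = _dmatrix(expr, obs)
        levels = list(dict.fromkeys(obs[grp].astype(str)))
        E = R.shape[1]
        Zm = np.zeros((N, E * len(levels)))
        for i, lv in enumerate(obs[grp].astype(str)):
            j = levels.index(lv)
            Zm[i, j * E:(j + 1) * E] = R[i]
        labels = [f"{lv}:{lab}" for lv in levels for lab in r_labels]
        return Zm, labels, levels, E

    Z, z_labels, groups, E = build_random(rand_mean)
    U, u_labels, _, _ = build_random(rand_scale)

    return DesignMatrices(X=X, Z=Z, W=W, U=U,
                          x_labels=x_labels, z_labels=z_labels,
                          w_labels=w_labels, u_labels=u_labels,
                          groups=groups, effects_per_group=E,
                          x_design_info=x_info, obs=obs)


def fixed_row(dm: DesignMatrices, **cell) -> np.ndarray:
    """Fixed-effect row vector for one factor cell, e.g.
    ``fixed_row(dm, group="healthy", region="sigmoid", meal="postprandial")``.

    Used by the contrast module to express comparisons as differences of
    cell means, which makes them invariant to the coding scheme.
    """
    if dm.x_design_info is None:
        raise ValueError("design matrices carry no patsy design info")
    row = {}
    for col, levels in _FACTOR_LEVELS.items():
        if col in cell:
            if cell[col] not in levels and dm.obs is not None \
                    and cell[col] not in set(dm.obs[col].astype(str)):
                raise ValueError(f"unknown level {cell[col]!r} for {col!r}")
            row[col] = [cell[col]]
    for k, v in cell.items():
        if k not in row:
            row[k] = [v]
    from patsy import build_design_matrices as _bdm
    (mat,) = _bdm([dm.x_design_info], pd.DataFrame(row))
    return np.asarray(mat)[0]
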