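"""Bivariate mixed-model evaluation (PBLUP / single-step GBLUP).

The model treats the breeding-goal trait expressed in the two environments
as two correlated traits.  For trait ``i`` (environment ``i``):

    y_i = X_i beta_i + Z_i a_i + e_i

with ``beta_i`` the generation means of environment ``i`` (one fixed level
per generation with records), ``a_i`` the additive genetic effects of every
pedigree animal, and diagonal residuals.  The genetic (co)variance is

    var([a_1; a_2]) = [[s2a1, rg*sa1*sa2], [rg*sa1*sa2, s2a2]] (x) H

where ``H`` is the pedigree relationship matrix (PBLUP) or the unified
single-step matrix (ssGBLUP), entering the equations through its sparse
inverse.  Residual covariance between the traits is zero because an animal
expresses the trait in exactly one environment.  Within-environment
evaluation sets the evaluation ``rg`` to zero, which decouples the system
into two univariate analyses.

Every animal in the pedigree — phenotyped or not, either environment —
receives an EBV for both traits.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.sparse.linalg import splu

__all__ = ["EvaluationSpec", "EvaluationResult", "build_mme", "solve_mme",
           "evaluate", "accuracy_report"]

# evaluation rg is clipped away from +/-1 so the 2x2 genetic covariance
# stays invertible; at this distance the two EBV columns agree to ~1e-7
_RG_CLIP = 1.0 - 1e-8


@dataclass
class EvaluationSpec:
    """Evaluation mode, scope and (assumed known) variance components."""

    mode: str                   # 'pedigree' | 'single_step'
    scope: str                  # 'within' | 'across'
    sigma2_a1: float = 1.0
    sigma2_a2: float = 1.0
    rg: float = 0.0             # genetic correlation assumed by the model
    sigma2_e1: float = 1.0
    sigma2_e2: float = 1.0

    def __post_init__(self) -> None:
        if self.mode not in ("pedigree", "single_step"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.scope not in ("within", "across"):
            raise ValueError(f"unknown scope {self.scope!r}")

    @property
    def rg_eval(self) -> float:
        """The rg actually used: 0 under within-environment scope."""
        if self.scope == "within":
            return 0.0
        return float(np.clip(self.rg, -_RG_CLIP, _RG_CLIP))

    def genetic_covariance(self) -> np.ndarray:
        sa1, sa2 = np.sqrt(self.sigma2_a1), np.sqrt(self.sigma2_a2)
        cov = self.rg_eval * sa1 * sa2
        return np.array([[self.sigma2_a1, cov], [cov, self.sigma2_a2]])


@dataclass
class EvaluationResult:
    """EBVs for both traits plus fixed-effect estimates and diagnostics."""

    ebv: np.ndarray                     # (n_animals, 2)
    fixed_effects: dict                 # trait -> {generation: estimate}
    residual_norm: float
    n_equations: int
    spec: EvaluationSpec = field(repr=False, default=None)


def _design(records: pd.DataFrame, trait: int):
    """Return (generation-level codes, animal indices, y, levels) for one
    trait."""
    sub = records[records["trait"] == trait]
    gens, lev = np.unique(sub["generation"].to_numpy(), return_inverse=True)
    return (lev, sub["animal"].to_numpy(dtype=np.int64),
            sub["phenotype"].to_numpy(dtype=np.float64), gens)


def build_mme(records: pd.DataFrame, spec: EvaluationSpec,
              h_inv: sp.spmatrix):
    """Assemble the mixed-model equations.

    ``records`` needs columns ``animal`` (position in the pedigree ordering),
    ``trait`` (1 or 2, the environment of the record), ``generation`` and
    ``phenotype``.  Each animal may carry a record for at most one trait.
    The coefficient matrix is assembled as a single COO triplet list to keep
    the dense genomic correction block cheap to handle.
    """
    n = h_inv.shape[0]
    if records["animal"].duplicated().any():
        raise ValueError("an animal may have at most one phenotype record")
    lev1, an1, y1, gens1 = _design(records, 1)
    lev2, an2, y2, gens2 = _design(records, 2)
    r1, r2 = 1.0 / spec.sigma2_e1, 1.0 / spec.sigma2_e2
    K = np.linalg.inv(spec.genetic_covariance())

    b1, b2 = len(gens1), len(gens2)
    off = {"b1": 0, "b2": b1, "a1": b1 + b2, "a2": b1 + b2 + n}
    N = b1 + b2 + 2 * n
    rows, cols, data = [], [], []

    def add(r, c, v):
        rows.append(r)
        cols.append(c)
        data.append(v)

    for lev, an, y, r, bo, ao, nb in ((lev1, an1, y1, r1, off["b1"],
                                       off["a1"], b1),
                                      (lev2, an2, y2, r2, off["b2"],
                                       off["a2"], b2)):
        if nb:
            add(bo + np.arange(nb), bo + np.arange(nb),
                np.bincount(lev, minlength=nb) * r)          # X'X
        if len(an):
            add(bo + lev, ao + an, np.full(len(an), r))      # X'Z
            add(ao + an, bo + lev, np.full(len(an), r))
            add(ao + an, ao + an, np.full(len(an), r))       # Z'Z (coo sums)
    hcoo = h_inv.tocoo()
    for i in range(2):
        for j in range(2):
            if K[i, j] != 0.0:
                ai, aj = off[f"a{i + 1}"], off[f"a{j + 1}"]
                add(hcoo.row + ai, hcoo.col + aj, K[i, j] * hcoo.data)
    lhs = sp.coo_matrix(
        (np.concatenate(data),
         (np.concatenate(rows), np.concatenate(cols))), shape=(N, N)).tocsc()

    rhs = np.zeros(N)
    np.add.at(rhs, off["b1"] + lev1, y1 * r1)
    np.add.at(rhs, off["b2"] + lev2, y2 * r2)
    np.add.at(rhs, off["a1"] + an1, y1 * r1)
    np.add.at(rhs, off["a2"] + an2, y2 * r2)
    layout = {"b1": (0, b1), "b2": (b1, b1 + b2),
              "a1": (b1 + b2, b1 + b2 + n),
              "a2": (b1 + b2 + n, b1 + b2 + 2 * n),
              "gens1": gens1, "gens2": gens2}
    return lhs, rhs, layout


def solve_mme(lhs: sp.spmatrix, rhs: np.ndarray, layout: dict,
              spec: EvaluationSpec, tolerance: float = 1e-8,
              ) -> EvaluationResult:
    """Solve the equations by sparse LU and package the solution."""
    sol = splu(lhs.tocsc()).solve(rhs)
    denom = np.linalg.norm(rhs)
    res = np.linalg.norm(lhs @ sol - rhs) / (denom if denom > 0 else 1.0)
    if not np.isfinite(res) or res > max(tolerance, 1e-6):
        raise RuntimeError(f"mixed-model solve failed: relative residual {res:.2e}")
    lo1, hi1 = layout["a1"]
    lo2, hi2 = layout["a2"]
    ebv = np.column_stack([sol[lo1:hi1], sol[lo2:hi2]])
    fixed = {
        1: dict(zip(layout["gens1"], sol[layout["b1"][0]:layout["b1"][1]])),
        2: dict(zip(layout["gens2"], sol[layout["b2"][0]:layout["b2"][1]])),
    }
    return EvaluationResult(ebv=ebv, fixed_effects=fixed, residual_norm=res,
                            n_equations=lhs.shape[0], spec=spec)


def evaluate(records: pd.DataFrame, spec: EvaluationSpec,
             h_inv: sp.spmatrix, tolerance: float = 1e-8) -> EvaluationResult:
    """Build and solve the mixed-model equations in one call."""
    lhs, rhs, layout = build_mme(records, spec, h_inv)
    return solve_mme(lhs, rhs, layout, spec, tolerance)


def accuracy_report(ebv: np.ndarray, animals: pd.DataFrame,
                    group_cols=("generation", "env"), min_group: int = 3,
                    ) -> pd.DataFrame:
    """Pearson correlation of own-environment EBV with TBV per group.

    ``animals`` needs ``tbv1``/``tbv2`` and ``env`` (1/2) columns plus the
    grouping columns; rows align with the rows of ``ebv``.  Groups smaller
    than ``min_group`` are skipped.
    """
    df = animals.reset_index(drop=True).copy()
    own = np.where(df["env"].to_numpy() == 1, ebv[:, 0], ebv[:, 1])
    tbv = np.where(df["env"].to_numpy() == 1,
                   df["tbv1"].to_numpy(), df["tbv2"].to_numpy())
    df["_ebv"], df["_tbv"] = own, tbv
    rows = []
    for key, sub in df.groupby(list(group_cols)):
        if len(sub) < min_group or sub["_ebv"].std() == 0 or sub["_tbv"].std() == 0:
            continue
        key = key if isinstance(key, tuple) else (key,)
        rows.append(dict(zip(group_cols, key),
                         accuracy=float(np.corrcoef(sub["_ebv"], sub["_tbv"])[0, 1]),
                         n=len(sub)))
    return pd.DataFrame(rows)
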