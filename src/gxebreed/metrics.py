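"""Endpoints: genetic gain, rate of inbreeding, external-sire proportions,
split-point genetic correlation, ancestor contributions.

* Genetic gain per generation is the OLS slope of the mean newborn TBV
  (own-environment trait) on generation over a late window, in base genetic
  standard deviations.
* The rate of inbreeding uses the identity ``F_t = 1 - (1 - dF)^t``:
  ``dF = 1 - exp(b)`` with ``b`` the OLS slope of ``ln(1 - F_t)`` on ``t``.
  ``F_t`` itself is the realized tracer-locus inbreeding — the probability
  that an animal's two alleles at an IBD tracer locus are copies of the same
  base-population allele.
* The split-point ``rg`` is the lowest genetic correlation at which a
  program keeps selecting external sires through the final generation
  (replicate-mean proportion at or above a baseline in every scenario-phase
  generation).
* Long-term contributions ``r_i`` are realized genomic contributions traced
  through the tracer loci: the fraction of a late generation's tracer
  alleles descending from ancestor ``i``; ``dF ~= (1/4) * sum r_i^2`` links
  them to inbreeding in unselected populations.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .engine import RunResult

__all__ = [
    "genetic_gain", "rate_of_inbreeding", "tracer_inbreeding",
    "external_sire_proportion", "split_point", "ancestor_contributions",
    "improvement_pct", "contribution_delta_f",
]


def _ols_slope(x: np.ndarray, y: np.ndarray) -> float:
    if len(x) < 2:
        raise ValueError("need at least two points for a regression slope")
    return float(np.polyfit(x, y, 1)[0])


def genetic_gain(mean_tbv: pd.Series, window: tuple[int, int] = (10, 20),
                 ) -> float:
    """Regression slope of mean TBV on generation over ``window`` (inclusive)."""
    t = mean_tbv.index.to_numpy()
    keep = (t >= window[0]) & (t <= window[1])
    return _ols_slope(t[keep], mean_tbv.to_numpy()[keep])


def tracer_inbreeding(labels: np.ndarray) -> float:
    """Mean identity of the two tracer alleles over animals and loci."""
    return float(np.mean(labels[:, 0, :] == labels[:, 1, :]))


def rate_of_inbreeding(f_t: pd.Series, window: tuple[int, int] = (10, 20),
                       ) -> float:
    """``dF = 1 - exp(b)`` from the ``ln(1 - F_t)`` regression over ``window``."""
    t = f_t.index.to_numpy()
    keep = (t >= window[0]) & (t <= window[1])
    f = f_t.to_numpy()[keep]
    if np.any(f >= 1.0):
        raise ValueError("F_t must stay below 1 in the regression window")
    return 1.0 - np.exp(_ols_slope(t[keep], np.log1p(-f)))


def external_sire_proportion(run: RunResult) -> pd.DataFrame:
    """Share of selected sires originating in the other environment,
    per selection event and selecting environment."""
    df = run.sires.copy()
    df["external"] = df["origin_env"] != df["env"]
    out = (df.groupby(["event", "env"])["external"].mean()
           .rename("proportion").reset_index())
    return out


def split_point(proportions_by_rg: dict[float, np.ndarray],
                threshold: float = 0.02):
    """Lowest ``rg`` sustaining long-term cooperation, over an ``rg`` grid.

    ``proportions_by_rg`` maps each grid ``rg`` to the replicate-mean
    external-sire proportion per scenario-phase generation.  Cooperation is
    long-term at an ``rg`` when the proportion stays at or above
    ``threshold`` in *every* generation.  Returns the lowest sustaining grid
    value, the open interval ``(below, lowest)`` when the indicator flips
    between adjacent grid points, or ``None`` when no grid value sustains
    cooperation.
    """
    if len(proportions_by_rg) < 2:
        raise ValueError("need a grid of at least two rg levels")
    grid = sorted(proportions_by_rg)
    sustained = [bool(np.all(np.asarray(proportions_by_rg[r]) >= threshold))
                 for r in grid]
    if not any(sustained):
        return None
    k = sustained.index(True)
    if k == 0:
        return grid[0]
    return (grid[k - 1], grid[k])


def ancestor_contributions(run: RunResult, ancestor_generation: int,
                           descendant_generation: int | None = None,
                           env: int | None = None) -> pd.Series:
    """Realized genomic contribution ``r_i`` of each ancestor of one
    generation to the tracer alleles of a later generation.

    Traces the recorded per-locus transmissions: every tracer allele in the
    descendant generation descends from exactly one chromosome set of one
    ``ancestor_generation`` animal, so the contributions sum to 1.  ``env``
    restricts the descendant group (not the ancestors).
    """
    if run.tracer_strands is None:
        raise ValueError("run was executed without contribution tracking")
    d = (descendant_generation if descendant_generation is not None
         else run.config.n_generations)
    if not 0 <= ancestor_generation < d <= run.config.n_generations:
        raise ValueError("need 0 <= ancestor generation < descendant "
                         "generation <= final generation")
    lo, hi = run.gen_slices[ancestor_generation]
    T = run.tracer_strands[0].shape[2]
    origin = np.broadcast_to(
        np.arange(lo, hi, dtype=np.int64)[:, None, None],
        (hi - lo, 2, T)).copy()
    sire_all = run.animals["sire"].to_numpy()
    dam_all = run.animals["dam"].to_numpy()
    cols = np.arange(T)
    for t in range(ancestor_generation + 1, d + 1):
        glo, ghi = run.gen_slices[t]
        plo = run.gen_slices[t - 1][0]
        strands = run.tracer_strands[t - 1]          # event t
        sire_rel = sire_all[glo:ghi] - plo
        dam_rel = dam_all[glo:ghi] - plo
        new = np.empty((ghi - glo, 2, T), dtype=np.int64)
        new[:, 0, :] = origin[sire_rel[:, None], strands[:, 0, :], cols]
        new[:, 1, :] = origin[dam_rel[:, None], strands[:, 1, :], cols]
        origin = new
    if env is not None:
        glo, ghi = run.gen_slices[d]
        mask = run.animals["env"].to_numpy()[glo:ghi] == env
        origin = origin[mask]
    counts = np.bincount(origin.ravel() - lo, minlength=hi - lo)
    r = counts / origin.size
    return pd.Series(r, index=np.arange(lo, hi), name="contribution")


def contribution_delta_f(r: pd.Series | np.ndarray, alpha: float = 0.0,
                         ) -> float:
    """Diagnostic ``dF = (1/4) (1 - alpha) sum r_i^2`` from contributions."""
    r = np.asarray(r, dtype=np.float64)
    return float(0.25 * (1.0 - alpha) * np.sum(r * r))


def improvement_pct(cooperative: float, independent: float) -> float:
    """Percentage increment of a cooperative metric over its independent
    baseline: ``100 * (coop - indep) / indep``."""
    if independent == 0:
        raise ValueError("independent baseline metric must be nonzero")
    return 100.0 * (cooperative - independent) / independent
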