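"""Generation loop for a configured breeding scenario.

Timeline (events indexed by the generation they produce):

* **generation 0** — base population sampled from the founder chromosome
  pools, appointed at random to the two environments in proportion to the
  environment population sizes; bivariate QTL effects assigned and scaled;
  unique IBD tracer alleles assigned.
* **event 1** — parents of generation 1 selected at random within
  environment (selected proportion 50% of the base).
* **events 2 .. scenario_start-1** — both programs run independently:
  within-environment PBLUP and within-environment truncation selection for
  both sexes.  Only selected sires are genotyped.
* **events scenario_start .. n_generations** — the scenario policy applies:
  evaluation is PBLUP or single-step GBLUP with within- or across-
  environment scope, and sires are selected within or across environments.
  All candidates are genotyped prior to selection.  Dams are always selected
  within environment.

Mating is even and random: selected dams are shuffled and dealt to the
selected sires in equal shares (remainder spread one per sire) and every dam
produces exactly ``offspring_per_dam`` offspring with Bernoulli(1/2) sex.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .evaluation import EvaluationSpec, evaluate
from .founders import (FounderSet, TraitArchitecture,
                       assign_ibd_tracer_alleles, assign_qtl_effects,
                       sample_base_population)
from .inheritance import breed_batch, sample_phenotypes
from .relationships import h_inverse, pedigree_a_inverse
from .rng import stream

__all__ = [
    "ScenarioConfig", "RunResult", "PoolTooSmallError", "run_scenario",
    "select_parents", "allocate_dams", "full_config", "desk_config",
    "SCENARIO_POLICIES",
]

# scenario code -> (evaluation mode, evaluation scope, sire-selection scope)
SCENARIO_POLICIES = {
    "AG-AS": ("single_step", "across", "across"),
    "WG-WS": ("single_step", "within", "within"),
    "AP-AS": ("pedigree", "across", "across"),
    "WP-WS": ("pedigree", "within", "within"),
    "AG-WS": ("single_step", "across", "within"),
}


class PoolTooSmallError(RuntimeError):
    """A selection or mating pool is smaller than the configured draw."""


@dataclass
class ScenarioConfig:
    """Everything that defines one scenario cell (not the founder genome)."""

    scenario: str
    h2: float = 0.3
    rg: float = 0.9
    n_generations: int = 20
    dams_per_env: tuple[int, int] = (1000, 1000)
    sires_phase1: tuple[int, int] = (50, 50)    # events 1 .. scenario_start-1
    sires_phase2: tuple[int, int] = (50, 50)    # scenario events
    base_males: int = 200
    base_females: int = 4000
    offspring_per_dam: int = 3
    scenario_start: int = 6
    omega: float = 0.95
    store_contributions: bool = True

    def __post_init__(self) -> None:
        if self.scenario not in SCENARIO_POLICIES:
            raise ValueError(f"unknown scenario {self.scenario!r}; "
                             f"known: {sorted(SCENARIO_POLICIES)}")

    def n_sires(self, event: int) -> tuple[int, int]:
        return (self.sires_phase1 if event < self.scenario_start
                else self.sires_phase2)


def full_config(scenario: str, h2: float = 0.3, rg: float = 0.9,
                 pop_mode: str = "equal") -> ScenarioConfig:
    """Full-scale configuration (1000:1000 or 400:1600 dams, 20 generations)."""
    if pop_mode == "equal":
        return ScenarioConfig(scenario, h2=h2, rg=rg)
    if pop_mode == "unequal":
        return ScenarioConfig(scenario, h2=h2, rg=rg,
                              dams_per_env=(400, 1600),
                              sires_phase1=(20, 80))
    raise ValueError("pop_mode must be 'equal' or 'unequal'")


def desk_config(scenario: str, h2: float = 0.3, rg: float = 0.9,
                pop_mode: str = "equal") -> ScenarioConfig:
    """Scaled-down configuration that runs in seconds per replicate.

    Desk scale preserves the structure (phase schedule, genotyping rule,
    selection proportions) but not the magnitudes of full-scale results.
    """
    kw = dict(h2=h2, rg=rg, n_generations=10, base_males=20,
              base_females=200, scenario_start=6)
    if pop_mode == "equal":
        return ScenarioConfig(scenario, dams_per_env=(50, 50),
                              sires_phase1=(5, 5), sires_phase2=(5, 5), **kw)
    if pop_mode == "unequal":
        return ScenarioConfig(scenario, dams_per_env=(20, 80),
                              sires_phase1=(2, 8), sires_phase2=(5, 5), **kw)
    raise ValueError("pop_mode must be 'equal' or 'unequal'")


@dataclass
class RunResult:
    """Complete output of one replicate of one scenario."""

    config: ScenarioConfig
    seed: int
    animals: pd.DataFrame           # one row per animal, position == id
    records: pd.DataFrame           # generation x env summaries
    sires: pd.DataFrame             # event, selecting env, sire id, origin env
    dams: pd.DataFrame              # event, env, dam id
    gen_slices: list[tuple[int, int]]          # [lo, hi) positions per gen
    tracer_strands: list[np.ndarray] | None    # per gen >= 1, (n, 2, T) uint8
    snp_dosage: np.ndarray | None   # rows follow genotyped_positions
    genotyped_positions: np.ndarray
    freqs: np.ndarray | None        # frozen centering frequencies
    architecture: TraitArchitecture

    def f_trajectory(self, env: int) -> pd.Series:
        sub = self.records[self.records["env"] == env]
        return sub.set_index("generation")["f_t"]

    def mean_tbv(self, env: int) -> pd.Series:
        sub = self.records[self.records["env"] == env]
        return sub.set_index("generation")["mean_tbv"]


def select_parents(candidates: pd.DataFrame, ebv: np.ndarray, n: int,
                   scope: str, target_env: int) -> np.ndarray:
    """Top-``n`` truncation selection on the target environment's EBV.

    ``candidates`` rows are the candidate pool (already restricted to one
    sex) indexed by animal position; ``ebv`` is the full (n_animals, 2) EBV
    table.  ``scope='within'`` keeps only candidates born in ``target_env``;
    ``scope='across'`` pools both environments.  Ties break to the smaller
    id.  Returns selected animal positions.
    """
    if scope == "within":
        pool = candidates.index.to_numpy()[
            candidates["env"].to_numpy() == target_env]
    elif scope == "across":
        pool = candidates.index.to_numpy()
    else:
        raise ValueError(f"unknown scope {scope!r}")
    if len(pool) < n:
        raise PoolTooSmallError(
            f"need {n} parents for environment {target_env} but the pool "
            f"holds {len(pool)} candidates")
    crit = ebv[pool, target_env - 1]
    order = np.lexsort((pool, -crit))     # descending EBV, then smaller id
    return pool[order[:n]]


def allocate_dams(sires: np.ndarray, dams: np.ndarray,
                  rng: np.random.Generator) -> np.ndarray:
    """Deal shuffled dams to sires in equal shares (counts differ by <= 1).

    Returns the sire assigned to each dam (aligned with ``dams``).
    """
    if len(sires) == 0 or len(dams) == 0:
        raise PoolTooSmallError("mating needs at least one sire and one dam")
    perm = rng.permutation(len(dams))
    base, rem = divmod(len(dams), len(sires))
    counts = np.full(len(sires), base)
    counts[:rem] += 1
    assignment = np.empty(len(dams), dtype=np.int64)
    assignment[perm] = np.repeat(sires, counts)
    return assignment


def _phenotype_records(animals: pd.DataFrame) -> pd.DataFrame:
    phen = animals[animals["phenotype"].notna()]
    return pd.DataFrame({
        "animal": phen.index.to_numpy(),
        "trait": phen["env"].to_numpy(),
        "generation": phen["generation"].to_numpy(),
        "phenotype": phen["phenotype"].to_numpy(),
    })


class _State:
    """Mutable bookkeeping for one run (kept out of the public surface)."""

    def __init__(self, config: ScenarioConfig, founder: FounderSet, seed: int):
        self.config = config
        self.gmap = founder.gmap
        self.seed = int(seed)
        rng_base = stream(seed, "base")
        self.rng = stream(seed, "engine")

        n_m, n_f = config.base_males, config.base_females
        geno = sample_base_population(founder.pools, n_m, n_f, rng_base)
        self.arch = assign_qtl_effects(self.gmap, geno, config.rg, config.h2,
                                       stream(seed, "effects"))
        tracer = assign_ibd_tracer_alleles(n_m + n_f, self.gmap.n_tracer)

        d1, d2 = config.dams_per_env
        m1 = int(round(n_m * d1 / (d1 + d2)))
        f1 = int(round(n_f * d1 / (d1 + d2)))
        env_m = rng_base.permutation(
            np.r_[np.ones(m1, np.int8), np.full(n_m - m1, 2, np.int8)])
        env_f = rng_base.permutation(
            np.r_[np.ones(f1, np.int8), np.full(n_f - f1, 2, np.int8)])

        tbv = self.arch.tbv(geno)
        sex = np.r_[np.zeros(n_m, np.int8), np.ones(n_f, np.int8)]  # 0=M 1=F
        env = np.r_[env_m, env_f]
        phen = np.full(n_m + n_f, np.nan)
        own = tbv[np.arange(n_m + n_f), env - 1]
        phen[sex == 1] = sample_phenotypes(own[sex == 1], self.arch.sigma2_e,
                                           self.rng)
        self.rows = [pd.DataFrame({
            "sex": sex, "env": env, "generation": 0,
            "sire": -1, "dam": -1, "genotyped": False,
            "tbv1": tbv[:, 0], "tbv2": tbv[:, 1], "phenotype": phen,
        })]
        self.gen_slices = [(0, n_m + n_f)]
        self.cur_geno = geno            # haplotypes of the newest generation
        self.cur_tracer = tracer
        self.records: list[dict] = []
        self.sire_log: list[dict] = []
        self.dam_log: list[dict] = []
        self.strands: list[np.ndarray] = []
        self.dosage_rows: list[np.ndarray] = []
        self.genotyped_positions: list[int] = []
        self.freqs: np.ndarray | None = None
        # incrementally maintained VanRaden-2 pieces: _w holds the
        # standardized centred marker rows, _g the current W W' product;
        # skipped entirely for pedigree-only scenarios
        self._need_g = SCENARIO_POLICIES[config.scenario][0] == "single_step"
        self._w: np.ndarray | None = None
        self._g: np.ndarray | None = None
        for e in (1, 2):
            self._record(0, e)

    # -- helpers ------------------------------------------------------------
    @property
    def animals(self) -> pd.DataFrame:
        return pd.concat(self.rows, ignore_index=True)

    def _record(self, generation: int, env: int) -> None:
        lo, hi = self.gen_slices[generation]
        df = self.rows[generation]
        mask = df["env"].to_numpy() == env
        tbv_own = df[["tbv1", "tbv2"]].to_numpy()[mask, env - 1]
        labels = self.cur_tracer[mask]
        self.records.append({
            "generation": generation, "env": env,
            "mean_tbv": float(tbv_own.mean()),
            "f_t": float(np.mean(labels[:, 0, :] == labels[:, 1, :])),
            "n": int(mask.sum()),
        })

    def genotype(self, positions: np.ndarray, cur_positions: np.ndarray,
                 animals: pd.DataFrame) -> None:
        """Flag ``positions`` as genotyped, storing their SNP dosages.

        ``cur_positions``/``self.cur_geno`` hold the newest generation, the
        only one whose haplotypes are still in memory; all positions passed
        here must belong to it.
        """
        new = [p for p in positions if not animals.at[p, "genotyped"]]
        if not new:
            return
        lookup = {p: i for i, p in enumerate(cur_positions)}
        rows = np.array([lookup[p] for p in new])
        snp = self.gmap.snp_index
        dos = (self.cur_geno[rows][:, 0, snp].astype(np.uint8)
               + self.cur_geno[rows][:, 1, snp])
        self.dosage_rows.append(dos)
        self.genotyped_positions.extend(new)
        gen = int(animals.loc[new, "generation"].iloc[0])
        self.rows[gen].loc[
            np.asarray(new) - self.gen_slices[gen][0], "genotyped"] = True
        if self.freqs is None:
            # centering frequencies frozen at the earliest genotyped cohort
            self.freqs = dos.mean(axis=0) / 2.0
        self._extend_g(dos)

    def _extend_g(self, dos: np.ndarray) -> None:
        """Grow the cached G by the new genotyped rows (VanRaden method 2,
        identical to :func:`gxebreed.relationships.genomic_g`)."""
        if not self._need_g:
            return
        p = self.freqs
        use = (p >= 0.01) & (p <= 0.99)
        pu = p[use]
        w_new = ((dos[:, use] - 2.0 * pu)
                 / np.sqrt(2.0 * pu * (1.0 - pu) * use.sum()))
        if self._w is None:
            self._w = w_new
            self._g = w_new @ w_new.T
        else:
            cross = self._w @ w_new.T
            self._w = np.vstack([self._w, w_new])
            self._g = np.block([[self._g, cross],
                                [cross.T, w_new @ w_new.T]])


def _evaluate(state: _State, animals: pd.DataFrame, mode: str, scope: str,
              config: ScenarioConfig):
    sire = animals["sire"].to_numpy()
    dam = animals["dam"].to_numpy()
    a_inv, _ = pedigree_a_inverse(sire, dam)
    if mode == "single_step" and state.genotyped_positions:
        gidx = np.asarray(state.genotyped_positions)
        h_inv = h_inverse(a_inv, state._g, gidx, omega=config.omega)
    else:
        h_inv = a_inv
    spec = EvaluationSpec(
        mode=mode, scope=scope, sigma2_a1=1.0, sigma2_a2=1.0,
        rg=config.rg, sigma2_e1=state.arch.sigma2_e,
        sigma2_e2=state.arch.sigma2_e)
    return evaluate(_phenotype_records(animals), spec, h_inv)


def run_scenario(config: ScenarioConfig, founder: FounderSet, seed: int,
                 ) -> RunResult:
    """Execute the full timeline for one replicate and collect results."""
    mode, eval_scope, sire_scope = SCENARIO_POLICIES[config.scenario]
    state = _State(config, founder, seed)
    rng = state.rng

    for event in range(1, config.n_generations + 1):
        animals = state.animals
        lo, hi = state.gen_slices[event - 1]
        cand_positions = np.arange(lo, hi)
        cand = animals.iloc[lo:hi]
        scenario_phase = event >= config.scenario_start

        if scenario_phase:
            state.genotype(cand_positions, cand_positions, animals)
            animals = state.animals          # refresh genotyped flags

        # -- evaluation and selection ---------------------------------------
        n_sires = config.n_sires(event)
        males = cand[cand["sex"] == 0]
        females = cand[cand["sex"] == 1]
        if event == 1:
            sel_sires, sel_dams = {}, {}
            for e in (1, 2):
                pool_m = males.index.to_numpy()[males["env"].to_numpy() == e]
                pool_f = females.index.to_numpy()[females["env"].to_numpy() == e]
                if len(pool_m) < n_sires[e - 1] or \
                        len(pool_f) < config.dams_per_env[e - 1]:
                    raise PoolTooSmallError("base population too small for "
                                            "the configured selections")
                sel_sires[e] = np.sort(rng.choice(pool_m, n_sires[e - 1],
                                                  replace=False))
                sel_dams[e] = np.sort(rng.choice(pool_f,
                                                 config.dams_per_env[e - 1],
                                                 replace=False))
        else:
            if scenario_phase:
                ev_mode, ev_scope, s_scope = mode, eval_scope, sire_scope
            else:
                ev_mode, ev_scope, s_scope = "pedigree", "within", "within"
            result = _evaluate(state, animals, ev_mode, ev_scope, config)
            sel_sires, sel_dams = {}, {}
            for e in (1, 2):
                sel_sires[e] = select_parents(males, result.ebv,
                                              n_sires[e - 1], s_scope, e)
                sel_dams[e] = select_parents(females, result.ebv,
                                             config.dams_per_env[e - 1],
                                             "within", e)

        if not scenario_phase:
            # only selected sires are genotyped before the scenario phase
            sires_both = np.unique(np.concatenate([sel_sires[1],
                                                   sel_sires[2]]))
            state.genotype(sires_both, cand_positions, animals)

        env_of = animals["env"].to_numpy()
        for e in (1, 2):
            for s in sel_sires[e]:
                state.sire_log.append({"event": event, "env": e,
                                       "id": int(s),
                                       "origin_env": int(env_of[s])})
            for d in sel_dams[e]:
                state.dam_log.append({"event": event, "env": e,
                                      "id": int(d)})

        # -- mating and reproduction ----------------------------------------
        off_sire, off_dam, off_env = [], [], []
        for e in (1, 2):
            dam_sires = allocate_dams(sel_sires[e], sel_dams[e], rng)
            rep = config.offspring_per_dam
            off_sire.append(np.repeat(dam_sires, rep))
            off_dam.append(np.repeat(sel_dams[e], rep))
            off_env.append(np.full(len(sel_dams[e]) * rep, e, np.int8))
        off_sire = np.concatenate(off_sire)
        off_dam = np.concatenate(off_dam)
        off_env = np.concatenate(off_env)
        n_off = len(off_sire)

        geno, tracer, strands = breed_batch(
            state.cur_geno, state.cur_tracer, off_sire - lo, off_dam - lo,
            state.gmap, rng)
        tbv = state.arch.tbv(geno)
        sex = rng.integers(0, 2, n_off).astype(np.int8)   # 0=M, 1=F
        phen = np.full(n_off, np.nan)
        own = tbv[np.arange(n_off), off_env - 1]
        fem = sex == 1
        phen[fem] = sample_phenotypes(own[fem], state.arch.sigma2_e, rng)

        start = state.gen_slices[-1][1]
        state.rows.append(pd.DataFrame({
            "sex": sex, "env": off_env, "generation": event,
            "sire": off_sire, "dam": off_dam, "genotyped": False,
            "tbv1": tbv[:, 0], "tbv2": tbv[:, 1], "phenotype": phen,
        }))
        state.gen_slices.append((start, start + n_off))
        state.cur_geno, state.cur_tracer = geno, tracer
        if config.store_contributions:
            state.strands.append(strands)
        for e in (1, 2):
            state._record(event, e)

    animals = state.animals
    return RunResult(
        config=config, seed=state.seed, animals=animals,
        records=pd.DataFrame(state.records),
        sires=pd.DataFrame(state.sire_log),
        dams=pd.DataFrame(state.dam_log),
        gen_slices=state.gen_slices,
        tracer_strands=state.strands if config.store_contributions else None,
        snp_dosage=(np.vstack(state.dosage_rows)
                    if state.dosage_rows else None),
        genotyped_positions=np.asarray(state.genotyped_positions,
                                       dtype=np.int64),
        freqs=state.freqs,
        architecture=state.arch,
    )
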