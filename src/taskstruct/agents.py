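"""Synthetic learner agents generating learning- and memory-phase records.

Two agent strategies mirror the behavioral hypotheses the analysis is built
to discriminate:

* ``flat`` agents memorize all four category-key associations directly; a
  change in the supraordinate feature is just another stimulus change, so
  their expected reaction-time (RT) difference between supraordinate-switch
  and supraordinate-repeat trials is zero by construction.
* ``hierarchical`` agents organize responses as a task-set nested under one
  supraordinate dimension and pay an additive RT penalty (``switch_cost_ms``)
  whenever that dimension's level changes between trials.

Accuracy follows a saturating trial-and-error learning curve from 4-choice
chance (0.25) toward an asymptote; RTs are lognormal (right-skewed, positive
support) with the switch penalty added on the natural scale; responses time
out at the 1250 ms response window and, additionally, at a small base rate
emulating lapses of responding.  Recognition memory is a Gaussian
equal-variance signal-detection process whose old-item strength depends on
the learning-phase quartile of encoding, declining across quartiles
(primacy).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .designs import (
    ConfigurationError,
    ExperimentDesign,
    enumerate_versions,
    generate_learning_trials,
    generate_memory_trials,
    transfer_classification,
)
from .preprocess import assign_bins

__all__ = [
    "AgentConfig",
    "Cohort",
    "flat_agent",
    "hierarchical_agent",
    "simulate_learning_phase",
    "simulate_memory_phase",
    "simulate_participant",
    "simulate_cohort",
    "RESPONSE_WINDOW_MS",
    "RATING_LEVELS",
]

#: Learning-phase response window; sampled RTs beyond it become timeouts.
RESPONSE_WINDOW_MS = 1250.0

#: 4-level recognition ratings, ordered from weakest to strongest evidence.
RATING_LEVELS = ("DefNew", "ProbNew", "ProbOld", "DefOld")

_DEFAULT_STRENGTHS = (1.0, 0.8, 0.65, 0.55)
_DEFAULT_CRITERIA = (-0.5, 0.5, 1.5)


@dataclass(frozen=True)
class AgentConfig:
    """Generative parameters of one simulated participant."""

    strategy: str = "flat"  # "flat" | "hierarchical"
    supra_dim: Optional[str] = None  # hierarchical only
    switch_cost_ms: float = 0.0
    post_switch_cost_ms: Optional[float] = None  # after an implicit rule switch
    base_rt_ms: float = 650.0
    rt_sd_log: float = 0.2
    learn_tau: float = 6.0
    p_asym: float = 0.92
    lapse_rate: float = 0.02
    timeout_rate: float = 0.03
    encoding_strength_by_bin: tuple[float, float, float, float] = _DEFAULT_STRENGTHS
    memory_criteria: tuple[float, float, float] = _DEFAULT_CRITERIA
    source_accuracy: float = 0.5
    memory_rt_ms: float = 800.0
    memory_timeout_rate: float = 0.03

    def __post_init__(self) -> None:
        if self.strategy not in ("flat", "hierarchical"):
            raise ConfigurationError(f"unknown strategy {self.strategy!r}")
        if self.strategy == "flat" and self.switch_cost_ms != 0.0:
            raise ConfigurationError("flat agents must have switch_cost_ms = 0")
        if self.strategy == "hierarchical" and self.supra_dim is None:
            raise ConfigurationError("hierarchical agents need a supra_dim")
        if self.switch_cost_ms < 0:
            raise ConfigurationError("switch_cost_ms must be nonnegative")
        if self.post_switch_cost_ms is not None and self.post_switch_cost_ms < 0:
            raise ConfigurationError("post_switch_cost_ms must be nonnegative")
        if not (0.25 < self.p_asym <= 1.0):
            raise ConfigurationError("p_asym must lie in (0.25, 1]")
        if not (0 <= self.lapse_rate < 1 and 0 <= self.timeout_rate < 1):
            raise ConfigurationError("rates must lie in [0, 1)")
        if not np.all(np.isfinite(self.encoding_strength_by_bin)):
            raise ConfigurationError("encoding strengths must be finite")
        if not np.all(np.diff(self.memory_criteria) > 0):
            raise ConfigurationError("memory criteria must be strictly ascending")


def flat_agent(**overrides) -> AgentConfig:
    """A flat-mapping agent (zero structural switch cost)."""
    return AgentConfig(strategy="flat", switch_cost_ms=0.0, **overrides)


def hierarchical_agent(
    supra_dim: str, switch_cost_ms: float = 80.0, **overrides
) -> AgentConfig:
    """A hierarchical task-set agent paying ``switch_cost_ms`` on supra switches."""
    return AgentConfig(
        strategy="hierarchical",
        supra_dim=supra_dim,
        switch_cost_ms=switch_cost_ms,
        **overrides,
    )


def _p_correct(t_eff: np.ndarray, agent: AgentConfig) -> np.ndarray:
    """Exponential learning curve from 4-choice chance toward ``p_asym``."""
    if agent.learn_tau <= 0:
        return np.full(t_eff.shape, agent.p_asym)
    return agent.p_asym - (agent.p_asym - 0.25) * np.exp(-t_eff / agent.learn_tau)


def simulate_learning_phase(
    agent: AgentConfig,
    design: ExperimentDesign,
    seed: int | np.random.Generator,
    trials: Optional[pd.DataFrame] = None,
) -> pd.DataFrame:
    """Simulate one agent's learning phase on a design's trial list.

    Returns one row per trial with ``response_key`` (NaN on timeouts),
    ``correct``, ``rt_ms`` and ``timeout``.  For Experiment-3 designs the
    learning curve of negative-transfer categories (whose key changed at the
    rule switch) restarts at the switch; positive-transfer categories
    continue on their original curve.
    """
    if agent.strategy == "hierarchical":
        if agent.supra_dim not in (design.dims[0].name, design.dims[1].name):
            raise ConfigurationError(
                f"agent supra_dim {agent.supra_dim!r} not among design dimensions"
            )
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if trials is None:
        trials = generate_learning_trials(design, rng)
    n = len(trials)
    d1, d2 = design.dims[0].name, design.dims[1].name
    t = trials["trial"].to_numpy()

    # Effective learning-curve position: restart for negative-transfer
    # categories after the Experiment-3 rule switch.
    t_eff = t.astype(float)
    if design.rule_switch_at is not None and design.post_switch_mapping is not None:
        negative = transfer_classification(
            design.mapping, design.post_switch_mapping
        )["negative"]
        neg_labels = {(c.level1, c.level2) for c in negative}
        is_neg = np.array(
            [(a, b) in neg_labels for a, b in zip(trials[d1], trials[d2])]
        )
        post = t > design.rule_switch_at
        t_eff[post & is_neg] = t[post & is_neg] - design.rule_switch_at

    pc = _p_correct(t_eff, agent)
    p_resp_correct = (1 - agent.lapse_rate) * pc + agent.lapse_rate * 0.25
    correct = rng.random(n) < p_resp_correct

    correct_key = trials["correct_key"].to_numpy()
    response = correct_key.astype(float)
    wrong_draw = rng.integers(0, 3, size=n)
    # Map a draw in {0,1,2} onto the three non-correct keys.
    for i in np.nonzero(~correct)[0]:
        options = [k for k in (1, 2, 3, 4) if k != correct_key[i]]
        response[i] = options[wrong_draw[i]]

    rt = np.exp(rng.normal(np.log(agent.base_rt_ms), agent.rt_sd_log, size=n))
    if agent.strategy == "hierarchical":
        si = 0 if agent.supra_dim == d1 else 1
        supra_levels = trials[design.dims[si].name].to_numpy()
        supra_changed = np.empty(n, dtype=bool)
        supra_changed[0] = False
        supra_changed[1:] = supra_levels[1:] != supra_levels[:-1]
        delta = np.full(n, agent.switch_cost_ms)
        if design.rule_switch_at is not None and agent.post_switch_cost_ms is not None:
            delta[t > design.rule_switch_at] = agent.post_switch_cost_ms
        rt = rt + delta * supra_changed

    timeout = (rng.random(n) < agent.timeout_rate) | (rt > RESPONSE_WINDOW_MS)
    rt = np.where(timeout, np.nan, rt)
    response = np.where(timeout, np.nan, response)
    correct = np.where(timeout, False, correct)

    out = trials.copy()
    out["response_key"] = response
    out["correct"] = correct.astype(bool)
    out["rt_ms"] = rt
    out["timeout"] = timeout
    return out


def simulate_memory_phase(
    agent: AgentConfig,
    memory_trials: pd.DataFrame,
    design: ExperimentDesign,
    seed: int | np.random.Generator,
) -> pd.DataFrame:
    """Simulate the surprise recognition test as Gaussian signal detection.

    Old-item memory strength is Normal(strength[bin], 1) where ``bin`` is the
    learning-phase quartile of encoding; new items are Normal(0, 1).  The
    4-level rating is read off the three ascending criteria.  Responses are
    omitted at the agent's memory timeout rate.  For source-memory designs
    (Experiment 1) each source question is answered correctly with
    ``source_accuracy`` (default 0.5 = chance).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    mem = memory_trials.copy()
    n = len(mem)
    bins = assign_bins(design.n_learning_trials)
    lp_bin = np.full(n, np.nan)
    old = mem["status"].to_numpy() == "old"
    lp_trial = mem["lp_trial"].to_numpy(dtype=float)
    lp_bin[old] = bins.bin_of(lp_trial[old].astype(int))

    strength = rng.normal(0.0, 1.0, size=n)
    strengths = np.asarray(agent.encoding_strength_by_bin, dtype=float)
    strength[old] += strengths[lp_bin[old].astype(int) - 1]

    crits = np.asarray(agent.memory_criteria, dtype=float)
    rating_idx = np.searchsorted(crits, strength)  # 0..3, DefNew..DefOld
    rating = np.array(RATING_LEVELS, dtype=object)[rating_idx]

    no_resp = rng.random(n) < agent.memory_timeout_rate
    rt = np.exp(rng.normal(np.log(agent.memory_rt_ms), 0.3, size=n))
    rating = np.where(no_resp, None, rating)
    rt = np.where(no_resp, np.nan, rt)

    mem["lp_bin"] = lp_bin
    mem["rating"] = rating
    mem["rt_ms"] = rt

    if design.source_memory:
        d1, d2 = design.dims[0].name, design.dims[1].name
        for dim_name, col in ((d1, "source_dim1_resp"), (d2, "source_dim2_resp")):
            levels = dict(zip((d.name for d in design.dims),
                              (d.levels for d in design.dims)))[dim_name]
            truth = mem[dim_name].to_numpy()
            correct_resp = rng.random(n) < agent.source_accuracy
            other = np.where(truth == levels[0], levels[1], levels[0])
            resp = np.where(correct_resp, truth, other)
            mem[col] = np.where(no_resp, None, resp)
    return mem


def simulate_participant(
    agent: AgentConfig,
    design: ExperimentDesign,
    seed: int | np.random.SeedSequence,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """One participant's full session: learning then surprise memory phase."""
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    rng = np.random.default_rng(ss)
    learning = simulate_learning_phase(agent, design, rng)
    mem_trials = generate_memory_trials(learning, design, rng)
    memory = simulate_memory_phase(agent, mem_trials, design, rng)
    return learning, memory


@dataclass
class Cohort:
    """Long-format cohort dataset: learning and memory records plus manifest."""

    experiment_id: int
    learning: pd.DataFrame
    memory: pd.DataFrame
    participants: pd.DataFrame  # participant, group, version, agent parameters

    def design_for(self, version_id: int) -> ExperimentDesign:
        return enumerate_versions(self.experiment_id)[version_id - 1]


GroupPopulation = Sequence[tuple[AgentConfig, float]]


def default_populations(
    dims: tuple[str, str],
    delta_ms: float = 80.0,
    hier_fraction_clustered: float = 0.4,
    hier_fraction_nonclustered: float = 0.05,
    **agent_overrides,
) -> dict[str, GroupPopulation]:
    """Mixture populations emulating the observed prevalence of structure
    formers: common among motor-clustered learners, rare otherwise.

    Hierarchical agents split evenly between the two candidate supraordinate
    dimensions.
    """
    pops: dict[str, GroupPopulation] = {}
    for group, f in (
        ("clustered", hier_fraction_clustered),
        ("non_clustered", hier_fraction_nonclustered),
    ):
        pops[group] = [
            (flat_agent(**agent_overrides), 1 - f),
            (hierarchical_agent(dims[0], delta_ms, **agent_overrides), f / 2),
            (hierarchical_agent(dims[1], delta_ms, **agent_overrides), f / 2),
        ]
    return pops


def simulate_cohort(
    n_per_group: int,
    populations: dict[str, GroupPopulation],
    experiment_id: int,
    seed: int,
) -> Cohort:
    """Simulate a two-group cohort, versions assigned round-robin per group.

    ``populations`` maps group label ("clustered"/"non_clustered") to a
    sequence of (AgentConfig, weight) pairs; each participant's agent is
    drawn from that mixture.  Per-participant random streams are spawned
    deterministically from the master seed.
    """
    if n_per_group < 1:
        raise ConfigurationError("n_per_group must be >= 1")
    for group, pop in populations.items():
        if not pop:
            raise ConfigurationError(f"empty agent population for group {group!r}")
    versions = enumerate_versions(experiment_id)
    by_group = {
        "clustered": [d for d in versions if d.mapping.clustered],
        "non_clustered": [d for d in versions if not d.mapping.clustered],
    }
    master = np.random.SeedSequence(seed)
    pick_rng = np.random.default_rng(master.spawn(1)[0])

    learning_frames, memory_frames, manifest = [], [], []
    pid = 0
    for group in ("clustered", "non_clustered"):
        pop = populations[group]
        configs = [c for c, _ in pop]
        weights = np.array([w for _, w in pop], dtype=float)
        weights = weights / weights.sum()
        group_versions = by_group[group]
        for i in range(n_per_group):
            pid += 1
            design = group_versions[i % len(group_versions)]
            agent = configs[pick_rng.choice(len(configs), p=weights)]
            learning, memory = simulate_participant(
                agent, design, np.random.SeedSequence([seed, pid])
            )
            for frame, store in ((learning, learning_frames), (memory, memory_frames)):
                frame = frame.copy()
                frame.insert(0, "participant", pid)
                frame.insert(1, "group", group)
                frame.insert(2, "version", design.version_id)
                store.append(frame)
            manifest.append(
                {
                    "participant": pid,
                    "group": group,
                    "version": design.version_id,
                    "strategy": agent.strategy,
                    "supra_dim": agent.supra_dim,
                    "switch_cost_ms": agent.switch_cost_ms,
                }
            )
    return Cohort(
        experiment_id=experiment_id,
        learning=pd.concat(learning_frames, ignore_index=True),
        memory=pd.concat(memory_frames, ignore_index=True),
        participants=pd.DataFrame(manifest),
    )
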