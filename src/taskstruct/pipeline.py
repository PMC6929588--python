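"""End-to-end orchestration: simulate -> preprocess -> infer -> memory report.

A run is specified by a :class:`RunConfig` (serializable to YAML, with the
master seed and every analysis toggle recorded in the output manifest) and
produces a directory of plain-text artifacts: the cohort data, the
exclusions report, per-participant switch-cost and permutation results, the
group-level permutation summaries, and the memory analyses.  Identical
configurations reproduce bit-identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Optional

import pandas as pd
import yaml

from . import agents, memory, switchcost
from .designs import ConfigurationError, enumerate_versions
from .preprocess import participant_gate

__all__ = ["RunConfig", "run_full", "load_cohort", "report"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class RunConfig:
    """Complete, serializable specification of one pipeline run."""

    experiment_id: int = 2
    n_per_group: int = 30
    n_perm: int = 10_000
    master_seed: int = 0
    delta_ms: float = 80.0
    hier_fraction_clustered: float = 0.4
    hier_fraction_nonclustered: float = 0.05
    clustered_bin1_deficit: float = 0.25
    with_covariates: bool = True
    out_dir: str = "taskstruct_run"

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text())
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys {sorted(unknown)}")
        return cls(**data)


def _populations(config: RunConfig) -> dict:
    dims = ("color", "shape") if config.experiment_id == 1 else ("age", "gender")
    pops = agents.default_populations(
        dims,
        delta_ms=config.delta_ms,
        hier_fraction_clustered=config.hier_fraction_clustered,
        hier_fraction_nonclustered=config.hier_fraction_nonclustered,
    )
    if config.clustered_bin1_deficit:
        weakened = []
        for cfg, w in pops["clustered"]:
            s = list(cfg.encoding_strength_by_bin)
            s[0] -= config.clustered_bin1_deficit
            weakened.append((replace(cfg, encoding_strength_by_bin=tuple(s)), w))
        pops["clustered"] = weakened
    return pops


def _exclusions(cohort: agents.Cohort) -> pd.DataFrame:
    rows = []
    for pid, ptrials in cohort.learning.groupby("participant"):
        responded = ptrials[~ptrials["timeout"]]
        accuracy = float(responded["correct"].mean()) if len(responded) else 0.0
        include, reason = participant_gate(accuracy)
        rows.append(
            {
                "participant": pid,
                "group": ptrials["group"].iloc[0],
                "learning_accuracy": accuracy,
                "include": include,
                "reason": reason,
            }
        )
    return pd.DataFrame(rows)


def run_full(config: RunConfig, force: bool = False) -> dict:
    """Execute the whole pipeline and write all artifacts to ``out_dir``.

    Refuses to write into a directory with prior outputs unless ``force``.
    Returns the in-memory results bundle.
    """
    out = Path(config.out_dir)
    if out.exists() and any(out.iterdir()) and not force:
        raise ConfigurationError(
            f"output directory {out} is not empty; pass force=True to overwrite"
        )
    out.mkdir(parents=True, exist_ok=True)

    cohort = agents.simulate_cohort(
        config.n_per_group,
        _populations(config),
        config.experiment_id,
        seed=config.master_seed,
    )
    cohort.learning.to_csv(out / "learning.csv", index=False)
    cohort.memory.to_csv(out / "memory.csv", index=False)
    cohort.participants.to_csv(out / "participants.csv", index=False)

    exclusions = _exclusions(cohort)
    exclusions.to_csv(out / "exclusions.csv", index=False)
    included = set(exclusions.loc[exclusions["include"], "participant"])
    kept = agents.Cohort(
        experiment_id=cohort.experiment_id,
        learning=cohort.learning[cohort.learning["participant"].isin(included)],
        memory=cohort.memory[cohort.memory["participant"].isin(included)],
        participants=cohort.participants[
            cohort.participants["participant"].isin(included)
        ],
    )

    individual, group_results = switchcost.analyze_cohort(
        kept, n_perm=config.n_perm, seed=config.master_seed
    )
    individual.to_csv(out / "switch_costs.csv", index=False)
    group_summary = pd.DataFrame(
        [
            {
                "group": g,
                "measure": m,
                "observed_mean_abs_z": res.observed,
                "percentile": res.percentile,
                "significant": res.significant,
                "n_perm": res.n_perm,
            }
            for (g, m), res in sorted(group_results.items())
        ]
    )
    group_summary.to_csv(out / "group_permutation.csv", index=False)

    recognition = memory.cohort_recognition(kept)
    recognition.to_csv(out / "recognition.csv", index=False)

    memory_results: dict = {"chance_tests": {}}
    for g in ("clustered", "non_clustered"):
        sub = recognition[recognition["group"] == g]
        if len(sub) >= 2:
            rep = memory.chance_memory_test(
                sub["hit_rate"].to_numpy(), sub["fa_rate"].to_numpy()
            )
            memory_results["chance_tests"][g] = dataclasses.asdict(rep)
    cov = None
    if config.with_covariates:
        cov = (
            individual.set_index("participant")
            .loc[
                recognition.set_index("participant").index,
                ["rt_signed_cost", "accuracy_signed_cost"],
            ]
            .reset_index(drop=True)
        )
        recognition = recognition.reset_index(drop=True)
    try:
        anova = memory.binned_anova(recognition, covariates=cov)
        memory_results["binned_anova"] = anova.to_dict(orient="records")
    except ValueError as err:
        logger.warning("binned ANOVA skipped: %s", err)
    if config.experiment_id == 1:
        source = memory.source_memory_analysis(kept)
        memory_results["source_anova"] = source["anova"].to_dict(orient="records")
        memory_results["source_chance"] = {
            f"{g}_{r}": dataclasses.asdict(rep)
            for (g, r), rep in source["chance"].items()
        }
    if config.experiment_id == 3:
        transfer = memory.transfer_analysis(kept)
        memory_results["transfer_anova"] = transfer.to_dict(orient="records")
    (out / "memory_results.json").write_text(
        json.dumps(memory_results, indent=2, sort_keys=True, default=float)
    )

    manifest = {
        "config": dataclasses.asdict(config),
        "n_versions": len(enumerate_versions(config.experiment_id)),
        "n_participants": int(cohort.participants.shape[0]),
        "n_included": len(included),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    config.to_yaml(out / "config.yaml")
    return {
        "cohort": kept,
        "exclusions": exclusions,
        "individual": individual,
        "group": group_results,
        "recognition": recognition,
        "memory": memory_results,
    }


def load_cohort(run_dir: str | Path, experiment_id: Optional[int] = None) -> agents.Cohort:
    """Reload a cohort written by :func:`run_full` (or the simulate command)."""
    run_dir = Path(run_dir)
    if experiment_id is None:
        manifest = json.loads((run_dir / "manifest.json").read_text())
        experiment_id = manifest["config"]["experiment_id"]
    return agents.Cohort(
        experiment_id=experiment_id,
        learning=pd.read_csv(run_dir / "learning.csv"),
        memory=pd.read_csv(run_dir / "memory.csv"),
        participants=pd.read_csv(run_dir / "participants.csv"),
    )


def report(run_dir: str | Path) -> str:
    """Human-readable summary of a completed run."""
    run_dir = Path(run_dir)
    lines = []
    for name in ("manifest.json", "group_permutation.csv", "switch_costs.csv",
                 "recognition.csv"):
        if not (run_dir / name).exists():
            return f"run incomplete: missing stage output {name!r} in {run_dir}"
    manifest = json.loads((run_dir / "manifest.json").read_text())
    lines.append(f"Experiment {manifest['config']['experiment_id']} | "
                 f"{manifest['n_included']}/{manifest['n_participants']} "
                 "participants included")
    group = pd.read_csv(run_dir / "group_permutation.csv")
    lines.append("\nGroup-level permutation results (mean |z| switch cost):")
    if group.empty:
        lines.append("  (no groups analyzable)")
    for _, r in group.iterrows():
        flag = "*" if r["significant"] else " "
        lines.append(
            f"  {r['group']:>14} {r['measure']:>9}: percentile "
            f"{100 * r['percentile']:6.2f}%{flag}"
        )
    indiv = pd.read_csv(run_dir / "switch_costs.csv")
    if not indiv.empty:
        if "structure_former" in indiv:
            formers = indiv.groupby("group")["structure_former"].sum()
            lines.append("\nFlagged structure formers (RT or accuracy):")
            for g, k in formers.items():
                n = (indiv["group"] == g).sum()
                lines.append(f"  {g:>14}: {int(k)}/{n}")
        counts = indiv.groupby(["group", "inferred_dim"]).size()
        lines.append("\nInferred supraordinate dimension:")
        for (g, d), k in counts.items():
            lines.append(f"  {g:>14} {d}: {k}")
    recog = pd.read_csv(run_dir / "recognition.csv")
    if not recog.empty:
        lines.append("\nRecognition memory (mean per group):")
        bin_cols = [c for c in recog.columns if c.startswith("hit_bin")]
        for g, sub in recog.groupby("group"):
            bins = " ".join(f"{sub[c].mean():.2f}" for c in bin_cols)
            lines.append(
                f"  {g:>14}: hit {sub['hit_rate'].mean():.2f} "
                f"fa {sub['fa_rate'].mean():.2f} | hit by bin: {bins}"
            )
    return "\n".join(lines)
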