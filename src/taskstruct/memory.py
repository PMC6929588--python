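"""Recognition- and source-memory analyses.

The surprise memory phase yields 4-level old/new confidence ratings that are
collapsed to binary old/new responses; hit rate is the proportion of old
items called old, false-alarm (FA) rate the proportion of new items called
old.  Above-chance encoding is a paired t-test of hit against FA rate within
each learner group.  Time-dependent encoding is probed by binning old items
by their learning-phase position and running a split-plot (mixed) ANOVA with
bin as the within-participant factor, learner group (and, when pooling
experiments, experiment) as between-participant factors, and optionally the
participants' RT and accuracy switch costs as centered continuous
covariates.  Greenhouse-Geisser correction is applied to within effects
whenever the within factor has more than two levels; epsilon is always
reported.

The ANOVA engine here is a self-contained least-squares split-plot
implementation (type-III style sums of squares via model comparison with
sum-coded factors) because the covariate variant — including
covariate-by-bin interactions, with within-stratum error degrees of freedom
(b - 1)(N - g - c) — is not offered by the usual repeated-measures helpers.

Effect-size conventions: paired designs report Cohen's d_z = t / sqrt(n)
with common-language (CL) effect size Phi(d_z); independent designs report
d_s from the pooled SD with CL = Phi(d_s / sqrt(2)); ANOVA effects report
partial eta squared.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats as sps

from .designs import Category, ExperimentDesign, transfer_classification
from .preprocess import BinAssignment, bin_occupancy_ok, filter_memory_trials

__all__ = [
    "UndefinedRates",
    "EffectSizeReport",
    "RecognitionSummary",
    "collapse_ratings",
    "recognition_summary",
    "baseline_category",
    "cohort_recognition",
    "chance_memory_test",
    "paired_t_report",
    "one_sample_t_report",
    "independent_t_report",
    "mixed_rm_anova",
    "binned_anova",
    "early_bins_comparison",
    "two_within_anova",
    "source_memory_analysis",
    "transfer_analysis",
    "greenhouse_geisser_epsilon",
]

logger = logging.getLogger(__name__)


class UndefinedRates(ValueError):
    """Hit/FA rates undefined (no responded old or new trials)."""


@dataclass(frozen=True)
class EffectSizeReport:
    """A t-test with its standardized effect sizes."""

    name: str
    t: float
    df: float
    p: float
    cohen_d: float
    cl_effect: float
    n: int


@dataclass(frozen=True)
class RecognitionSummary:
    """One participant's recognition-memory summary."""

    hit_rate: float
    fa_rate: float
    hits_by_bin: tuple[float, ...]
    n_by_bin: tuple[int, ...]
    baseline_category_hit: float


_OLD_RATINGS = frozenset({"DefOld", "ProbOld"})
_NEW_RATINGS = frozenset({"DefNew", "ProbNew"})


def collapse_ratings(records: pd.DataFrame) -> pd.DataFrame:
    """Collapse 4-level confidence ratings to binary old/new responses."""
    rating = records["rating"]
    unknown = set(rating.dropna()) - _OLD_RATINGS - _NEW_RATINGS
    if unknown:
        raise ValueError(f"unknown rating levels {sorted(unknown)}")
    out = records.copy()
    out["response"] = np.where(rating.isin(_OLD_RATINGS), "old", "new")
    out.loc[rating.isna(), "response"] = None
    return out


def baseline_category(design: ExperimentDesign) -> Category:
    """The category whose key assignment is shared across learner groups.

    Under the canonical clustered and non-clustered patterns the category at
    the first level of both dimensions sits on key 1 in every counterbalanced
    version, making it the group-invariant baseline probe of memory capacity
    or motivation.
    """
    return Category(design.dims[0].levels[0], design.dims[1].levels[0])


def recognition_summary(
    records: pd.DataFrame,
    bins: BinAssignment,
    baseline: Category,
    dim_names: tuple[str, str],
) -> RecognitionSummary:
    """Hit/FA rates, per-bin hit rates and the baseline-category hit rate.

    Expects one participant's memory-filtered records with collapsed
    responses and an ``lp_bin`` column.
    """
    old = records[records["status"] == "old"]
    new = records[records["status"] == "new"]
    if old.empty or new.empty:
        raise UndefinedRates("no responded old or new trials")
    hit_rate = float((old["response"] == "old").mean())
    fa_rate = float((new["response"] == "old").mean())
    hits, counts = [], []
    for b in range(1, len(bins.bin_sizes) + 1):
        in_bin = old[old["lp_bin"] == float(b)]
        counts.append(len(in_bin))
        hits.append(float((in_bin["response"] == "old").mean()) if len(in_bin) else np.nan)
    base = old[
        (old[dim_names[0]] == baseline.level1) & (old[dim_names[1]] == baseline.level2)
    ]
    base_hit = float((base["response"] == "old").mean()) if len(base) else np.nan
    return RecognitionSummary(
        hit_rate=hit_rate,
        fa_rate=fa_rate,
        hits_by_bin=tuple(hits),
        n_by_bin=tuple(counts),
        baseline_category_hit=base_hit,
    )


def cohort_recognition(cohort) -> pd.DataFrame:
    """Per-participant recognition summaries for a simulated cohort.

    Applies the memory trial filter and rating collapse, then computes each
    participant's summary plus the >= 10-responded-trials-per-bin gate for
    the binned ANOVA.  Participants with undefined rates are dropped with a
    log entry.
    """
    from .preprocess import assign_bins

    rows = []
    for pid, precs in cohort.memory.groupby("participant"):
        design = cohort.design_for(int(precs["version"].iloc[0]))
        dims = (design.dims[0].name, design.dims[1].name)
        bins = assign_bins(design.n_learning_trials)
        kept = collapse_ratings(filter_memory_trials(precs))
        try:
            summary = recognition_summary(kept, bins, baseline_category(design), dims)
        except UndefinedRates as err:
            logger.info("participant %s dropped from memory analysis: %s", pid, err)
            continue
        row = {
            "participant": pid,
            "group": precs["group"].iloc[0],
            "hit_rate": summary.hit_rate,
            "fa_rate": summary.fa_rate,
            "baseline_hit": summary.baseline_category_hit,
            "bin_gate_ok": bin_occupancy_ok(kept, n_bins=len(bins.bin_sizes)),
        }
        for b, (h, c) in enumerate(zip(summary.hits_by_bin, summary.n_by_bin), 1):
            row[f"hit_bin{b}"] = h
            row[f"n_bin{b}"] = c
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# t-tests and effect sizes
# ---------------------------------------------------------------------------

def _cl_from_d(d: float) -> float:
    return float(sps.norm.cdf(d))


def paired_t_report(x: np.ndarray, y: np.ndarray, name: str = "paired") -> EffectSizeReport:
    """Paired t-test with d_z = t/sqrt(n) and CL = Phi(d_z)."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    diffs = x - y
    n = len(diffs)
    if np.allclose(diffs.std(ddof=1), 0.0):
        raise ValueError("zero-variance differences: t undefined")
    t, p = sps.ttest_rel(x, y)
    d_z = float(t) / np.sqrt(n)
    return EffectSizeReport(name, float(t), n - 1, float(p), d_z, _cl_from_d(d_z), n)


def one_sample_t_report(x: np.ndarray, popmean: float, name: str = "one-sample") -> EffectSizeReport:
    x = np.asarray(x, float)
    n = len(x)
    if np.allclose(x.std(ddof=1), 0.0):
        raise ValueError("zero-variance sample: t undefined")
    t, p = sps.ttest_1samp(x, popmean)
    d_z = float(t) / np.sqrt(n)
    return EffectSizeReport(name, float(t), n - 1, float(p), d_z, _cl_from_d(d_z), n)


def independent_t_report(x: np.ndarray, y: np.ndarray, name: str = "independent") -> EffectSizeReport:
    """Independent-samples t-test with pooled-SD d_s and CL = Phi(d_s/sqrt(2))."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n1, n2 = len(x), len(y)
    t, p = sps.ttest_ind(x, y)
    sp = np.sqrt(
        ((n1 - 1) * x.var(ddof=1) + (n2 - 1) * y.var(ddof=1)) / (n1 + n2 - 2)
    )
    d_s = float((x.mean() - y.mean()) / sp) if sp > 0 else 0.0
    return EffectSizeReport(
        name, float(t), n1 + n2 - 2, float(p), d_s, _cl_from_d(d_s / np.sqrt(2)), n1 + n2
    )


def chance_memory_test(hit_rates: np.ndarray, fa_rates: np.ndarray) -> EffectSizeReport:
    """Above-chance encoding: paired t of per-participant hit vs FA rates."""
    return paired_t_report(hit_rates, fa_rates, name="hit_vs_fa")


# ---------------------------------------------------------------------------
# split-plot ANOVA engine
# ---------------------------------------------------------------------------

def _sum_code(values: np.ndarray) -> tuple[np.ndarray, list]:
    """Sum-to-zero contrast columns for a categorical vector (levels-1 cols)."""
    levels = sorted(pd.unique(values))
    k = len(levels)
    cols = np.zeros((len(values), k - 1))
    for j, level in enumerate(levels[:-1]):
        cols[:, j] = np.where(values == level, 1.0, 0.0)
    cols[np.isin(values, [levels[-1]])] = -1.0
    return cols, levels


def _ss_resid(X: np.ndarray, y: np.ndarray) -> float:
    if X.shape[1] == 0:
        return float((y**2).sum())
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    return float(((y - X @ beta) ** 2).sum())


def greenhouse_geisser_epsilon(Y: np.ndarray, groups: Optional[np.ndarray] = None) -> float:
    """GG sphericity epsilon from the pooled within-group covariance of Y."""
    Y = np.asarray(Y, float)
    n, b = Y.shape
    if groups is None:
        groups = np.zeros(n)
    resid = np.empty_like(Y)
    n_cells = 0
    for g in pd.unique(groups):
        mask = groups == g
        resid[mask] = Y[mask] - Y[mask].mean(axis=0)
        n_cells += 1
    S = resid.T @ resid / (n - n_cells)
    M = np.eye(b) - np.ones((b, b)) / b
    A = M @ S @ M
    tr = np.trace(A)
    tr2 = np.trace(A @ A)
    if tr2 <= 0:
        return 1.0
    eps = tr**2 / ((b - 1) * tr2)
    return float(np.clip(eps, 1.0 / (b - 1), 1.0))


def mixed_rm_anova(
    Y: np.ndarray,
    between: Optional[pd.DataFrame] = None,
    covariates: Optional[np.ndarray] = None,
    within_name: str = "bin",
    gg_correct: Optional[bool] = None,
) -> pd.DataFrame:
    """Split-plot ANOVA: one within factor (columns of Y), between factors,
    optional participant-level continuous covariates.

    ``Y`` is an (N, b) complete table of one value per participant per
    within level.  ``between`` holds one categorical column per between
    factor (a full factorial is modeled when there are two).  Covariates are
    centered before entry and interact with the within factor.

    Returns a table with columns effect, SS, df1, df2, F, p, eta_p_sq,
    epsilon, p_gg.  Between effects are tested against the between-subject
    error; within effects against the bin-by-participant error with
    df2 = (b - 1)(N - g - c).  ``gg_correct`` defaults to b > 2.
    """
    Y = np.asarray(Y, float)
    if np.isnan(Y).any():
        raise ValueError("Y must be a complete participants x bins table")
    n, b = Y.shape
    if gg_correct is None:
        gg_correct = b > 2
    if between is None:
        between = pd.DataFrame(index=pd.RangeIndex(n))

    factor_cols: dict[str, np.ndarray] = {}
    for fname in between.columns:
        cols, levels = _sum_code(between[fname].to_numpy())
        if len(levels) < 2:
            raise ValueError(f"between factor {fname!r} needs >= 2 levels")
        factor_cols[fname] = cols
    between_terms = list(factor_cols)
    if len(between_terms) == 2:
        f1, f2 = between_terms
        inter = np.einsum("ni,nj->nij", factor_cols[f1], factor_cols[f2])
        factor_cols[f"{f1}:{f2}"] = inter.reshape(n, -1)
        between_terms.append(f"{f1}:{f2}")
    elif len(between_terms) > 2:
        raise ValueError("at most 2 between factors supported")

    cov = None
    cov_names: list[str] = []
    if covariates is not None:
        cov = np.atleast_2d(np.asarray(covariates, float))
        if cov.shape[0] != n:
            cov = cov.T
        cov = cov - cov.mean(axis=0)
        cov_names = [f"cov{i+1}" for i in range(cov.shape[1])]

    rows = []

    # --- between-subjects stratum (participant means) ---
    m = Y.mean(axis=1)
    blocks: dict[str, np.ndarray] = {t: factor_cols[t] for t in between_terms}
    for i, cname in enumerate(cov_names):
        blocks[cname] = cov[:, [i]]
    X_between = np.column_stack([np.ones(n)] + [blocks[k] for k in blocks])
    rank_between = X_between.shape[1]
    sse_b = _ss_resid(X_between, m)
    df_b = n - rank_between
    for term, cols in blocks.items():
        X_red = np.column_stack(
            [np.ones(n)] + [c for k, c in blocks.items() if k != term]
        )
        ss = _ss_resid(X_red, m) - sse_b
        df1 = cols.shape[1]
        F = (ss / df1) / (sse_b / df_b) if df_b > 0 else np.nan
        rows.append(
            {
                "effect": term,
                "SS": ss,
                "df1": float(df1),
                "df2": float(df_b),
                "F": F,
                "p": float(sps.f.sf(F, df1, df_b)) if df_b > 0 else np.nan,
                "eta_p_sq": ss / (ss + sse_b) if ss + sse_b > 0 else 0.0,
                "epsilon": np.nan,
                "p_gg": np.nan,
            }
        )

    # --- within-subjects stratum (deviations from participant means) ---
    D = (Y - m[:, None]).reshape(-1)  # row-major: participant-by-bin
    bin_ind = np.tile(np.eye(b), (n, 1))
    wblocks: dict[str, tuple[np.ndarray, int]] = {
        within_name: (bin_ind, b - 1)
    }
    for term in between_terms:
        cols = np.repeat(factor_cols[term], b, axis=0)
        prod = np.concatenate(
            [bin_ind * cols[:, [j]] for j in range(cols.shape[1])], axis=1
        )
        wblocks[f"{within_name}:{term}"] = (prod, (b - 1) * factor_cols[term].shape[1])
    for i, cname in enumerate(cov_names):
        cov_long = np.repeat(cov[:, i], b)
        wblocks[f"{within_name}:{cname}"] = (bin_ind * cov_long[:, None], b - 1)

    X_within = np.column_stack([blk for blk, _ in wblocks.values()])
    sse_w = _ss_resid(X_within, D)
    df_w = (b - 1) * (n - rank_between)
    cell_labels = (
        between.astype(str).agg("|".join, axis=1).to_numpy()
        if len(between.columns)
        else None
    )
    eps = greenhouse_geisser_epsilon(Y, cell_labels)
    for term, (cols, df1) in wblocks.items():
        X_red = np.column_stack(
            [blk for k, (blk, _) in wblocks.items() if k != term]
        ) if len(wblocks) > 1 else np.empty((len(D), 0))
        ss = _ss_resid(X_red, D) - sse_w
        F = (ss / df1) / (sse_w / df_w) if df_w > 0 else np.nan
        p_unc = float(sps.f.sf(F, df1, df_w)) if df_w > 0 else np.nan
        p_gg = (
            float(sps.f.sf(F, df1 * eps, df_w * eps)) if df_w > 0 else np.nan
        )
        rows.append(
            {
                "effect": term,
                "SS": ss,
                "df1": df1 * eps if gg_correct else float(df1),
                "df2": df_w * eps if gg_correct else float(df_w),
                "F": F,
                "p": p_gg if gg_correct else p_unc,
                "eta_p_sq": ss / (ss + sse_w) if ss + sse_w > 0 else 0.0,
                "epsilon": eps,
                "p_gg": p_gg,
            }
        )
    return pd.DataFrame(rows)


def binned_anova(
    summaries: pd.DataFrame,
    covariates: Optional[pd.DataFrame] = None,
    n_bins: int = 4,
    enforce_gate: bool = True,
) -> pd.DataFrame:
    """Hit-rate ANOVA: bin (within) x learner group (between) [+ covariates].

    ``summaries`` is the frame from :func:`cohort_recognition`; participants
    failing the 10-trials-per-bin gate are excluded when ``enforce_gate``.
    ``covariates`` (indexed like ``summaries``) typically holds the RT and
    accuracy switch costs.
    """
    data = summaries[summaries["bin_gate_ok"]] if enforce_gate else summaries
    bin_cols = [f"hit_bin{b}" for b in range(1, n_bins + 1)]
    data = data.dropna(subset=bin_cols)
    cov = None
    if covariates is not None:
        cov_sub = covariates.loc[data.index]
        complete = cov_sub.notna().all(axis=1)
        if not complete.all():
            logger.info("%d participants dropped for missing covariates",
                        int((~complete).sum()))
        data = data[complete]
        cov = cov_sub[complete].to_numpy(float)
    for g in ("clustered", "non_clustered"):
        if (data["group"] == g).sum() < 2:
            raise ValueError(f"need >= 2 participants in group {g!r}")
    Y = data[bin_cols].to_numpy(float)
    return mixed_rm_anova(Y, data[["group"]], cov)


def early_bins_comparison(
    summaries_by_experiment: dict[int, pd.DataFrame],
    covariates_by_experiment: Optional[dict[int, pd.DataFrame]] = None,
) -> tuple[pd.DataFrame, EffectSizeReport]:
    """Pooled analysis of the first two learning-phase bins across experiments.

    Within factor: bin (1-30 vs 31-60); between factors: learner group and,
    when more than one experiment is supplied, experiment.  Also returns the
    independent t-test comparing bin-1 hit rates between groups (pooled).
    """
    frames = []
    covs = []
    for exp_id, summ in summaries_by_experiment.items():
        d = summ[summ["bin_gate_ok"]].dropna(subset=["hit_bin1", "hit_bin2"]).copy()
        d["experiment"] = exp_id
        frames.append(d)
        if covariates_by_experiment is not None:
            covs.append(covariates_by_experiment[exp_id].loc[d.index])
    data = pd.concat(frames, ignore_index=True)
    Y = data[["hit_bin1", "hit_bin2"]].to_numpy(float)
    between_cols = ["group"]
    if data["experiment"].nunique() > 1:
        between_cols.append("experiment")
    else:
        logger.warning("single experiment supplied; experiment factor dropped")
    cov = pd.concat(covs, ignore_index=True).to_numpy(float) if covs else None
    table = mixed_rm_anova(Y, data[between_cols], cov)
    t_bin1 = independent_t_report(
        data.loc[data["group"] == "non_clustered", "hit_bin1"].to_numpy(),
        data.loc[data["group"] == "clustered", "hit_bin1"].to_numpy(),
        name="bin1_nonclustered_vs_clustered",
    )
    return table, t_bin1


def two_within_anova(
    cells: np.ndarray,
    groups: np.ndarray,
    factor_a: str,
    factor_b: str,
) -> pd.DataFrame:
    """Split-plot ANOVA with two 2-level within factors and one between factor.

    ``cells`` is (N, 4) ordered [A1B1, A1B2, A2B1, A2B2].  Each within
    effect is tested via its per-participant contrast score (exact for
    2-level factors): the effect itself as the sum-coded intercept and the
    effect-by-group interaction as the group term, both against the
    contrast's between-participant error with df2 = N - g.
    """
    cells = np.asarray(cells, float)
    if cells.shape[1] != 4:
        raise ValueError("cells must have 4 columns (2 x 2 within design)")
    n = cells.shape[0]
    gcols, glevels = _sum_code(np.asarray(groups))
    g = len(glevels)
    contrasts = {
        factor_a: (cells[:, 0] + cells[:, 1] - cells[:, 2] - cells[:, 3]) / 2,
        factor_b: (cells[:, 0] - cells[:, 1] + cells[:, 2] - cells[:, 3]) / 2,
        f"{factor_a}:{factor_b}": (cells[:, 0] - cells[:, 1] - cells[:, 2] + cells[:, 3]) / 2,
    }
    rows = []
    X_full = np.column_stack([np.ones(n), gcols])
    for name, c in contrasts.items():
        sse = _ss_resid(X_full, c)
        df2 = n - X_full.shape[1]
        ss_eff = _ss_resid(gcols, c) - sse if g > 1 else _ss_resid(
            np.empty((n, 0)), c
        ) - sse  # drop intercept
        tests = [(name, ss_eff, 1)]
        if g > 1:
            ss_int = _ss_resid(np.ones((n, 1)), c) - sse  # drop group
            tests.append((f"{name}:group", ss_int, g - 1))
        for label, ss, df1 in tests:
            F = (ss / df1) / (sse / df2)
            rows.append(
                {
                    "effect": label,
                    "SS": ss,
                    "df1": float(df1),
                    "df2": float(df2),
                    "F": F,
                    "p": float(sps.f.sf(F, df1, df2)),
                    "eta_p_sq": ss / (ss + sse) if ss + sse > 0 else 0.0,
                    "epsilon": np.nan,
                    "p_gg": np.nan,
                }
            )
    if g < 2:
        return pd.DataFrame(rows)
    # between-subjects group effect on participant means
    m = cells.mean(axis=1)
    sse = _ss_resid(X_full, m)
    df2 = n - X_full.shape[1]
    ss = _ss_resid(np.ones((n, 1)), m) - sse
    F = (ss / (g - 1)) / (sse / df2)
    rows.append(
        {
            "effect": "group",
            "SS": ss,
            "df1": float(g - 1),
            "df2": float(df2),
            "F": F,
            "p": float(sps.f.sf(F, g - 1, df2)),
            "eta_p_sq": ss / (ss + sse) if ss + sse > 0 else 0.0,
            "epsilon": np.nan,
            "p_gg": np.nan,
        }
    )
    return pd.DataFrame(rows)


def source_memory_analysis(cohort) -> dict:
    """Source-memory analysis (Experiment 1 designs only).

    Restricted, as in the recognition analysis itself, to old images: source
    accuracy is compared to chance (0.5) per recognition-rating class within
    each learner group, rated-old vs rated-new accuracy is compared with a
    paired t-test per group, and a trial type (2) x rating (2) x group ANOVA
    is run on the per-participant cell accuracies.
    """
    rows = []
    for pid, precs in cohort.memory.groupby("participant"):
        design = cohort.design_for(int(precs["version"].iloc[0]))
        if not design.source_memory:
            raise ValueError(
                "source-memory analysis requires an Experiment-1 design with "
                "source responses"
            )
        d1, d2 = design.dims[0].name, design.dims[1].name
        kept = collapse_ratings(filter_memory_trials(precs))
        old = kept[(kept["status"] == "old") & kept["response"].notna()]
        cell = {"participant": pid, "group": precs["group"].iloc[0]}
        ok = True
        for rating in ("old", "new"):
            rated = old[old["response"] == rating]
            for dim, col in ((d1, "source_dim1_resp"), (d2, "source_dim2_resp")):
                answered = rated[rated[col].notna()]
                key = f"{dim}_{rating}"
                if answered.empty:
                    ok = False
                    break
                cell[key] = float((answered[col] == answered[dim]).mean())
            if not ok:
                break
        if ok:
            rows.append(cell)
        else:
            logger.info("participant %s dropped from source analysis (empty cell)", pid)
    table = pd.DataFrame(rows)
    d1_key = [c for c in table.columns if c.endswith("_old")][0].rsplit("_", 1)[0]
    d2_key = [c for c in table.columns if c.endswith("_old")][1].rsplit("_", 1)[0]
    cells = table[
        [f"{d1_key}_old", f"{d1_key}_new", f"{d2_key}_old", f"{d2_key}_new"]
    ].to_numpy(float)

    chance_tests = {}
    for group in ("clustered", "non_clustered"):
        sub = table[table["group"] == group]
        for rating in ("old", "new"):
            acc = sub[[f"{d1_key}_{rating}", f"{d2_key}_{rating}"]].mean(axis=1)
            chance_tests[(group, rating)] = one_sample_t_report(
                acc.to_numpy(), 0.5, name=f"{group}_{rating}_vs_chance"
            )
    old_vs_new = {
        group: paired_t_report(
            table.loc[table["group"] == group, [f"{d1_key}_old", f"{d2_key}_old"]]
            .mean(axis=1).to_numpy(),
            table.loc[table["group"] == group, [f"{d1_key}_new", f"{d2_key}_new"]]
            .mean(axis=1).to_numpy(),
            name=f"{group}_rated_old_vs_new",
        )
        for group in ("clustered", "non_clustered")
    }
    anova = two_within_anova(
        cells, table["group"].to_numpy(), factor_a="trial_type", factor_b="rating"
    )
    return {"chance": chance_tests, "old_vs_new": old_vs_new, "anova": anova,
            "cells": table}


def transfer_analysis(cohort) -> pd.DataFrame:
    """Post-rule-switch accuracy: transfer (2) x time bin (2) x group ANOVA.

    For Experiment-3 cohorts only: accuracy on responded post-switch trials
    is tabulated per transfer type (positive: key kept; negative: key
    changed) and post-switch half (trials 61-90 vs 91-120), then analyzed
    with both within factors and learner group between.  Participants with
    an empty cell are dropped with a log entry.
    """
    rows = []
    for pid, ptrials in cohort.learning.groupby("participant"):
        design = cohort.design_for(int(ptrials["version"].iloc[0]))
        if design.rule_switch_at is None or design.post_switch_mapping is None:
            raise ValueError("transfer analysis requires an Experiment-3 design")
        cut = design.rule_switch_at
        half = (design.n_learning_trials - cut) // 2
        classif = transfer_classification(design.mapping, design.post_switch_mapping)
        d1, d2 = design.dims[0].name, design.dims[1].name
        pos = {(c.level1, c.level2) for c in classif["positive"]}
        post = ptrials[(ptrials["trial"] > cut) & ~ptrials["timeout"]].copy()
        post["transfer"] = [
            "positive" if (a, b) in pos else "negative"
            for a, b in zip(post[d1], post[d2])
        ]
        post["time_bin"] = np.where(post["trial"] <= cut + half, "early", "late")
        cell = {"participant": pid, "group": ptrials["group"].iloc[0]}
        ok = True
        for transfer in ("positive", "negative"):
            for tb in ("early", "late"):
                sub = post[(post["transfer"] == transfer) & (post["time_bin"] == tb)]
                if sub.empty:
                    ok = False
                    break
                cell[f"{transfer}_{tb}"] = float(sub["correct"].mean())
            if not ok:
                break
        if ok:
            rows.append(cell)
        else:
            logger.info("participant %s dropped from transfer analysis", pid)
    table = pd.DataFrame(rows)
    cells = table[
        ["positive_early", "positive_late", "negative_early", "negative_late"]
    ].to_numpy(float)
    return two_within_anova(
        cells, table["group"].to_numpy(), factor_a="transfer", factor_b="time_bin"
    )
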