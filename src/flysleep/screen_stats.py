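"""Screen hit calling and the two-group statistical procedure.

A reverse-genetics sleep screen calls a genotype a *hit* when its mean sleep
duration and/or average sleep bout length (ABL) deviates by at least 2
standard deviations from the population of genotype means — computed within
each experiment batch — in 3 independent experiments, with a consistent
direction.  No multiple-testing correction is applied (mirroring screen
practice); the expected false-positive count is reported instead so users
can judge the background rate.

Group comparisons follow the screen's convention: bout-length metrics are
compared with the Mann-Whitney U test (bout lengths are not normally
distributed); other metrics use a Shapiro-Wilk gate (alpha = 0.05 on each
group) choosing between a two-tailed Welch t-test and Mann-Whitney U.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "GroupComparison",
    "compare_groups",
    "genotype_summaries",
    "population_stats",
    "call_hits",
    "expected_false_positives",
    "penetrance",
]

HIT_THRESHOLD_SD = 2.0
REQUIRED_REPLICATES = 3
SHAPIRO_ALPHA = 0.05
# metric kinds compared with the rank test regardless of normality
RANK_ONLY_KINDS = frozenset({"abl", "abl_min", "bout_length", "sleep_bout_length"})


@dataclass(frozen=True)
class GroupComparison:
    test_name: str  # "welch_t" or "mann_whitney_u"
    statistic: float
    pvalue: float
    n_a: int
    n_b: int


def compare_groups(
    sample_a,
    sample_b,
    metric_kind: str = "generic",
    normality_alpha: float = SHAPIRO_ALPHA,
) -> GroupComparison:
    """Two-group comparison with Shapiro-Wilk-gated test selection.

    Bout-length metric kinds always use Mann-Whitney U; otherwise both groups
    must pass Shapiro-Wilk (p > alpha) for the two-tailed Welch t-test to be
    used, else Mann-Whitney U.  Requires n >= 3 per group.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    a, b = a[np.isfinite(a)], b[np.isfinite(b)]
    if len(a) < 3 or len(b) < 3:
        raise ValueError("each sample needs n >= 3")
    use_rank = metric_kind.lower() in RANK_ONLY_KINDS
    if not use_rank:
        # Shapiro-Wilk is degenerate on constant samples; treat as non-normal
        if np.ptp(a) == 0 or np.ptp(b) == 0:
            use_rank = True
        else:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                normal = (
                    stats.shapiro(a).pvalue > normality_alpha
                    and stats.shapiro(b).pvalue > normality_alpha
                )
            use_rank = not normal
    if use_rank:
        res = stats.mannwhitneyu(a, b, alternative="two-sided")
        name = "mann_whitney_u"
    else:
        res = stats.ttest_ind(a, b, equal_var=False)
        name = "welch_t"
    return GroupComparison(
        test_name=name,
        statistic=float(res.statistic),
        pvalue=float(res.pvalue),
        n_a=len(a),
        n_b=len(b),
    )


def genotype_summaries(
    per_fly: pd.DataFrame,
    metrics: tuple[str, ...] = ("sleep_min_per_day", "abl_min"),
    genotype_col: str = "genotype",
    experiment_col: str = "experiment_id",
) -> pd.DataFrame:
    """Mean metric per genotype within each experiment batch (plus n_flies)."""
    g = per_fly.groupby([experiment_col, genotype_col])
    out = g[list(metrics)].mean()
    out["n_flies"] = g.size()
    return out.reset_index()


def population_stats(
    summaries: pd.DataFrame,
    metrics: tuple[str, ...] = ("sleep_min_per_day", "abl_min"),
    genotype_col: str = "genotype",
    experiment_col: str = "experiment_id",
) -> pd.DataFrame:
    """Z-score genotype means against their experiment's population.

    z = (genotype mean - mean over genotypes) / SD over genotypes, computed
    within each experiment only.  Raises on zero SD; warns when an experiment
    has fewer than 3 genotypes (SD unstable).
    """
    out = summaries.copy()
    for metric in metrics:
        zcol = f"z_{metric}"
        out[zcol] = np.nan
        for exp, idx in out.groupby(experiment_col).groups.items():
            vals = out.loc[idx, metric].astype(float)
            if len(vals) < 3:
                warnings.warn(
                    f"experiment {exp!r}: <3 genotypes, z-scores unstable",
                    stacklevel=2,
                )
            sd = vals.std(ddof=1)
            if not np.isfinite(sd) or sd == 0:
                raise ValueError(f"experiment {exp!r}: zero SD for {metric}")
            out.loc[idx, zcol] = (vals - vals.mean()) / sd
    return out


_DIRECTIONS = {
    ("sleep_min_per_day", 1): "long",
    ("sleep_min_per_day", -1): "short",
    ("abl_min", 1): "consol",
    ("abl_min", -1): "frag",
}


def call_hits(
    zscores: pd.DataFrame,
    threshold_sd: float = HIT_THRESHOLD_SD,
    required_replicates: int = REQUIRED_REPLICATES,
    metrics: tuple[str, ...] = ("sleep_min_per_day", "abl_min"),
    genotype_col: str = "genotype",
    experiment_col: str = "experiment_id",
) -> pd.DataFrame:
    """Call screen hits from a per-experiment z-score table.

    A genotype is a hit when, for sleep duration and/or ABL, |z| >= threshold
    in at least ``required_replicates`` experiments with the same sign.
    Genotypes measured in fewer experiments are flagged not callable.
    """
    rows = []
    for geno, sub in zscores.groupby(genotype_col, sort=False):
        n_exp = sub[experiment_col].nunique()
        callable_ = n_exp >= required_replicates
        hit = False
        directions: list[str] = []
        n_supporting = 0
        for metric in metrics:
            z = sub[f"z_{metric}"].astype(float)
            exceed = z[np.abs(z) >= threshold_sd]
            if (
                callable_
                and len(exceed) >= required_replicates
                and (np.sign(exceed).nunique() == 1)
            ):
                hit = True
                directions.append(_DIRECTIONS.get(
                    (metric, int(np.sign(exceed.iloc[0]))), metric
                ))
                n_supporting = max(n_supporting, len(exceed))
        rows.append(
            {
                genotype_col: geno,
                "callable": callable_,
                "n_experiments": n_exp,
                "hit": hit,
                "direction": "+".join(directions),
                "n_supporting_experiments": n_supporting,
            }
        )
    return pd.DataFrame(rows)


def expected_false_positives(
    n_genotypes: int,
    threshold_sd: float = HIT_THRESHOLD_SD,
    required_replicates: int = REQUIRED_REPLICATES,
) -> dict[str, float]:
    """Expected null flag/hit counts under a Gaussian population.

    Per-experiment flags occur at rate 2*Phi(-threshold); a same-direction
    triple hit at 2*Phi(-threshold)^replicates.  No correction is applied in
    hit calling, so these counts quantify the background.
    """
    p1 = 2.0 * stats.norm.sf(threshold_sd)
    p_rep = 2.0 * stats.norm.sf(threshold_sd) ** required_replicates
    return {
        "per_experiment_flag_rate": p1,
        "expected_flags_per_experiment": n_genotypes * p1,
        "replicated_hit_rate": p_rep,
        "expected_replicated_hits": n_genotypes * p_rep,
    }


def penetrance(n_affected: int, n_total: int) -> float:
    """Percent of individuals showing a phenotype (e.g. 10/50 brains -> 20.0)."""
    if n_total <= 0 or not 0 <= n_affected <= n_total:
        raise ValueError("need 0 <= n_affected <= n_total, n_total > 0")
    return 100.0 * n_affected / n_total
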