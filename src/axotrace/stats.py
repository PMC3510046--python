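"""Normality-routed group comparisons, climbing scores and report output.

The study's statistical recipe: every group is first tested for normality
with the Shapiro-Wilk test at α = 0.05. If all groups pass, comparison is
parametric — Student's t-test for two groups, one-way ANOVA followed by a
Tukey-Kramer post-test for more. Otherwise it is nonparametric —
Mann-Whitney for two groups, Kruskal-Wallis H followed by Dunn's test
(tie-corrected z statistics) for more. Significance stars: * p<0.05,
** p<0.01, *** p<0.001. Descriptives report mean, s.d. and s.e.m.

Dunn's test is implemented here directly (rank sums with the tie
correction); an optional multiple-comparison adjustment can be requested
but is off by default.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "GroupData",
    "PairwiseResult",
    "ComparisonReport",
    "ClimbingResult",
    "group_compare",
    "dunn_test",
    "climbing_scores",
    "significance_stars",
    "make_report",
]

PARAMETRIC = "parametric"
NONPARAMETRIC = "nonparametric"


@dataclass
class GroupData:
    """Labelled groups of numeric observations with a unit annotation."""

    groups: dict
    unit: str = ""

    def __post_init__(self) -> None:
        self.groups = {k: np.asarray(v, dtype=float) for k, v in self.groups.items()}
        if len(self.groups) < 2:
            raise ValueError("need at least two groups for a comparison")
        for k, v in self.groups.items():
            if v.size == 0:
                raise ValueError(f"group {k!r} is empty")

    @property
    def labels(self) -> list:
        return list(self.groups)


@dataclass
class PairwiseResult:
    group_a: str
    group_b: str
    statistic: float
    p_value: float

    @property
    def stars(self) -> str:
        return significance_stars(self.p_value)


@dataclass
class ComparisonReport:
    route: str                       # parametric | nonparametric
    omnibus_test: str
    omnibus_statistic: float
    omnibus_p: float
    pairwise: list
    descriptives: pd.DataFrame
    shapiro_p: dict
    notes: list = field(default_factory=list)


@dataclass
class ClimbingResult:
    per_fly: np.ndarray              # mean of 3 binary trials, in [0, 1]
    group_mean: float
    n_flies: int
    notes: list = field(default_factory=list)


def significance_stars(p: float) -> str:
    """Star convention: * p<0.05, ** p<0.01, *** p<0.001."""
    if not np.isfinite(p):
        return ""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def _descriptives(data: GroupData) -> pd.DataFrame:
    rows = []
    for k, v in data.groups.items():
        sd = float(np.std(v, ddof=1)) if v.size > 1 else 0.0
        rows.append({
            "group": k, "n": v.size, "mean": float(np.mean(v)),
            "sd": sd, "sem": sd / np.sqrt(v.size) if v.size else np.nan,
        })
    return pd.DataFrame(rows).set_index("group")


def dunn_test(groups: dict, adjust: str | None = None) -> list[PairwiseResult]:
    """Dunn's post-hoc test on ranks with tie correction.

    z_ij = (R̄_i - R̄_j) / sqrt([N(N+1)/12 - ΣT/(12(N-1))] (1/n_i + 1/n_j))
    where ΣT = Σ(t³ - t) over tie groups; two-sided normal p-values,
    optionally adjusted ('bonferroni' or 'holm').
    """
    labels = list(groups)
    values = [np.asarray(groups[k], dtype=float) for k in labels]
    all_vals = np.concatenate(values)
    N = all_vals.size
    ranks = sps.rankdata(all_vals)
    mean_ranks = {}
    i0 = 0
    for k, v in zip(labels, values):
        mean_ranks[k] = float(np.mean(ranks[i0:i0 + v.size]))
        i0 += v.size
    _, counts = np.unique(all_vals, return_counts=True)
    tie_sum = float(np.sum(counts**3 - counts))
    var_base = N * (N + 1) / 12.0 - tie_sum / (12.0 * (N - 1))

    results = []
    for i in range(len(labels)):
        for j in range(i + 1, len(labels)):
            a, b = labels[i], labels[j]
            na, nb = len(values[i]), len(values[j])
            se = np.sqrt(var_base * (1.0 / na + 1.0 / nb))
            z = (mean_ranks[a] - mean_ranks[b]) / se if se > 0 else 0.0
            p = 2.0 * sps.norm.sf(abs(z))
            results.append(PairwiseResult(a, b, float(z), float(min(p, 1.0))))
    if adjust:
        from statsmodels.stats.multitest import multipletests
        ps = [r.p_value for r in results]
        adj = multipletests(ps, method=adjust)[1]
        for r, p in zip(results, adj):
            r.p_value = float(p)
    return results


def group_compare(data: GroupData, alpha: float = 0.05, dunn_adjust: str | None = None) -> ComparisonReport:
    """Run the normality-routed comparison and report the route taken.

    Shapiro-Wilk per group at ``alpha``; all normal → t-test (2 groups) or
    one-way ANOVA + Tukey-Kramer (>2); otherwise Mann-Whitney (2) or
    Kruskal-Wallis + Dunn's test (>2). Any group with fewer than 3
    observations cannot be normality-tested and forces the nonparametric
    route (with a logged warning).
    """
    notes: list[str] = []
    shapiro_p: dict = {}
    force_nonpar = False
    for k, v in data.groups.items():
        if v.size < 3:
            shapiro_p[k] = float("nan")
            force_nonpar = True
            msg = f"group {k!r} has {v.size} < 3 observations; nonparametric route forced"
            notes.append(msg)
            warnings.warn(msg, stacklevel=2)
        elif np.ptp(v) == 0:
            shapiro_p[k] = 0.0   # constant data: treat as non-normal
        else:
            shapiro_p[k] = float(sps.shapiro(v).pvalue)
    normal = (not force_nonpar) and all(p > alpha for p in shapiro_p.values())

    labels = data.labels
    values = [data.groups[k] for k in labels]
    pairwise: list[PairwiseResult] = []
    if normal:
        route = PARAMETRIC
        if len(labels) == 2:
            res = sps.ttest_ind(values[0], values[1], equal_var=True)
            omnibus = ("student_t", float(res.statistic), float(res.pvalue))
            pairwise = [PairwiseResult(labels[0], labels[1], float(res.statistic), float(res.pvalue))]
        else:
            f = sps.f_oneway(*values)
            omnibus = ("one_way_anova", float(f.statistic), float(f.pvalue))
            from statsmodels.stats.multicomp import pairwise_tukeyhsd
            endog = np.concatenate(values)
            grp = np.concatenate([[k] * len(v) for k, v in zip(labels, values)])
            tk = pairwise_tukeyhsd(endog, grp, alpha=alpha)
            for (a, b, meandiff, p_adj, *_rest) in tk.summary().data[1:]:
                pairwise.append(PairwiseResult(str(a), str(b), float(meandiff), float(p_adj)))
    else:
        route = NONPARAMETRIC
        if len(labels) == 2:
            res = sps.mannwhitneyu(values[0], values[1], alternative="two-sided")
            omnibus = ("mann_whitney", float(res.statistic), float(res.pvalue))
            pairwise = [PairwiseResult(labels[0], labels[1], float(res.statistic), float(res.pvalue))]
        else:
            h = sps.kruskal(*values)
            omnibus = ("kruskal_wallis", float(h.statistic), float(h.pvalue))
            pairwise = dunn_test(data.groups, adjust=dunn_adjust)

    return ComparisonReport(
        route=route,
        omnibus_test=omnibus[0],
        omnibus_statistic=omnibus[1],
        omnibus_p=omnibus[2],
        pairwise=pairwise,
        descriptives=_descriptives(data),
        shapiro_p=shapiro_p,
        notes=notes,
    )


def climbing_scores(trials, expected_flies: int = 50) -> ClimbingResult:
    """Per-fly climbing score = mean of exactly 3 binary trials.

    A successful climb scores 1, a failed one 0; the group mean averages
    the per-fly scores. A note is recorded when the cohort deviates from
    the protocol's 50 flies.
    """
    arr = np.asarray(trials, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 3:
        raise ValueError("expected one row of exactly 3 trials per fly")
    if not np.all(np.isin(arr, (0.0, 1.0))):
        raise ValueError("trial values must be binary (0 or 1)")
    per_fly = arr.mean(axis=1)
    notes = []
    if arr.shape[0] != expected_flies:
        notes.append(f"{arr.shape[0]} flies scored; protocol uses {expected_flies}")
    return ClimbingResult(per_fly, float(per_fly.mean()), arr.shape[0], notes)


# ---------------------------------------------------------------------------
# reporting
# ---------------------------------------------------------------------------

def make_report(results: dict, out_dir, config: dict | None = None, seeds=None):
    """Write figures and CSV tables for a dict of metric -> GroupData.

    Figures follow the study's convention: the s.e.m. is drawn as a box
    around each group mean and the s.d. as a black line. A run log with a
    config hash and the seeds used is written alongside. Empty input
    produces an empty report with a warning rather than an error.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = []
    if not results:
        warnings.warn("empty results: writing empty report", stacklevel=2)
    for name, data in sorted(results.items()):
        report = group_compare(data)
        desc = report.descriptives.copy()
        desc.to_csv(out / f"{name}_descriptives.csv")
        pw = pd.DataFrame(
            [{"group_a": r.group_a, "group_b": r.group_b,
              "statistic": r.statistic, "p": r.p_value, "stars": r.stars}
             for r in report.pairwise]
        )
        pw.to_csv(out / f"{name}_pairwise.csv", index=False)

        fig, ax = plt.subplots(figsize=(1.2 * len(desc) + 1.5, 3.2))
        for i, (g, row) in enumerate(desc.iterrows()):
            ax.add_patch(plt.Rectangle((i - 0.25, row["mean"] - row["sem"]),
                                       0.5, 2 * row["sem"],
                                       facecolor="0.8", edgecolor="0.3"))
            ax.plot([i, i], [row["mean"] - row["sd"], row["mean"] + row["sd"]],
                    color="black", lw=1.5)
            ax.plot([i - 0.25, i + 0.25], [row["mean"]] * 2, color="black", lw=2)
        ax.set_xticks(range(len(desc)))
        ax.set_xticklabels(desc.index, rotation=30, ha="right")
        ax.set_ylabel(f"{name} ({data.unit})" if data.unit else name)
        ax.set_title(f"{name} [{report.route}]")
        fig.tight_layout()
        fig.savefig(out / f"{name}.png", dpi=120)
        plt.close(fig)
        written.append(name)

    cfg = config or {}
    log = {
        "metrics": written,
        "config_hash": hashlib.sha256(
            json.dumps(cfg, sort_keys=True, default=str).encode()
        ).hexdigest(),
        "seeds": list(np.atleast_1d(seeds).tolist()) if seeds is not None else [],
    }
    (out / "run_log.json").write_text(json.dumps(log, indent=2, sort_keys=True))
    return log
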