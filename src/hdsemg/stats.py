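"""Statistical harness for feature tables: normality gating, split-plot
ANOVA (two between factors, one within factor), Bonferroni post hocs,
Mann–Whitney and Pearson correlation.

Feature tables are long-format DataFrames with columns ``subject``,
``age_group``, ``sex``, ``level``, ``feature``, ``value`` (plus anything
else, ignored). Every feature is gated per cell by Shapiro–Wilk at
α = 0.05 and routed parametric only if all cells pass.

The split-plot (mixed) ANOVA is computed from balanced cell means with
subjects as the error stratum for the between effects and the
subject-by-level interaction as the error stratum for the within effects;
Greenhouse–Geisser correction accompanies within effects whenever the
within factor has more than two levels.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sst

__all__ = [
    "normality_gate",
    "anova_two_way_within",
    "mann_whitney",
    "pearson_correlation",
    "GateResult",
    "AnovaResult",
    "MannWhitneyResult",
]

ALPHA = 0.05


# ---------------------------------------------------------------------------
# Normality gate


@dataclass
class GateResult:
    route: str  # "parametric" | "nonparametric"
    cells: pd.DataFrame  # one row per cell: key, n, W, p, normal, flagged


def normality_gate(
    table: pd.DataFrame,
    feature: str | None = None,
    cell_by: tuple[str, ...] = ("age_group", "sex", "level"),
    alpha: float = ALPHA,
) -> GateResult:
    """Shapiro–Wilk per cell; parametric route iff every cell passes.

    Cells with fewer than 3 observations cannot be tested; they are
    flagged and force the nonparametric route.
    """
    df = table
    if feature is not None and "feature" in df.columns:
        df = df[df["feature"] == feature]
    rows = []
    all_normal = True
    for key, grp in df.groupby(list(cell_by), sort=True, observed=True):
        values = np.asarray(grp["value"], dtype=float)
        if len(values) < 3:
            rows.append({"cell": key, "n": len(values), "W": np.nan, "p": np.nan,
                         "normal": False, "flagged": True})
            all_normal = False
            continue
        if np.ptp(values) == 0:  # constant cell: shapiro is undefined
            rows.append({"cell": key, "n": len(values), "W": np.nan, "p": np.nan,
                         "normal": False, "flagged": True})
            all_normal = False
            continue
        W, p = sst.shapiro(values)
        normal = p > alpha
        all_normal &= normal
        rows.append({"cell": key, "n": len(values), "W": W, "p": p,
                     "normal": normal, "flagged": False})
    if not rows:
        raise ValueError("no cells found in the feature table")
    return GateResult(
        route="parametric" if all_normal else "nonparametric",
        cells=pd.DataFrame(rows),
    )


# ---------------------------------------------------------------------------
# Split-plot ANOVA


@dataclass
class AnovaResult:
    effects: pd.DataFrame  # effect, ss, df1, df2, F, p (+ p_gg for within)
    posthoc: pd.DataFrame | None
    epsilon_gg: float | None
    within_degenerate: bool  # True when only one within level was supplied

    def p(self, effect: str) -> float:
        return float(self.effects.set_index("effect").loc[effect, "p"])


def _balanced_array(
    df: pd.DataFrame, between: tuple[str, str], within: str, subject: str
) -> tuple[np.ndarray, list, list, list]:
    """Reshape the long table into Y[a, b, subject, w]; error on holes."""
    a_levels = sorted(df[between[0]].unique())
    b_levels = sorted(df[between[1]].unique())
    w_levels = sorted(df[within].unique())
    missing = []
    cells = {}
    counts = set()
    for ai, bi in itertools.product(a_levels, b_levels):
        sub = df[(df[between[0]] == ai) & (df[between[1]] == bi)]
        subjects = sorted(sub[subject].unique())
        if not subjects:
            missing.append((ai, bi, "all levels"))
            continue
        counts.add(len(subjects))
        mat = np.full((len(subjects), len(w_levels)), np.nan)
        piv = sub.pivot_table(index=subject, columns=within, values="value", aggfunc="mean")
        for si, s in enumerate(subjects):
            for wi, w in enumerate(w_levels):
                if s in piv.index and w in piv.columns and not np.isnan(piv.loc[s, w]):
                    mat[si, wi] = piv.loc[s, w]
                else:
                    missing.append((ai, bi, f"subject {s} level {w}"))
        cells[(ai, bi)] = mat
    if missing:
        raise ValueError(f"missing cells in the design: {missing[:10]}")
    if len(counts) != 1:
        raise ValueError(f"unbalanced design: per-cell subject counts {sorted(counts)}")
    n = counts.pop()
    Y = np.stack(
        [np.stack([cells[(ai, bi)] for bi in b_levels]) for ai in a_levels]
    )  # [a, b, n, w]
    assert Y.shape == (len(a_levels), len(b_levels), n, len(w_levels))
    return Y, a_levels, b_levels, w_levels


def _gg_epsilon(Y: np.ndarray) -> float:
    """Greenhouse–Geisser epsilon from the pooled within-cell covariance."""
    a, b, n, w = Y.shape
    if w < 3 or n < 2:
        return 1.0
    covs = [np.cov(Y[ai, bi], rowvar=False) for ai in range(a) for bi in range(b)]
    S = np.mean(covs, axis=0)
    H = np.eye(w) - np.ones((w, w)) / w
    S_dc = H @ S @ H
    num = np.trace(S_dc) ** 2
    den = (w - 1) * np.sum(S_dc * S_dc)
    if den <= 0:
        return 1.0
    return float(np.clip(num / den, 1.0 / (w - 1), 1.0))


def anova_two_way_within(
    table: pd.DataFrame,
    feature: str | None = None,
    between: tuple[str, str] = ("age_group", "sex"),
    within: str = "level",
    subject: str = "subject",
    alpha: float = ALPHA,
    posthoc: bool = True,
) -> AnovaResult:
    """Two-between, one-within (split-plot) ANOVA on a balanced design.

    Between effects are tested against the subjects-within-groups stratum,
    within effects against the level-by-subject stratum. On a significant
    interaction between the two between factors, focused per-level
    comparisons are run by fixing one between factor at a time, with a
    single Bonferroni family spanning all focused comparisons (its size
    ``m`` is emitted with every row).
    """
    df = table
    if feature is not None and "feature" in df.columns:
        df = df[df["feature"] == feature]
    if df.empty:
        raise ValueError(f"no rows for feature {feature!r}")
    Y, a_levels, b_levels, w_levels = _balanced_array(df, between, within, subject)
    a, b, n, w = Y.shape
    if n < 2:
        raise ValueError("need at least two subjects per group cell")
    grand = Y.mean()

    # Between-subjects stratum -------------------------------------------
    subj_means = Y.mean(axis=3)  # [a, b, n]
    ss_between_subj = w * np.sum((subj_means - grand) ** 2)
    mean_a = Y.mean(axis=(1, 2, 3))
    mean_b = Y.mean(axis=(0, 2, 3))
    mean_ab = Y.mean(axis=(2, 3))
    ss_a = b * n * w * np.sum((mean_a - grand) ** 2)
    ss_b = a * n * w * np.sum((mean_b - grand) ** 2)
    ss_ab = n * w * np.sum((mean_ab - grand) ** 2) - ss_a - ss_b
    ss_subj_err = ss_between_subj - ss_a - ss_b - ss_ab
    df_subj_err = a * b * (n - 1)

    rows = []

    def add_between(name, ss, df1):
        ms_err = ss_subj_err / df_subj_err
        F = (ss / df1) / ms_err
        p = sst.f.sf(F, df1, df_subj_err)
        rows.append({"effect": name, "ss": ss, "df1": df1, "df2": df_subj_err,
                     "F": F, "p": p, "p_gg": np.nan, "stratum": "between"})

    name_a, name_b = between
    add_between(name_a, ss_a, a - 1)
    add_between(name_b, ss_b, b - 1)
    add_between(f"{name_a}:{name_b}", ss_ab, (a - 1) * (b - 1))

    eps = None
    degenerate = w == 1
    if not degenerate:
        # Within-subjects stratum ----------------------------------------
        ss_total = np.sum((Y - grand) ** 2)
        mean_w = Y.mean(axis=(0, 1, 2))
        mean_aw = Y.mean(axis=(1, 2))
        mean_bw = Y.mean(axis=(0, 2))
        mean_abw = Y.mean(axis=2)
        ss_w = a * b * n * np.sum((mean_w - grand) ** 2)
        ss_aw = b * n * np.sum((mean_aw - grand) ** 2) - ss_a - ss_w
        ss_bw = a * n * np.sum((mean_bw - grand) ** 2) - ss_b - ss_w
        ss_abw = (
            n * np.sum((mean_abw - grand) ** 2)
            - ss_a - ss_b - ss_ab - ss_w - ss_aw - ss_bw
        )
        ss_w_err = ss_total - ss_between_subj - ss_w - ss_aw - ss_bw - ss_abw
        df_w_err = a * b * (n - 1) * (w - 1)
        eps = _gg_epsilon(Y)

        def add_within(name, ss, df1):
            ms_err = ss_w_err / df_w_err
            F = (ss / df1) / ms_err
            p = sst.f.sf(F, df1, df_w_err)
            p_gg = sst.f.sf(F, eps * df1, eps * df_w_err) if w > 2 else p
            rows.append({"effect": name, "ss": ss, "df1": df1, "df2": df_w_err,
                         "F": F, "p": p, "p_gg": p_gg, "stratum": "within"})

        add_within(within, ss_w, w - 1)
        add_within(f"{name_a}:{within}", ss_aw, (a - 1) * (w - 1))
        add_within(f"{name_b}:{within}", ss_bw, (b - 1) * (w - 1))
        add_within(f"{name_a}:{name_b}:{within}", ss_abw, (a - 1) * (b - 1) * (w - 1))

    effects = pd.DataFrame(rows)

    posthoc_df = None
    interaction_p = float(effects.set_index("effect").loc[f"{name_a}:{name_b}", "p"])
    if posthoc and interaction_p < alpha:
        posthoc_df = _focused_comparisons(Y, a_levels, b_levels, w_levels, between, within)

    return AnovaResult(
        effects=effects, posthoc=posthoc_df, epsilon_gg=eps, within_degenerate=degenerate
    )


def _focused_comparisons(Y, a_levels, b_levels, w_levels, between, within):
    """Per-level comparisons fixing one between factor at a time.

    One Bonferroni family spans every comparison made; ``m`` and the
    adjusted p accompany each row.
    """
    rows = []
    for wi, wl in enumerate(w_levels):
        for ai, al in enumerate(a_levels):  # fix factor A, compare B groups
            for (bi1, bl1), (bi2, bl2) in itertools.combinations(enumerate(b_levels), 2):
                rows.append(_ttest_row(Y[ai, bi1, :, wi], Y[ai, bi2, :, wi],
                                       wl, f"{between[0]}={al}", f"{bl1} vs {bl2}"))
        for bi, bl in enumerate(b_levels):  # fix factor B, compare A groups
            for (ai1, al1), (ai2, al2) in itertools.combinations(enumerate(a_levels), 2):
                rows.append(_ttest_row(Y[ai1, bi, :, wi], Y[ai2, bi, :, wi],
                                       wl, f"{between[1]}={bl}", f"{al1} vs {al2}"))
    df = pd.DataFrame(rows)
    m = len(df)
    df["m"] = m
    df["p_bonferroni"] = np.minimum(1.0, df["p"] * m)
    return df


def _ttest_row(x, y, level, fixed, comparison):
    t, p = sst.ttest_ind(x, y, equal_var=True)
    return {"level": level, "fixed": fixed, "comparison": comparison,
            "mean_diff": float(np.mean(x) - np.mean(y)),
            "t": float(t), "df": len(x) + len(y) - 2, "p": float(p)}


# ---------------------------------------------------------------------------
# Rank and correlation tests


@dataclass(frozen=True)
class MannWhitneyResult:
    U: float
    p: float
    method: str  # "exact" | "asymptotic" | "degenerate"


def mann_whitney(x, y, exact_max_n: int = 8) -> MannWhitneyResult:
    """Two-sided Mann–Whitney U.

    Exact enumeration when both groups have at most ``exact_max_n``
    observations and no ties; otherwise the normal approximation with tie
    correction (and continuity correction). Two fully tied samples carry
    no ordering information and return p = 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be non-empty")
    if np.ptp(np.concatenate([x, y])) == 0:
        return MannWhitneyResult(U=x.size * y.size / 2.0, p=1.0, method="degenerate")
    has_ties = len(np.unique(np.concatenate([x, y]))) < x.size + y.size
    if x.size <= exact_max_n and y.size <= exact_max_n and not has_ties:
        res = sst.mannwhitneyu(x, y, alternative="two-sided", method="exact")
        return MannWhitneyResult(U=float(res.statistic), p=float(res.pvalue), method="exact")
    res = sst.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
    return MannWhitneyResult(U=float(res.statistic), p=float(res.pvalue), method="asymptotic")


def pearson_correlation(x, y) -> tuple[float, float]:
    """Pearson r with a two-sided p from the t transform."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length vectors")
    if x.size < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation is undefined for a zero-variance input")
    r, p = sst.pearsonr(x, y)
    return float(r), float(p)
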