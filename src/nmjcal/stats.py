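"""The study's statistical comparison scheme.

Per-larva datapoints (each larva contributes the mean of its NMJs) are
gated by a Shapiro-Wilk normality test in every group (Levene's test on
variances is run and reported alongside): normally distributed data are
routed to parametric tests (Student's t, mixed-design repeated-measures
ANOVA), otherwise to non-parametric ones (Mann-Whitney U, Kruskal-Wallis).
Tukey HSD compares all pairs post hoc; Dunnett compares every group to a
single control.
"""

from __future__ import annotations

import warnings
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm
import statsmodels.formula.api as smf
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from .datatypes import GroupSummary, StatResult

PARAMETRIC = "parametric"
NONPARAMETRIC = "nonparametric"


def larval_datapoint(nmj_values: Sequence[float]) -> float:
    """Collapse one larva's per-NMJ values into its single datapoint (mean).

    Downstream ``n`` counts larvae, not NMJs.
    """
    v = np.asarray(nmj_values, dtype=float)
    if v.size < 1:
        raise ValueError("a larval datapoint needs at least one NMJ value")
    return float(v.mean())


def larval_datapoints(df: pd.DataFrame, value: str, larva: str = "larva_id",
                      keep: Sequence[str] = ("genotype",)) -> pd.DataFrame:
    """Per-larva means of a tidy per-NMJ table, keeping group columns."""
    keep = [k for k in keep if k in df.columns]
    return (df.groupby([larva, *keep], as_index=False)[value]
              .mean())


def group_summary(values: Sequence[float], label: str = "") -> GroupSummary:
    v = np.asarray(values, dtype=float)
    q75, q25 = np.percentile(v, [75, 25])
    sem = float(v.std(ddof=1) / np.sqrt(v.size)) if v.size > 1 else 0.0
    return GroupSummary(label=label, n=int(v.size), mean=float(v.mean()),
                        sem=sem, median=float(np.median(v)), iqr=float(q75 - q25))


def normality_gate(groups: Sequence[Sequence[float]], alpha: float = 0.05) -> dict:
    """Route to parametric vs non-parametric tests.

    Parametric iff every group passes Shapiro-Wilk at ``alpha``. Levene's
    test across groups is computed and reported but, per the scheme,
    normality alone drives the routing. Returns a dict with keys ``route``,
    ``shapiro_p`` (per group) and ``levene_p``.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    for g in groups:
        if g.size < 3:
            raise ValueError("normality gate needs n >= 3 per group")
        if g.std() == 0:
            raise ValueError("zero-variance group; normality test is degenerate")
    shapiro_p = [float(sps.shapiro(g).pvalue) for g in groups]
    levene_p = float(sps.levene(*groups).pvalue) if len(groups) > 1 else np.nan
    route = PARAMETRIC if all(p > alpha for p in shapiro_p) else NONPARAMETRIC
    return {"route": route, "shapiro_p": shapiro_p, "levene_p": levene_p}


def two_group_test(g1: Sequence[float], g2: Sequence[float], route: str,
                   labels: tuple = ("group1", "group2"),
                   welch: bool = False) -> StatResult:
    """Unpaired two-group comparison.

    ``parametric`` runs the two-tailed Student's t test (pooled variance by
    default; ``welch=True`` drops the equal-variance assumption).
    ``nonparametric`` runs the Mann-Whitney U test: exact enumeration when
    the smaller group has n <= 8 and there are no ties, otherwise the
    normal approximation with tie correction.
    """
    x = np.asarray(g1, dtype=float)
    y = np.asarray(g2, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each group needs n >= 2")
    summaries = [group_summary(x, labels[0]), group_summary(y, labels[1])]
    if route == PARAMETRIC:
        pooled = np.concatenate([x - x.mean(), y - y.mean()])
        if np.allclose(pooled, 0.0):
            raise ValueError("degenerate (zero) variance; t test undefined")
        res = sps.ttest_ind(x, y, equal_var=not welch)
        df = float(res.df) if hasattr(res, "df") else x.size + y.size - 2
        name = "welch_t" if welch else "student_t"
        return StatResult(test_name=name, statistic=float(res.statistic),
                          df=(df,), p_value=float(res.pvalue), groups=summaries)
    if route == NONPARAMETRIC:
        ties = len(np.unique(np.concatenate([x, y]))) < x.size + y.size
        method = "exact" if (min(x.size, y.size) <= 8 and not ties) else "asymptotic"
        res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method)
        return StatResult(test_name=f"mann_whitney_u_{method}",
                          statistic=float(res.statistic), df=(np.nan,),
                          p_value=float(res.pvalue), groups=summaries)
    raise ValueError(f"unknown route {route!r}")


def t_test_from_summary(mean1: float, sem1: float, n1: int,
                        mean2: float, sem2: float, n2: int) -> StatResult:
    """Pooled-variance two-tailed Student's t from printed summary stats
    (mean ± SEM, n); useful for checking reported comparisons."""
    s1sq = (sem1 * np.sqrt(n1)) ** 2
    s2sq = (sem2 * np.sqrt(n2)) ** 2
    df = n1 + n2 - 2
    sp2 = ((n1 - 1) * s1sq + (n2 - 1) * s2sq) / df
    se = np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    t = (mean1 - mean2) / se
    p = 2.0 * sps.t.sf(abs(t), df)
    return StatResult(test_name="student_t_summary", statistic=float(t),
                      df=(float(df),), p_value=float(p))


def multi_group_test(df: pd.DataFrame, value: str = "value",
                     between: str = "genotype", within: str = "frequency_hz",
                     subject: str = "larva_id",
                     route: str = PARAMETRIC) -> StatResult:
    """Genotype x stimulation-frequency comparison.

    With more than one within-subject (frequency) level, fits a
    mixed-effects repeated-measures model: fixed effects
    ``between * within`` with a random intercept per subject (larva),
    estimated by REML; genotype and frequency main effects and their
    interaction are Wald chi-square tests on the fixed-effect groups.
    Unbalanced designs and missing cells are tolerated; a subject observed
    at a single frequency level triggers a warning but is retained.

    With a single within level the design collapses to a one-way
    between-subject comparison (ANOVA F, equal to t**2 for two groups), or
    Kruskal-Wallis on the non-parametric route.
    """
    df = df.copy()
    levels_within = df[within].unique()
    groups_between = df[between].unique()

    if len(levels_within) <= 1:
        samples = [df.loc[df[between] == g, value].to_numpy()
                   for g in groups_between]
        summaries = [group_summary(s, str(g)) for s, g in zip(samples, groups_between)]
        if route == NONPARAMETRIC:
            res = sps.kruskal(*samples)
            return StatResult(test_name="kruskal_wallis",
                              statistic=float(res.statistic),
                              df=(float(len(samples) - 1),),
                              p_value=float(res.pvalue), groups=summaries)
        f, p = sps.f_oneway(*samples)
        df1 = len(samples) - 1
        df2 = sum(len(s) for s in samples) - len(samples)
        return StatResult(test_name="one_way_anova", statistic=float(f),
                          df=(float(df1), float(df2)), p_value=float(p),
                          groups=summaries)

    counts = df.groupby(subject)[within].nunique()
    lonely = counts[counts < 2]
    if len(lonely):
        warnings.warn(
            f"{len(lonely)} subject(s) observed at a single {within} level; "
            "retained via the mixed model", stacklevel=2)

    # sum-to-zero contrasts so each first-order coefficient group is the
    # factor's main effect averaged over the other factor's levels
    formula = f"{value} ~ C({between}, Sum) * C({within}, Sum)"
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = smf.mixedlm(formula, df, groups=df[subject])
        fit = model.fit(reml=True)

    names = list(fit.fe_params.index)
    k = len(fit.params)  # fixed effects + variance components

    def term_p(select) -> tuple:
        rows = [i for i, nm in enumerate(names) if select(nm)]
        contrast = np.zeros((len(rows), k))
        for r, i in enumerate(rows):
            contrast[r, i] = 1.0
        wt = fit.wald_test(contrast, scalar=False)
        return float(np.squeeze(wt.statistic)), float(wt.pvalue), len(rows)

    b_tag, w_tag = f"C({between}, Sum)[", f"C({within}, Sum)["
    chi2_b, p_b, df_b = term_p(lambda nm: b_tag in nm and ":" not in nm)
    chi2_w, p_w, df_w = term_p(lambda nm: w_tag in nm and ":" not in nm)
    chi2_i, p_i, df_i = term_p(lambda nm: ":" in nm)

    summaries = [group_summary(df.loc[df[between] == g, value].to_numpy(), str(g))
                 for g in groups_between]
    return StatResult(
        test_name="mixed_effects_rm_anova", statistic=chi2_b, df=(float(df_b),),
        p_value=p_b, groups=summaries,
        extra={"between_effect": {"chi2": chi2_b, "df": df_b, "p": p_b},
               "within_effect": {"chi2": chi2_w, "df": df_w, "p": p_w},
               "interaction": {"chi2": chi2_i, "df": df_i, "p": p_i}})


def posthoc(values: Sequence[float], labels: Sequence, method: str = "tukey",
            control_label=None, alpha: float = 0.05) -> list:
    """All-pairs (Tukey HSD) or each-vs-control (Dunnett) adjusted p-values.

    Returns a list of ``(comparison, adjusted_p)`` tuples, where comparison
    is ``"a vs b"``.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    uniq = list(pd.unique(labels))
    if method == "tukey":
        res = pairwise_tukeyhsd(values, labels, alpha=alpha)
        out = []
        for row in res.summary().data[1:]:
            out.append((f"{row[0]} vs {row[1]}", float(row[3])))
        return out
    if method == "dunnett":
        if control_label is None:
            raise ValueError("Dunnett's test requires a control_label")
        if control_label not in uniq:
            raise ValueError(f"control label {control_label!r} not found")
        others = [u for u in uniq if u != control_label]
        samples = [values[labels == u] for u in others]
        control = values[labels == control_label]
        res = sps.dunnett(*samples, control=control)
        return [(f"{u} vs {control_label}", float(p))
                for u, p in zip(others, res.pvalue)]
    raise ValueError(f"unknown post-hoc method {method!r}; use 'tukey' or 'dunnett'")


def compare_groups(df: pd.DataFrame, value: str = "value",
                   group: str = "genotype", alpha: float = 0.05) -> StatResult:
    """Gate-then-test convenience for independent groups.

    Applies the normality gate, then Student's t / Mann-Whitney U for two
    groups or one-way ANOVA / Kruskal-Wallis for more; attaches the gate
    outcome to the result.
    """
    labels = list(pd.unique(df[group]))
    samples = [df.loc[df[group] == g, value].to_numpy() for g in labels]
    gate = normality_gate(samples, alpha=alpha)
    if len(samples) == 2:
        res = two_group_test(samples[0], samples[1], gate["route"],
                             labels=(str(labels[0]), str(labels[1])))
    else:
        tidy = df.rename(columns={group: "genotype", value: "value"})
        tidy["frequency_hz"] = 0.0
        res = multi_group_test(tidy, value="value", route=gate["route"])
    res.extra["gate"] = gate
    return res
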