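"""Behavioral trial filtering, binding scores, and group-level statistics.

The prime-probe (S1-S2) task crosses response relation (repeat/alternate)
with feature relation (repeat/alternate), giving the four key conditions
RRFR, RRFA, RAFR, RAFA.  The binding score

    ((RRFA - RRFR) + (RAFR - RAFA))

sums the feature-repetition benefit under response repetition and response
alternation; a positive score indicates partial-repetition costs, i.e. that
an event file bound at S1 was retrieved at S2.  The score applies identically
to mean reaction times (ms) and to error rates (percentage points).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import scipy.stats

from .epochs import CONDITIONS

PARTIAL_CONDITIONS = frozenset({"RRFA", "RAFR"})

__all__ = [
    "PARTIAL_CONDITIONS",
    "filter_trials",
    "binding_score",
    "participant_binding",
    "one_sample_t",
    "welch_t",
    "chi2_2x2",
    "mixed_anova_2x2x2",
]


def filter_trials(
    table: pd.DataFrame,
    rt_floor_ms: float = 200.0,
    fence_factor: float = 1.5,
    min_trials: int = 4,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-participant trial exclusion for the S2 analysis.

    Excludes trials with incorrect or missed S1 responses, S2 reaction times
    below ``rt_floor_ms``, and S2 reaction times above the participant's
    Tukey upper fence Q3 + ``fence_factor`` * IQR (quartiles by linear
    interpolation, computed on that participant's RT2 after the first two
    filters).  S2-incorrect trials are retained (they feed the error-rate
    analysis).  Participants with fewer than ``min_trials`` trials after the
    floor filters are flagged and their fence is skipped.

    Returns the filtered table and a per-participant report.
    """
    if table.empty:
        raise ValueError("empty trial table")
    out = []
    rows = []
    for pid, sub in table.groupby("participant", sort=False):
        n0 = len(sub)
        sub = sub[sub["s1_correct"].astype(bool)]
        sub = sub[np.isfinite(sub["rt2"]) & (sub["rt2"] >= rt_floor_ms)]
        fence = np.nan
        flagged = len(sub) < min_trials
        if not flagged and len(sub):
            q1, q3 = np.percentile(sub["rt2"], [25, 75])
            fence = q3 + fence_factor * (q3 - q1)
            sub = sub[sub["rt2"] <= fence]
        out.append(sub)
        rows.append(
            {
                "participant": pid,
                "n_input": n0,
                "n_retained": len(sub),
                "fence_ms": fence,
                "flagged": flagged,
            }
        )
    return pd.concat(out, ignore_index=True), pd.DataFrame(rows)


def binding_score(cond_means) -> float:
    """((RRFA - RRFR) + (RAFR - RAFA)) from a mapping of condition means."""
    try:
        return float(
            (cond_means["RRFA"] - cond_means["RRFR"])
            + (cond_means["RAFR"] - cond_means["RAFA"])
        )
    except KeyError as err:
        raise ValueError(f"missing condition mean: {err}") from None


def participant_binding(table: pd.DataFrame) -> pd.DataFrame:
    """Per-participant condition means, error rates, and binding scores.

    RT means use S2-correct trials only; error rates (percent) use all
    retained trials.  Returns one row per participant with columns
    ``rt_<cond>``, ``err_<cond>``, ``rt_binding`` (ms), ``err_binding``
    (percentage points), and ``group``.
    """
    rows = []
    for pid, sub in table.groupby("participant", sort=False):
        row = {"participant": pid}
        if "group" in sub:
            row["group"] = sub["group"].iloc[0]
        rt_means, err_rates = {}, {}
        for cond in CONDITIONS:
            cs = sub[sub["condition"] == cond]
            correct = cs[cs["s2_correct"].astype(bool)]
            rt_means[cond] = correct["rt2"].mean() if len(correct) else np.nan
            err_rates[cond] = 100.0 * (1.0 - cs["s2_correct"].mean()) if len(cs) else np.nan
            row[f"rt_{cond}"] = rt_means[cond]
            row[f"err_{cond}"] = err_rates[cond]
        row["rt_binding"] = (
            binding_score(rt_means) if np.isfinite(list(rt_means.values())).all() else np.nan
        )
        row["err_binding"] = (
            binding_score(err_rates) if np.isfinite(list(err_rates.values())).all() else np.nan
        )
        rows.append(row)
    return pd.DataFrame(rows)


def one_sample_t(mean: float, sd: float, n: int) -> tuple[float, int, float]:
    """One-sample t against zero from summary statistics.

    Returns (t, df, dz) with t = mean / (sd / sqrt(n)), df = n - 1 and the
    standardized effect dz = mean / sd.
    """
    if n < 2:
        raise ValueError("need n >= 2")
    if sd <= 0:
        raise ValueError("sd must be positive")
    t = mean / (sd / np.sqrt(n))
    return float(t), int(n - 1), float(mean / sd)


def one_sample_t_data(x) -> tuple[float, int, float, float]:
    """One-sample t from a data vector; returns (t, df, dz, p)."""
    x = np.asarray(x, dtype=float)
    x = x[np.isfinite(x)]
    t, df, dz = one_sample_t(x.mean(), x.std(ddof=1), x.size)
    p = 2.0 * scipy.stats.t.sf(abs(t), df)
    return t, df, dz, float(p)


def welch_t(m1, s1, n1, m2, s2, n2) -> tuple[float, float, float]:
    """Welch two-sample t with Satterthwaite df; returns (t, df, p)."""
    if n1 < 2 or n2 < 2:
        raise ValueError("need n >= 2 in both groups")
    v1, v2 = s1**2 / n1, s2**2 / n2
    if v1 + v2 <= 0:
        raise ValueError("both group variances are zero")
    t = (m1 - m2) / np.sqrt(v1 + v2)
    df = (v1 + v2) ** 2 / (v1**2 / (n1 - 1) + v2**2 / (n2 - 1))
    p = 2.0 * scipy.stats.t.sf(abs(t), df)
    return float(t), float(df), float(p)


def chi2_2x2(a: int, b: int, c: int, d: int, continuity: bool = True) -> tuple[float, float]:
    """Chi-squared test of independence for a 2x2 table [[a, b], [c, d]].

    With ``continuity`` the Yates-corrected statistic
    N(|ad - bc| - N/2)^2 / ((a+b)(c+d)(a+c)(b+d)) is used (floored at zero);
    otherwise the uncorrected Pearson form.  Returns (chi2, p) with 1 df.
    """
    cells = np.array([a, b, c, d], dtype=float)
    if np.any(cells < 0) or np.any(cells != np.round(cells)):
        raise ValueError("cell counts must be nonnegative integers")
    n = cells.sum()
    margins = np.array([a + b, c + d, a + c, b + d], dtype=float)
    if np.any(margins == 0):
        raise ValueError("all table margins must be positive")
    det = abs(a * d - b * c)
    if continuity:
        det = max(det - n / 2.0, 0.0)
    chi2 = n * det**2 / margins.prod()
    return float(chi2), float(scipy.stats.chi2.sf(chi2, 1))


# within-cell contrast order: (rep, FR), (rep, FA), (alt, FR), (alt, FA);
# orthonormal rows (sum of squared coefficients = 1) so stratum sums of
# squares land on the classical scale
_CELLS = ["RRFR", "RRFA", "RAFR", "RAFA"]
_CONTRASTS = {
    "between": np.array([1, 1, 1, 1]) / 2.0,
    "response": np.array([1, 1, -1, -1]) / 2.0,
    "feature": np.array([1, -1, 1, -1]) / 2.0,
    "response:feature": np.array([1, -1, -1, 1]) / 2.0,
}


def mixed_anova_2x2x2(cell_means: pd.DataFrame) -> pd.DataFrame:
    """Mixed 2 (group) x 2 (response relation) x 2 (feature relation) ANOVA.

    ``cell_means`` holds one row per participant with columns ``group`` and
    the four condition means RRFR/RRFA/RAFR/RAFA.  The within-subject design
    is balanced by construction, so each within effect is evaluated on an
    orthonormal per-subject contrast; the group factor may be unbalanced and
    main effects use unweighted (Type III) marginal means.  Generalized
    eta-squared divides each effect's SS by that SS plus all subject-related
    error SS (Bakeman/Olejnik convention for manipulated factors).

    Returns a table of effects with SS, df, F, p, and ges.
    """
    df = cell_means.dropna(subset=_CELLS)
    n_dropped = len(cell_means) - len(df)
    if n_dropped:
        import warnings

        warnings.warn(f"excluded {n_dropped} participant(s) with missing cells")
    groups = sorted(df["group"].unique())
    if len(groups) != 2:
        raise ValueError("exactly two groups required")
    y = df[_CELLS].to_numpy(float)
    g = (df["group"] == groups[1]).to_numpy()
    n1, n2 = int((~g).sum()), int(g.sum())
    if min(n1, n2) < 2:
        raise ValueError("need at least two participants per group")
    n_tot = n1 + n2
    inv_n = 1.0 / n1 + 1.0 / n2

    strata = {}
    for name, w in _CONTRASTS.items():
        c = y @ w
        cbar1, cbar2 = c[~g].mean(), c[g].mean()
        grand = 0.5 * (cbar1 + cbar2)  # unweighted (Type III) marginal mean
        ss_main = 4.0 * grand**2 / inv_n
        ss_group = (cbar1 - cbar2) ** 2 / inv_n
        resid = c.copy()
        resid[~g] -= cbar1
        resid[g] -= cbar2
        ss_err = float(resid @ resid)
        strata[name] = (ss_main, ss_group, ss_err)

    df_err = n_tot - 2
    all_err = sum(s[2] for s in strata.values())
    rows = []

    def add(effect, ss, ss_err):
        ms_err = ss_err / df_err
        f = ss / ms_err if ms_err > 0 else 0.0
        p = float(scipy.stats.f.sf(f, 1, df_err)) if ms_err > 0 else np.nan
        rows.append(
            {
                "effect": effect,
                "ss": ss,
                "df": 1,
                "df_error": df_err,
                "ss_error": ss_err,
                "F": f,
                "p": p,
                "ges": ss / (ss + all_err) if (ss + all_err) > 0 else 0.0,
            }
        )

    add("group", strata["between"][1], strata["between"][2])
    for name in ("response", "feature", "response:feature"):
        ss_main, ss_group, ss_err = strata[name]
        add(name, ss_main, ss_err)
        add(f"{name}:group", ss_group, ss_err)
    return pd.DataFrame(rows)
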