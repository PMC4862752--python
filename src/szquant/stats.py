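"""Group statistics used on pipeline outputs.

Two-way mixed (drug x time) ANOVA with time as the repeated variable, ANCOVA
with KA dose as a covariate, Bonferroni-corrected post-hoc t tests, Pearson
chi-square on stage-attainment proportions, Cohen's d, and Newman-Keuls
(SNK) pairwise comparisons between behaviors.

Mixed ANOVA and ANCOVA are delegated to pingouin and reshaped into plain
dicts keyed by effect; sphericity corrections are not applied (with two
within-subject levels they are moot, and reported degrees of freedom follow
the classical uncorrected form). Post-hoc t tests default to pooled variance.
Newman-Keuls is implemented here directly on the studentized range
distribution (scipy), with the harmonic mean n for unbalanced groups.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sst

__all__ = [
    "mixed_anova",
    "ancova",
    "posthoc_ttests",
    "chi_square",
    "cohens_d",
    "newman_keuls",
]


def _effect(row: pd.Series) -> dict:
    return {
        "F": float(row["F"]),
        "df1": float(row["DF1"]) if "DF1" in row else float(row["DF"]),
        "df2": float(row["DF2"]) if "DF2" in row else None,
        "p": float(row["p_unc"]),
    }


def mixed_anova(
    data: pd.DataFrame,
    dv: str = "response",
    within: str = "time",
    between: str = "group",
    subject: str = "subject",
) -> dict:
    """Two-way mixed-design ANOVA (between x repeated).

    Returns ``{between: {...}, within: {...}, "interaction": {...}}`` with F,
    numerator/denominator df and the uncorrected p per effect.
    """
    counts = data.groupby([subject])[within].nunique()
    if counts.nunique() != 1:
        raise ValueError("incomplete within-factor data: unequal repeats per subject")
    if data.groupby(between)[subject].nunique().min() < 2:
        raise ValueError("need at least 2 subjects per group")
    import pingouin as pg

    res = pg.mixed_anova(
        data=data, dv=dv, within=within, between=between, subject=subject, correction=False
    ).set_index("Source")
    return {
        between: _effect(res.loc[between]),
        within: _effect(res.loc[within]),
        "interaction": _effect(res.loc["Interaction"]),
    }


def ancova(
    data: pd.DataFrame,
    dv: str = "response",
    between: str = "group",
    covariate: str = "dose",
) -> dict:
    """One-way ANCOVA: group effect adjusted for a continuous covariate."""
    if data[covariate].nunique() < 2:
        raise ValueError("covariate does not vary")
    # A covariate constant within groups but varying between them is
    # perfectly collinear with the group factor.
    if data.groupby(between)[covariate].nunique().max() == 1:
        raise ValueError("covariate is collinear with the group factor")
    import pingouin as pg

    res = pg.ancova(data=data, dv=dv, between=between, covar=covariate).set_index("Source")
    n = len(data)
    k = data[between].nunique()
    out = {}
    for name, key in ((between, between), (covariate, covariate)):
        row = res.loc[key]
        out[name] = {
            "F": float(row["F"]),
            "df1": float(row["DF"]),
            "df2": float(n - k - 1),
            "p": float(row["p_unc"]),
        }
    return out


def posthoc_ttests(
    pairs: Sequence[tuple[np.ndarray, np.ndarray]],
    equal_var: bool = True,
    correction: str = "bonferroni",
) -> list[dict]:
    """Unpaired t tests over ``pairs`` with Bonferroni adjustment.

    ``p_adj = min(1, k * p)`` where k is the number of comparisons.
    """
    if correction not in ("bonferroni", "none"):
        raise ValueError("correction must be 'bonferroni' or 'none'")
    k = len(pairs)
    if k < 1:
        raise ValueError("need at least one comparison")
    out = []
    for a, b in pairs:
        a = np.asarray(a, dtype=float)
        b = np.asarray(b, dtype=float)
        t, p = sst.ttest_ind(a, b, equal_var=equal_var)
        df = a.size + b.size - 2 if equal_var else None
        p_adj = min(1.0, k * p) if correction == "bonferroni" else p
        out.append({"t": float(t), "df": df, "p_raw": float(p), "p_adj": float(p_adj)})
    return out


def chi_square(table: np.ndarray, correction: bool = False) -> dict:
    """Pearson chi-square on an r x c count table (no continuity correction
    by default)."""
    table = np.asarray(table, dtype=float)
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise ValueError("chi-square undefined with a zero marginal")
    chi2, p, df, _ = sst.chi2_contingency(table, correction=correction)
    return {"chi2": float(chi2), "df": int(df), "p": float(p)}


def cohens_d(a: Sequence[float], b: Sequence[float]) -> float:
    """Cohen's d with the pooled standard deviation."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("need at least 2 observations per group")
    sp2 = ((a.size - 1) * a.var(ddof=1) + (b.size - 1) * b.var(ddof=1)) / (a.size + b.size - 2)
    if sp2 == 0:
        raise ValueError("zero pooled standard deviation")
    return float((a.mean() - b.mean()) / np.sqrt(sp2))


def newman_keuls(
    groups: Sequence[np.ndarray],
    labels: Sequence[str] | None = None,
    alpha: float = 0.05,
) -> list[dict]:
    """Student-Newman-Keuls stepwise pairwise comparisons on a one-way layout.

    Means are ordered; each pair is tested against the studentized-range
    quantile for its span p (the number of means it straddles) at the one-way
    ANOVA error df. Following the standard stepwise rule, a pair nested
    inside a non-significant stretch is declared non-significant without
    testing. Unequal group sizes use the harmonic mean n.

    Returns one dict per pair: labels, means, q, critical q, span, and the
    rejection decision.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    k = len(groups)
    if k < 3:
        raise ValueError("Newman-Keuls needs at least 3 groups")
    labels = list(labels) if labels is not None else [f"g{i}" for i in range(k)]
    ns = np.array([g.size for g in groups])
    means = np.array([g.mean() for g in groups])
    df_err = int(ns.sum() - k)
    mse = sum((g.size - 1) * g.var(ddof=1) for g in groups) / df_err
    n_h = k / np.sum(1.0 / ns)  # harmonic mean n
    se = np.sqrt(mse / n_h)

    order = np.argsort(means)
    m_sorted = means[order]
    # blocked[i][j] True means the stretch i..j is inside a retained (non-
    # significant) range and must not be declared significant.
    results = {}
    nonsig_ranges: list[tuple[int, int]] = []
    for span in range(k, 1, -1):
        q_crit = float(sst.studentized_range.ppf(1 - alpha, span, df_err))
        for i in range(0, k - span + 1):
            j = i + span - 1
            if (i, j) in results:
                continue
            if any(lo <= i and j <= hi for lo, hi in nonsig_ranges):
                results[(i, j)] = (np.nan, q_crit, False, True)
                continue
            if se == 0:
                diff = m_sorted[j] - m_sorted[i]
                reject = diff > 0
                results[(i, j)] = (np.inf if reject else 0.0, q_crit, reject, False)
                if not reject:
                    nonsig_ranges.append((i, j))
                continue
            q = float((m_sorted[j] - m_sorted[i]) / se)
            reject = q > q_crit
            results[(i, j)] = (q, q_crit, reject, False)
            if not reject:
                nonsig_ranges.append((i, j))
    out = []
    for (i, j), (q, q_crit, reject, blocked) in sorted(results.items()):
        out.append(
            {
                "group_low": labels[order[i]],
                "group_high": labels[order[j]],
                "mean_low": float(m_sorted[i]),
                "mean_high": float(m_sorted[j]),
                "span": j - i + 1,
                "q": q,
                "q_crit": q_crit,
                "reject": bool(reject),
                "blocked": bool(blocked),
            }
        )
    return out
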