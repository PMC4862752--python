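"""Independent brute-force reference implementations used only by tests.

Each oracle restates a definition in the most literal way possible (explicit
scans over seconds or bins), deliberately sharing no code with the package.
"""

from __future__ import annotations

import numpy as np


def detect_runs_oracle(values, bin_width_s, threshold, min_duration_s, start_bin=0):
    """Literal scan for maximal supra-threshold runs of sufficient length."""
    events = []
    n = len(values)
    i = start_bin
    while i < n:
        if values[i] >= threshold:
            j = i
            while j < n and values[j] >= threshold:
                j += 1
            if (j - i) * bin_width_s >= min_duration_s:
                events.append((i * bin_width_s, j * bin_width_s))
            i = j
        else:
            i += 1
    return events


def time_in_seizure_oracle(intervals, bin_width_s, duration_s):
    """Per-second membership counting (resolution 0.01 s for sub-second
    edges handled by the caller using integer-second fixtures)."""
    n_bins = int(np.ceil(duration_s / bin_width_s - 1e-9))
    covered = np.zeros(int(duration_s), dtype=bool)
    for on, off in intervals:
        covered[int(on) : min(int(off), int(duration_s))] = True
    out = np.zeros(n_bins)
    for b in range(n_bins):
        seg = covered[int(b * bin_width_s) : int((b + 1) * bin_width_s)]
        out[b] = 100.0 * seg.sum() / bin_width_s
    return out


def behavioral_se_oracle(conv, onset_run_s=30, max_gap_s=120):
    """Second-by-second simulation of the behavioral SE definition."""
    episodes = []
    in_se = False
    onset = None
    last_conv = None
    run = 0
    for t in range(len(conv)):
        if conv[t]:
            run += 1
            last_conv = t
            if not in_se and run >= onset_run_s:
                in_se = True
                onset = t - run + 1
        else:
            run = 0
            if in_se and t - last_conv > max_gap_s:
                episodes.append((onset, last_conv + 1))
                in_se = False
    if in_se:
        episodes.append((onset, last_conv + 1))
    return episodes


def electrographic_se_oracle(values, bin_width_s, onset_x=10.0, onset_run_s=30.0,
                             offset_x=3.0, offset_run_s=30.0):
    """Bin-by-bin simulation of the amplitude hysteresis machine, written as
    forward searches rather than counters."""
    n_on = int(round(onset_run_s / bin_width_s))
    n_off = int(round(offset_run_s / bin_width_s))
    n = len(values)
    episodes = []
    i = 0
    while i <= n - n_on:
        if all(values[i + k] >= onset_x for k in range(n_on)):
            onset = i
            # search for the closing quiet run
            j = onset + n_on
            close = None
            while j <= n - n_off:
                if all(values[j + k] < offset_x for k in range(n_off)):
                    close = j
                    break
                j += 1
            if close is None:
                episodes.append((onset * bin_width_s, n * bin_width_s))
                return episodes
            episodes.append((onset * bin_width_s, close * bin_width_s))
            i = close + n_off
        else:
            i += 1
    return episodes


def pearson_oracle(x, y):
    """Textbook Pearson formula."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    xm, ym = x - x.mean(), y - y.mean()
    return float((xm * ym).sum() / np.sqrt((xm**2).sum() * (ym**2).sum()))


def mixed_anova_oracle(y, group, time, subject):
    """Balanced two-way mixed ANOVA from the classical sums-of-squares
    decomposition (groups between, time within)."""
    import pandas as pd

    df = pd.DataFrame({"y": y, "g": group, "t": time, "s": subject})
    a = df["g"].nunique()
    b = df["t"].nunique()
    n = df["s"].nunique() // a
    grand = df["y"].mean()
    subj_means = df.groupby("s")["y"].mean()
    group_means = df.groupby("g")["y"].mean()
    time_means = df.groupby("t")["y"].mean()
    cell_means = df.groupby(["g", "t"])["y"].mean()
    ss_between_subj = b * ((subj_means - grand) ** 2).sum()
    ss_group = n * b * ((group_means - grand) ** 2).sum()
    ss_subj_within = ss_between_subj - ss_group
    ss_time = a * n * ((time_means - grand) ** 2).sum()
    ss_cells = n * ((cell_means - grand) ** 2).sum()
    ss_inter = ss_cells - ss_group - ss_time
    ss_total = ((df["y"] - grand) ** 2).sum()
    ss_err = ss_total - ss_between_subj - ss_time - ss_inter
    df_g, df_sw = a - 1, a * (n - 1)
    df_t = b - 1
    df_i = (a - 1) * (b - 1)
    df_e = a * (n - 1) * (b - 1)
    return {
        "group": (ss_group / df_g) / (ss_subj_within / df_sw),
        "time": (ss_time / df_t) / (ss_err / df_e),
        "interaction": (ss_inter / df_i) / (ss_err / df_e),
        "df": {"group": (df_g, df_sw), "time": (df_t, df_e), "interaction": (df_i, df_e)},
    }


def ancova_oracle(y, group, covariate):
    """Two-group ANCOVA F for the group effect via nested OLS models."""
    y = np.asarray(y, float)
    x = np.asarray(covariate, float)
    levels = sorted(set(group))
    k = len(levels)
    n = y.size
    dummies = np.column_stack([[1.0 if g == lv else 0.0 for g in group] for lv in levels[1:]])
    full = np.column_stack([np.ones(n), x, dummies])
    red = np.column_stack([np.ones(n), x])

    def sse(X):
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        r = y - X @ beta
        return float(r @ r)

    sse_f, sse_r = sse(full), sse(red)
    df1, df2 = k - 1, n - k - 1
    return ((sse_r - sse_f) / df1) / (sse_f / df2), (df1, df2)
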