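"""Microdialysis estradiol (E2) quantification.

Covers the analytic side of hippocampal microdialysis: four-parameter
logistic (4PL) calibration of the enzyme immunoassay, probe recovery and the
recovery-corrected tissue estimate, pg/ml <-> pM unit conversion,
percent-of-baseline time courses, assay coefficients of variation, and
stratification of animals into seizure-severity classes.

Dialysate is collected in 30 min samples; concentrations are in pg/ml as
measured in dialysate. The 4PL calibration uses six E2 standards obtained by
2.5-fold serial dilution from 200 down to 2.048 pg/ml.

The molar mass of 17beta-estradiol (272.38 g/mol) converts pg/ml to pM:
``pM = pg/ml / 272.38 * 1000``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

__all__ = [
    "ESTRADIOL_MW_G_PER_MOL",
    "DialysisSample",
    "StandardCurve",
    "RecoveryEstimate",
    "dilution_series",
    "probe_recovery",
    "fit_4pl",
    "invert_4pl",
    "pgml_to_pm",
    "tissue_estimate",
    "percent_baseline",
    "classify_severity",
    "assay_cv",
]

ESTRADIOL_MW_G_PER_MOL = 272.38


@dataclass(frozen=True)
class DialysisSample:
    """One 30 min dialysate sample."""

    t_start_min: float
    t_end_min: float
    conc_pg_ml: float
    phase: str = "baseline"  # baseline | post_KA | retrodialysis

    def __post_init__(self) -> None:
        if abs((self.t_end_min - self.t_start_min) - 30.0) > 1e-6:
            raise ValueError("dialysis samples span 30 min")
        if self.conc_pg_ml < 0:
            raise ValueError("concentration must be non-negative")


@dataclass(frozen=True)
class StandardCurve:
    """4PL calibration ``y = d + (a - d) / (1 + (x / c)**b)``.

    ``a`` is the response at zero concentration, ``d`` the response at
    infinite concentration, ``c`` the midpoint concentration (EC50) and ``b``
    the slope. For a competitive immunoassay the response decreases with
    concentration (a > d).
    """

    a: float
    b: float
    c: float
    d: float

    def predict(self, conc: np.ndarray | float) -> np.ndarray | float:
        x = np.asarray(conc, dtype=float)
        return self.d + (self.a - self.d) / (1.0 + (x / self.c) ** self.b)


@dataclass(frozen=True)
class RecoveryEstimate:
    recovery_fraction: float
    bath_conc_ng_ml: float
    sample_index: int | None = None

    @property
    def percent(self) -> float:
        return self.recovery_fraction * 100.0


def dilution_series(top: float = 200.0, factor: float = 2.5, n: int = 6) -> np.ndarray:
    """Serial dilution, e.g. 200, 80, 32, 12.8, 5.12, 2.048 pg/ml."""
    if top <= 0 or factor <= 1 or n < 1:
        raise ValueError("need top > 0, factor > 1, n >= 1")
    return top / factor ** np.arange(n)


def probe_recovery(
    dialysate_conc: float, bath_conc: float, sample_index: int | None = None
) -> RecoveryEstimate:
    """Fraction of bath concentration recovered in dialysate."""
    if bath_conc <= 0:
        raise ValueError("bath concentration must be positive")
    if dialysate_conc < 0:
        raise ValueError("dialysate concentration must be non-negative")
    return RecoveryEstimate(dialysate_conc / bath_conc, bath_conc, sample_index)


def _mean_by_conc(conc: np.ndarray, resp: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    xs = np.unique(conc)
    return xs, np.array([resp[conc == x].mean() for x in xs])


def fit_4pl(conc: Sequence[float], response: Sequence[float]) -> StandardCurve:
    """Least-squares 4PL fit of assay response vs. concentration.

    Requires at least 5 distinct positive concentrations with monotone mean
    responses. Internally parameterized in log(c) with b > 0, which pins the
    curve direction to the data; initial values come from the extreme
    responses, the geometric-mean concentration, and a logit-vs-log-x slope.
    """
    conc = np.asarray(conc, dtype=float)
    response = np.asarray(response, dtype=float)
    if conc.shape != response.shape:
        raise ValueError("conc and response must have the same length")
    if np.any(conc <= 0):
        raise ValueError("concentrations must be positive")
    xs, ys = _mean_by_conc(conc, response)
    if xs.size < 5:
        raise ValueError("need at least 5 distinct concentrations")
    diffs = np.diff(ys)
    if not (np.all(diffs < 0) or np.all(diffs > 0)):
        raise ValueError("mean responses are not monotone in concentration")

    a0, d0 = ys[0], ys[-1]  # response at lowest / highest concentration
    span = a0 - d0
    pad = 0.05 * abs(span)
    inner = (np.abs(ys - a0) > pad) & (np.abs(ys - d0) > pad)
    if inner.sum() >= 2:
        z = np.log((a0 + np.sign(span) * pad - ys[inner]) / (ys[inner] - d0 + np.sign(span) * pad))
        b0 = max(np.polyfit(np.log(xs[inner]), z, 1)[0], 0.1)
    else:
        b0 = 1.0
    c0 = float(np.exp(np.mean(np.log(xs))))

    def resid(theta):
        a, log_b, log_c, d = theta
        return d + (a - d) / (1.0 + (conc / np.exp(log_c)) ** np.exp(log_b)) - response

    sol = least_squares(
        resid,
        x0=[a0, np.log(b0), np.log(c0), d0],
        method="lm",
        xtol=1e-15,
        ftol=1e-15,
        gtol=1e-15,
        max_nfev=20000,
    )
    a, log_b, log_c, d = sol.x
    return StandardCurve(a=float(a), b=float(np.exp(log_b)), c=float(np.exp(log_c)), d=float(d))


def invert_4pl(curve: StandardCurve, response: float) -> float:
    """Concentration producing ``response``; responses at or beyond the
    asymptotes are out of range."""
    lo, hi = sorted((curve.a, curve.d))
    if not (lo < response < hi):
        raise ValueError(
            f"response {response} outside the open asymptote range ({lo}, {hi})"
        )
    return float(curve.c * ((curve.a - curve.d) / (response - curve.d) - 1.0) ** (1.0 / curve.b))


def pgml_to_pm(conc_pg_ml: float, molar_mass_g_per_mol: float = ESTRADIOL_MW_G_PER_MOL) -> float:
    """pg/ml -> pM. Linear: f(alpha * x) = alpha * f(x)."""
    if conc_pg_ml < 0:
        raise ValueError("concentration must be non-negative")
    return conc_pg_ml / molar_mass_g_per_mol * 1000.0


def tissue_estimate(dialysate_conc: float, recovery_fraction: float) -> float:
    """Recovery-corrected tissue concentration (dialysate / recovery).

    The in vitro recovery was measured with no carrier protein in the bath
    and therefore reflects *maximum* recovery; the corrected value is a lower
    bound on tissue concentration.
    """
    if not 0 < recovery_fraction <= 1:
        raise ValueError("recovery fraction must be in (0, 1]")
    return dialysate_conc / recovery_fraction


def percent_baseline(samples: Sequence[DialysisSample]) -> np.ndarray:
    """Each sample as percent of the mean of this subject's baseline samples.

    Ratios are formed per subject *before* any group averaging, so a cohort
    mean of this output is a mean of within-subject ratios.
    """
    base = [s.conc_pg_ml for s in samples if s.phase == "baseline"]
    if not base:
        raise ValueError("no baseline-phase samples")
    m = float(np.mean(base))
    if m <= 0:
        raise ValueError("zero baseline mean")
    return np.array([s.conc_pg_ml / m * 100.0 for s in samples])


def classify_severity(trace, horizon_s: float = 7200.0) -> str:
    """Severity class from total time in Racine 1-5 behaviors over 2 h.

    < 30 min -> mild; 30-90 min (closed interval) -> moderate; > 90 min ->
    severe.
    """
    from .behavior import BehaviorTrace, CATEGORIES  # local import avoids cycle at module load

    if not isinstance(trace, BehaviorTrace):
        raise TypeError("expected a BehaviorTrace")
    if trace.n_seconds < horizon_s:
        raise ValueError(f"trace shorter than the {horizon_s:g} s scoring horizon")
    member = np.isin(trace.codes[: int(horizon_s)], list(CATEGORIES["R1_5"]))
    total_min = member.sum() / 60.0
    if total_min < 30.0:
        return "mild"
    if total_min <= 90.0:
        return "moderate"
    return "severe"


def assay_cv(
    replicates: Mapping[float, Sequence[float]] | pd.DataFrame,
    conc_range: tuple[float, float] | None = None,
) -> dict:
    """Intra-/inter-assay coefficients of variation, percent.

    ``replicates`` is either a mapping {concentration: replicate values}
    (single plate -> intra-assay only) or a long DataFrame with columns
    ``conc``, ``response`` and optionally ``plate``. CV = SD/mean * 100 per
    level (sample SD, ddof=1); the reported figure is the mean CV across
    levels inside ``conc_range``. With a ``plate`` column, intra-assay CV
    pools within-plate CVs and inter-assay CV is computed across plate means.
    """
    if isinstance(replicates, Mapping):
        df = pd.DataFrame(
            [(c, v) for c, vals in replicates.items() for v in vals],
            columns=["conc", "response"],
        )
        df["plate"] = 0
    else:
        df = replicates.copy()
        if "plate" not in df.columns:
            df["plate"] = 0
    if conc_range is not None:
        df = df[(df["conc"] >= conc_range[0]) & (df["conc"] <= conc_range[1])]
    if df.empty:
        raise ValueError("no replicates in range")

    def _cv(v: pd.Series) -> float:
        if v.size < 2:
            raise ValueError("need at least 2 replicates per level")
        return float(v.std(ddof=1) / v.mean() * 100.0)

    intra = df.groupby(["plate", "conc"])["response"].apply(_cv)
    out = {"intra_cv_percent": float(intra.mean()), "inter_cv_percent": None}
    if df["plate"].nunique() > 1:
        plate_means = df.groupby(["conc", "plate"])["response"].mean()
        inter = plate_means.groupby("conc").apply(_cv)
        out["inter_cv_percent"] = float(inter.mean())
    return out
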