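"""Group-comparison statistics on the tidy learning table.

Mirrors the original analysis chain: Shapiro-Wilk normality screening,
two-factor repeated-measures ANOVA (between factor: group; within factor:
time; subject: animal) with Tukey HSD post hoc contrasts over the
group x time cell means, and two-sample / paired t-tests.  Significance
is judged at alpha = 0.05 throughout.

Sphericity handling: the uncorrected within-subject p-values drive the
significance flags; Greenhouse-Geisser corrected p-values are reported
alongside whenever the design allows them.  A failed normality screen is
logged as a warning only — the parametric tests are still run.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import pingouin as pg
from scipy import stats as sps
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from .core import InvalidArgumentError

__all__ = [
    "ALPHA",
    "ComparisonSpec",
    "StatResult",
    "shapiro_wilk",
    "t_test",
    "rm_anova_tukey",
]

log = logging.getLogger(__name__)

ALPHA = 0.05


@dataclass
class ComparisonSpec:
    """Declarative description of one statistical comparison."""

    response: str
    between: str | None = None
    within: str | None = None
    subject: str | None = None
    kind: str = "rm_anova_tukey"  # rm_anova_tukey | t_two_sample | t_paired | shapiro

    def __post_init__(self) -> None:
        if self.kind in ("rm_anova_tukey", "t_paired") and not self.subject:
            raise InvalidArgumentError(f"{self.kind} requires a subject/pairing key")


@dataclass
class StatResult:
    label: str
    statistic: float
    df: float | tuple[float, float] | None
    p: float
    alpha: float = ALPHA

    def __post_init__(self) -> None:
        if not (0.0 <= self.p <= 1.0 or np.isnan(self.p)):
            raise InvalidArgumentError(f"p-value {self.p} outside [0, 1]")

    @property
    def significant(self) -> bool:
        return bool(self.p < self.alpha)


def shapiro_wilk(values, alpha: float = ALPHA) -> StatResult:
    """Shapiro-Wilk test of normality."""
    x = np.asarray(values, dtype=float)
    if x.size < 3 or x.size > 5000:
        raise InvalidArgumentError("Shapiro-Wilk requires 3 <= n <= 5000")
    if np.ptp(x) == 0:
        raise InvalidArgumentError("Shapiro-Wilk is undefined for a constant sample")
    w, p = sps.shapiro(x)
    return StatResult("shapiro_wilk", float(w), float(x.size), float(p), alpha)


def t_test(a, b, paired: bool = False, alpha: float = ALPHA) -> StatResult:
    """Two-sided two-sample or paired t-test.

    A paired test of identical samples has no variability in the
    differences; by convention it reports t = 0, p = 1.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise InvalidArgumentError("each sample needs at least 2 values")
    if paired:
        if a.size != b.size:
            raise InvalidArgumentError("paired samples must have equal length")
        d = a - b
        if np.ptp(d) == 0 and d[0] == 0:
            return StatResult("t_paired", 0.0, float(a.size - 1), 1.0, alpha)
        t, p = sps.ttest_rel(a, b)
        return StatResult("t_paired", float(t), float(a.size - 1), float(p), alpha)
    t, p = sps.ttest_ind(a, b)
    return StatResult("t_two_sample", float(t), float(a.size + b.size - 2), float(p), alpha)


def _complete_cases(
    data: pd.DataFrame, dv: str, within: str, subject: str
) -> pd.DataFrame:
    """Drop subjects missing any within-factor level (with a warning)."""
    data = data.dropna(subset=[dv])
    levels = data[within].nunique()
    counts = data.groupby(subject)[within].nunique()
    keep = counts[counts == levels].index
    dropped = sorted(set(data[subject]) - set(keep))
    if dropped:
        log.warning("dropping subjects with incomplete time series: %s", dropped)
    return data[data[subject].isin(keep)]


def rm_anova_tukey(
    data: pd.DataFrame,
    spec: ComparisonSpec,
    alpha: float = ALPHA,
) -> tuple[pd.DataFrame, pd.DataFrame, list[StatResult]]:
    """Two-factor repeated-measures ANOVA with Tukey HSD post hoc.

    Returns ``(anova, tukey, results)``: the ANOVA table (main effects of
    group and time and their interaction, with uncorrected and, where
    available, Greenhouse-Geisser p-values), the full Tukey table over all
    group x time cell means, and one :class:`StatResult` per ANOVA source
    (flags driven by the uncorrected p).

    Subjects missing a within level are dropped with a logged warning.
    With a single between-group level the model reduces to a one-factor
    repeated-measures ANOVA on time.
    """
    dv, between, within, subject = spec.response, spec.between, spec.within, spec.subject
    if within is None or subject is None:
        raise InvalidArgumentError("rm_anova_tukey needs within and subject columns")
    d = data.copy()
    if d[within].nunique() < 2:
        raise InvalidArgumentError("within factor needs at least 2 levels")
    d = _complete_cases(d, dv, within, subject)
    if d.empty:
        raise InvalidArgumentError("no complete cases")
    n_groups = d[between].nunique() if between is not None else 1
    # the sphericity screen needs more subjects than within levels
    correction = d[subject].nunique() > d[within].nunique()
    if n_groups >= 2:
        aov = pg.mixed_anova(
            data=d, dv=dv, within=within, subject=subject, between=between,
            correction=correction,
        )
    else:
        aov = pg.rm_anova(
            data=d, dv=dv, within=within, subject=subject, correction=correction,
            detailed=True,
        )
        aov = aov[aov["Source"] != "Error"]
    results = []
    for _, row in aov.iterrows():
        df = (float(row["DF1"]), float(row["DF2"])) if "DF1" in row else float(row["DF"])
        results.append(
            StatResult(str(row["Source"]), float(row["F"]), df, float(row["p_unc"]), alpha)
        )
    # Tukey HSD over the group x time cell means
    if n_groups >= 2:
        cells = d[between].astype(str) + "@" + d[within].astype(str)
    else:
        cells = d[within].astype(str)
    tk = pairwise_tukeyhsd(endog=d[dv].to_numpy(), groups=cells.to_numpy(), alpha=alpha)
    tukey = pd.DataFrame(
        tk.summary().data[1:], columns=[str(c) for c in tk.summary().data[0]]
    )
    return aov, tukey, results


def run_comparison(data: pd.DataFrame, spec: ComparisonSpec, alpha: float = ALPHA):
    """Dispatch a :class:`ComparisonSpec` to the matching test."""
    if spec.kind == "shapiro":
        return shapiro_wilk(data[spec.response].dropna(), alpha)
    if spec.kind in ("t_two_sample", "t_paired"):
        if spec.between is None:
            raise InvalidArgumentError("t-tests need a between column")
        levels = sorted(data[spec.between].dropna().unique())
        if len(levels) != 2:
            raise InvalidArgumentError("t-tests need exactly 2 groups")
        if spec.kind == "t_paired":
            wide = data.pivot_table(
                index=spec.subject, columns=spec.between, values=spec.response
            ).dropna()
            return t_test(wide[levels[0]], wide[levels[1]], paired=True, alpha=alpha)
        a = data.loc[data[spec.between] == levels[0], spec.response].dropna()
        b = data.loc[data[spec.between] == levels[1], spec.response].dropna()
        return t_test(a, b, paired=False, alpha=alpha)
    return rm_anova_tukey(data, spec, alpha)
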