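"""Shared statistical machinery.

Paired t-tests with Cohen's d, fixed-effects two-factor ANOVA with
interaction (type-II sums of squares), simple-effect contrasts on the
pooled error term, and Bonferroni correction.  These are the exact
quantities the analysis stages report: F with its df pair, p, partial
eta-squared, and simple-effect mean differences (MD).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "PairedTResult",
    "EffectStats",
    "AnovaResult",
    "SimpleEffect",
    "paired_t",
    "two_way_anova",
    "simple_effects",
    "bonferroni",
]


@dataclass(frozen=True)
class PairedTResult:
    """Paired two-tailed t-test with the standardized effect size."""

    t: float
    df: int
    p: float
    cohen_d: float
    mean_diff: float
    degenerate: bool = False

    def summary(self) -> str:
        flag = "  [degenerate: zero-variance differences]" if self.degenerate else ""
        return (
            f"t({self.df}) = {self.t:.4g}, p = {self.p:.4g}, "
            f"Cohen's d = {self.cohen_d:.4g}, MD = {self.mean_diff:.4g}{flag}"
        )


def paired_t(x, y) -> PairedTResult:
    """Paired sample t-test (two-tailed) of ``x`` against ``y``.

    t = mean(d) / (sd(d)/sqrt(n)) and Cohen's d = mean(d)/sd(d) with
    d = x - y and the sample (ddof=1) standard deviation.  Zero-variance
    differences are degenerate: t is 0 when the mean difference is also 0,
    +/-inf otherwise (documented convention), and the result is flagged.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("paired_t requires two equal-length 1-d samples")
    n = x.size
    if n < 2:
        raise ValueError("paired_t requires n >= 2")
    d = x - y
    md = float(d.mean())
    sd = float(d.std(ddof=1))
    df = n - 1
    if sd == 0.0:
        if md == 0.0:
            return PairedTResult(0.0, df, 1.0, 0.0, 0.0, degenerate=True)
        t = np.inf if md > 0 else -np.inf
        return PairedTResult(float(t), df, 0.0, float(np.sign(md) * np.inf), md, degenerate=True)
    t = md / (sd / np.sqrt(n))
    p = float(2.0 * sps.t.sf(abs(t), df))
    return PairedTResult(float(t), df, p, md / sd, md)


@dataclass(frozen=True)
class EffectStats:
    F: float
    df_num: int
    df_den: int
    p: float
    partial_eta_sq: float
    ss: float


@dataclass
class SimpleEffect:
    """Contrast between two levels of one factor at a fixed level of the other."""

    at_level: object
    level_hi: object
    level_lo: object
    md: float
    t: float
    p: float


@dataclass
class AnovaResult:
    """Two-factor fixed-effects ANOVA with interaction.

    ``effects`` maps effect name (factor A, factor B, "A:B") to
    :class:`EffectStats`; ``cell_means`` is the A x B table of cell means.
    """

    factor_a: str
    factor_b: str
    effects: dict = field(default_factory=dict)
    cell_means: pd.DataFrame | None = None
    ss_error: float = 0.0
    df_error: int = 0
    ms_error: float = 0.0
    cell_counts: pd.DataFrame | None = None
    ss_type: str = "II"

    def summary(self) -> str:
        lines = [f"Two-way ANOVA ({self.factor_a} x {self.factor_b}), type-{self.ss_type} SS"]
        for name, e in self.effects.items():
            lines.append(
                f"  {name}: F({e.df_num}, {e.df_den}) = {e.F:.4g}, "
                f"p = {e.p:.4g}, partial eta^2 = {e.partial_eta_sq:.4g}"
            )
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "factor_a": self.factor_a,
            "factor_b": self.factor_b,
            "ss_type": self.ss_type,
            "effects": {
                k: {
                    "F": e.F,
                    "df": [e.df_num, e.df_den],
                    "p": e.p,
                    "partial_eta_sq": e.partial_eta_sq,
                    "ss": e.ss,
                }
                for k, e in self.effects.items()
            },
            "cell_means": None
            if self.cell_means is None
            else {str(k): v for k, v in self.cell_means.stack().to_dict().items()},
        }


def _anova_frame(values, factor_a, factor_b) -> pd.DataFrame:
    df = pd.DataFrame(
        {
            "y": np.asarray(values, dtype=float),
            "a": np.asarray(factor_a),
            "b": np.asarray(factor_b),
        }
    )
    if df["y"].size == 0:
        raise ValueError("empty data")
    if df["a"].nunique() < 2 or df["b"].nunique() < 2:
        raise ValueError("both factors need >= 2 levels")
    counts = df.groupby(["a", "b"], observed=True).size().unstack()
    if counts.isna().any().any() or (counts == 0).any().any():
        raise ValueError("every factor-level cell needs >= 1 observation")
    return df


def two_way_anova(values, factor_a, factor_b, names: tuple[str, str] = ("A", "B")) -> AnovaResult:
    """Fixed-effects two-factor ANOVA with interaction, type-II SS.

    Handles balanced and unbalanced layouts.  Partial eta-squared is
    SS_effect / (SS_effect + SS_error) per effect.
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    df = _anova_frame(values, factor_a, factor_b)
    model = smf.ols("y ~ C(a) * C(b)", data=df).fit()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # anova_lm warns on near-zero residual SS
        tab = sm.stats.anova_lm(model, typ=2)
    ss_err = float(tab.loc["Residual", "sum_sq"])
    df_err = int(tab.loc["Residual", "df"])
    name_map = {"C(a)": names[0], "C(b)": names[1], "C(a):C(b)": f"{names[0]}:{names[1]}"}
    res = AnovaResult(factor_a=names[0], factor_b=names[1])
    for row, label in name_map.items():
        ss = float(tab.loc[row, "sum_sq"])
        dnum = int(tab.loc[row, "df"])
        F = float(tab.loc[row, "F"])
        p = float(tab.loc[row, "PR(>F)"])
        peta = ss / (ss + ss_err) if (ss + ss_err) > 0 else 0.0
        res.effects[label] = EffectStats(F, dnum, df_err, p, peta, ss)
    res.ss_error = ss_err
    res.df_error = df_err
    res.ms_error = ss_err / df_err if df_err > 0 else np.nan
    res.cell_means = df.groupby(["a", "b"], observed=True)["y"].mean().unstack()
    res.cell_counts = df.groupby(["a", "b"], observed=True).size().unstack()
    return res


def simple_effects(values, factor_a, factor_b, within_level_of: str = "b",
                   names: tuple[str, str] = ("A", "B")) -> list[SimpleEffect]:
    """Pairwise level contrasts of one factor at each level of the other.

    ``within_level_of="b"`` contrasts levels of factor A separately at every
    level of factor B (and vice versa), using the pooled error term of the
    full two-way model; MD is the plain cell-mean difference.
    """
    res = two_way_anova(values, factor_a, factor_b, names=names)
    df = _anova_frame(values, factor_a, factor_b)
    if within_level_of not in ("a", "b"):
        # accept the factor's display name too
        if within_level_of == names[0]:
            within_level_of = "a"
        elif within_level_of == names[1]:
            within_level_of = "b"
        else:
            raise ValueError(f"unknown factor {within_level_of!r}")
    fix, vary = ("b", "a") if within_level_of == "b" else ("a", "b")
    out: list[SimpleEffect] = []
    for lev in sorted(df[fix].unique()):
        sub = df[df[fix] == lev]
        levels = sorted(sub[vary].unique())
        if len(levels) < 2:
            raise ValueError(f"factor {vary!r} has a single level at {fix}={lev!r}")
        for i in range(len(levels)):
            for j in range(i + 1, len(levels)):
                gi = sub[sub[vary] == levels[i]]["y"]
                gj = sub[sub[vary] == levels[j]]["y"]
                md = float(gj.mean() - gi.mean())
                se = float(np.sqrt(res.ms_error * (1.0 / len(gi) + 1.0 / len(gj))))
                t = md / se if se > 0 else np.sign(md) * np.inf
                p = float(2.0 * sps.t.sf(abs(t), res.df_error)) if np.isfinite(t) else 0.0
                out.append(SimpleEffect(lev, levels[j], levels[i], md, float(t), p))
    return out


def bonferroni(p_values, n_tests: int | None = None):
    """Bonferroni correction: min(1, p * n_tests); scalar or elementwise."""
    p = np.asarray(p_values, dtype=float)
    if np.any(p < 0) or np.any(p > 1):
        raise ValueError("p-values must lie in [0, 1]")
    n = p.size if n_tests is None else int(n_tests)
    out = np.minimum(1.0, p * n)
    return float(out) if np.isscalar(p_values) or p.ndim == 0 else out
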