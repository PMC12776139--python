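"""Statistics layer: Welch t, Pearson, Sidak correction, mixed factorial ANOVA.

The mixed ANOVA uses the conventional split-plot partitioning for designs
with between-subject factors (sex, group, virus) and at most one
within-subject factor (week/day/zone): between effects are tested against
subjects-within-groups, within effects against the subject-by-within
residual.  Sums of squares are computed by an established OLS backend
(statsmodels); the partitioning is validated against a brute-force
sums-of-squares oracle in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .types import ValidationError

__all__ = ["TestResult", "welch_t", "pearson", "sidak", "mixed_anova", "MixedAnovaResult"]


@dataclass
class TestResult:
    """A single test outcome with its degrees of freedom and metadata."""

    kind: str
    statistic: float
    df: float
    p: float
    effect: dict = field(default_factory=dict)
    correction: dict | None = None
    flags: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if np.isfinite(self.p) and not 0 <= self.p <= 1:
            raise ValidationError("p must lie in [0, 1]")


def welch_t(x, y) -> TestResult:
    """Two-sided Welch unequal-variance t test with Welch-Satterthwaite df."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    nx, ny = len(x), len(y)
    if nx < 2 or ny < 2:
        raise ValidationError("welch_t needs at least 2 observations per sample")
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    se2 = vx / nx + vy / ny
    diff = x.mean() - y.mean()
    if se2 == 0:
        # both samples constant: equal means give t = 0, p = 1
        t = 0.0 if diff == 0 else np.inf * np.sign(diff)
        df = float(nx + ny - 2)
    else:
        t = diff / np.sqrt(se2)
        df = se2**2 / ((vx / nx) ** 2 / (nx - 1) + (vy / ny) ** 2 / (ny - 1))
    p = float(2 * sps.t.sf(abs(t), df)) if np.isfinite(t) else 0.0
    return TestResult(kind="welch_t", statistic=float(t), df=float(df), p=p,
                      effect={"mean_diff": float(diff)})


def pearson(x, y) -> TestResult:
    """Pearson r with a two-sided p from the t transform."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValidationError("x and y must have equal length")
    n = len(x)
    if n < 3:
        raise ValidationError("pearson needs n >= 3")
    if x.std() == 0 or y.std() == 0:
        return TestResult(kind="pearson", statistic=float("nan"), df=float(n - 2),
                          p=float("nan"), flags=["zero_variance"])
    r, p = sps.pearsonr(x, y)
    return TestResult(kind="pearson", statistic=float(r), df=float(n - 2), p=float(p),
                      effect={"r": float(r), "n": n})


def sidak(p=None, alpha: float | None = None, m: int = 1):
    """Sidak multiplicity correction for ``m`` comparisons.

    With ``alpha`` given, returns the adjusted per-comparison level
    ``1 - (1 - alpha)**(1/m)``.  With ``p`` given (scalar or array),
    returns adjusted p-values ``1 - (1 - p)**m`` capped at 1.
    """
    if m < 1:
        raise ValidationError("m must be >= 1")
    if (p is None) == (alpha is None):
        raise ValidationError("pass exactly one of p or alpha")
    if alpha is not None:
        return 1.0 - (1.0 - alpha) ** (1.0 / m)
    p = np.asarray(p, dtype=float)
    adj = np.minimum(1.0 - (1.0 - p) ** m, 1.0)
    return float(adj) if adj.ndim == 0 else adj


@dataclass
class MixedAnovaResult:
    """Effect table plus design metadata (exclusions, balance, sphericity handling)."""

    table: pd.DataFrame
    meta: dict


def _check_factor(df: pd.DataFrame, col: str) -> None:
    if col not in df.columns:
        raise ValidationError(f"missing factor column {col!r}")
    if df[col].nunique() < 2:
        raise ValidationError(f"factor {col!r} needs >= 2 levels")


def _between_formula(between: list[str], response: str) -> str:
    terms = "*".join(f"C(Q('{b}'))" for b in between)
    return f"Q('{response}') ~ {terms}"


def _effect_name(raw: str) -> str:
    """Translate patsy term names to plain factor names (a, a:b, ...)."""
    out = raw
    for tok in ("C(Q('", "'))"):
        out = out.replace(tok, "")
    return out


def mixed_anova(
    table: pd.DataFrame,
    between: list[str] | str | None,
    within: list[str] | str | None,
    response: str,
    subject: str = "subject",
) -> MixedAnovaResult:
    """Mixed factorial ANOVA (split-plot) on a tidy subject-by-condition table.

    ``between`` lists between-subject factors, ``within`` at most one
    repeated (within-subject) factor.  Subjects with incomplete
    within-factor cells are excluded listwise and counted in the metadata.
    Sphericity is assumed (declared in the metadata); with two within
    levels the assumption is vacuous.
    """
    import statsmodels.api as sm
    from statsmodels.formula.api import ols

    between = [between] if isinstance(between, str) else list(between or [])
    within = [within] if isinstance(within, str) else list(within or [])
    if len(within) > 1:
        raise ValidationError("at most one within-subject factor is supported")
    if not between and not within:
        raise ValidationError("need at least one factor")
    df = table.copy()
    for col in between + within:
        _check_factor(df, col)
    if subject not in df.columns:
        raise ValidationError(f"missing subject column {subject!r}")
    df = df.dropna(subset=[response])

    excluded: list = []
    if within:
        w = within[0]
        levels = sorted(df[w].unique())
        counts = df.groupby(subject)[w].nunique()
        complete = counts[counts == len(levels)].index
        excluded = sorted(set(df[subject]) - set(complete))
        df = df[df[subject].isin(complete)]
        if df[subject].nunique() < 2:
            raise ValidationError("fewer than 2 complete subjects")

    rows = []
    meta: dict = {
        "excluded_subjects": excluded,
        "n_subjects": int(df[subject].nunique()),
        "sphericity": "assumed",
        "backend": "statsmodels OLS",
    }

    if between:
        # between-subject stratum: factorial ANOVA on the per-subject means;
        # its residual is subjects-within-groups, the classical error term
        keep = [subject] + between
        subj_means = df.groupby(keep, as_index=False)[response].mean()
        if len(subj_means) <= int(np.prod([subj_means[b].nunique() for b in between])):
            raise ValidationError("no residual degrees of freedom (one subject per cell)")
        model = ols(_between_formula(between, response), data=subj_means).fit()
        aov = sm.stats.anova_lm(model, typ=2)
        resid_df = float(aov.loc["Residual", "df"])
        for name, r in aov.iterrows():
            if name == "Residual":
                continue
            rows.append({"effect": _effect_name(name), "stratum": "between",
                         "df1": float(r["df"]), "df2": resid_df,
                         "F": float(r["F"]), "p": float(r["PR(>F)"])})

    if within:
        w = within[0]
        # within stratum: the subject term absorbs all between-subject
        # variance; sequential RSS drops over an incrementally grown dummy
        # design give the classical split-plot SS, with the final residual
        # (the subject-by-within interaction) as the error term
        from itertools import combinations

        y = df[response].to_numpy(dtype=float)
        n_obs = len(y)

        def cells(cols: list[str]) -> np.ndarray:
            key = df[cols[0]].astype(str)
            for c in cols[1:]:
                key = key + "\x1f" + df[c].astype(str)
            return pd.get_dummies(key, dtype=float).to_numpy()

        def rss(X: np.ndarray) -> tuple[float, int]:
            beta, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
            return float(((y - X @ beta) ** 2).sum()), int(rank)

        n_levels = {c: df[c].nunique() for c in between + [w]}
        term_sets: list[tuple[str, list[str]]] = [(w, [w])]
        for k in range(1, len(between) + 1):
            for combo in combinations(between, k):
                term_sets.append((":".join([w, *combo]), [w, *combo]))
        X = cells([subject])
        prev_rss, _ = rss(X)
        seq: list[tuple[str, float, float]] = []
        for name, cols in term_sets:
            X = np.hstack([X, cells(cols)])
            cur_rss, rank = rss(X)
            df1 = float(np.prod([n_levels[c] - 1 for c in cols]))
            seq.append((name, prev_rss - cur_rss, df1))
            prev_rss = cur_rss
        resid_df = float(n_obs - rank)
        if resid_df <= 0:
            raise ValidationError("no residual degrees of freedom in the within stratum")
        resid_ms = prev_rss / resid_df
        for name, ss, df1 in seq:
            F = (ss / df1) / resid_ms
            p = float(sps.f.sf(F, df1, resid_df))
            rows.append({"effect": name, "stratum": "within",
                         "df1": df1, "df2": resid_df, "F": F, "p": p})
        cell_counts = df.groupby(between + [w] if between else [w])[response].count()
        meta["balanced"] = bool(cell_counts.nunique() == 1)

    return MixedAnovaResult(table=pd.DataFrame(rows), meta=meta)
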