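"""Within-subject inferential layer.

Implements the classical two-way repeated-measures ANOVA decomposition
(Condition x Route event, subjects random), generalized eta-squared effect
sizes, Tukey-adjusted pairwise post hocs on subject-level collapsed
differences, and t-based 95% confidence summaries.

Sums of squares (balanced complete design, a x b cells, n subjects):

    SS_S   = ab * sum_s (m_s - m)^2          subjects
    SS_A   = nb * sum_a (m_a - m)^2          factor A
    SS_B   = na * sum_b (m_b - m)^2          factor B
    SS_AB  = n  * sum_ab (m_ab - m_a - m_b + m)^2
    SS_AS  = b  * sum_as (m_as - m_a - m_s + m)^2
    SS_BS  = a  * sum_bs (m_bs - m_b - m_s + m)^2
    SS_ABS = SS_total - (all of the above)

with F_A = MS_A / MS_AS etc., p from the F distribution (no sphericity
correction by default; Greenhouse-Geisser available but off, matching
reporting of uncorrected dfs).  eta^2_G uses all subject-related variance
in the denominator.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "AnovaResult",
    "EffectResult",
    "rm_anova",
    "generalized_eta_squared",
    "tukey_posthoc",
    "ci95",
    "complete_cases",
]


@dataclass(frozen=True)
class EffectResult:
    name: str
    F: float
    df_num: float
    df_den: float
    p: float
    ges: float


@dataclass(frozen=True)
class AnovaResult:
    effects: dict  # name -> EffectResult
    decomposition: dict  # SS components
    n_subjects: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "effect": e.name,
                    "F": e.F,
                    "df_num": e.df_num,
                    "df_den": e.df_den,
                    "p": e.p,
                    "ges": e.ges,
                }
                for e in self.effects.values()
            ]
        )


def complete_cases(
    table: pd.DataFrame,
    *,
    subject: str = "subject",
    factors: tuple[str, str] = ("condition", "event"),
    value: str = "value",
) -> tuple[np.ndarray, list, list, list, list]:
    """Listwise-deleted, balanced subject x A x B value array.

    Returns (Y[n, a, b], subjects kept, A levels, B levels, subjects
    dropped).  Raises on duplicate cells or if fewer than 2 complete
    subjects remain.
    """
    fa, fb = factors
    dup = table.duplicated(subset=[subject, fa, fb])
    if dup.any():
        bad = table.loc[dup, subject].unique().tolist()
        raise ValueError(f"duplicate cells for subjects {bad}")
    a_levels = sorted(table[fa].unique().tolist())
    b_levels = sorted(table[fb].unique().tolist())
    n_cells = len(a_levels) * len(b_levels)
    ok = table.dropna(subset=[value])
    counts = ok.groupby(subject).size()
    keep = [s for s in counts.index if counts[s] == n_cells]
    dropped = sorted(set(table[subject]) - set(keep))
    if len(keep) < 2:
        raise ValueError(
            f"fewer than 2 complete subjects (dropped: {dropped})"
        )
    sub = ok[ok[subject].isin(keep)]
    piv = sub.pivot_table(
        index=subject, columns=[fa, fb], values=value, aggfunc="first", sort=True
    )
    subjects = piv.index.tolist()
    Y = np.empty((len(subjects), len(a_levels), len(b_levels)))
    for i, al in enumerate(a_levels):
        for j, bl in enumerate(b_levels):
            Y[:, i, j] = piv[(al, bl)].to_numpy()
    return Y, subjects, a_levels, b_levels, dropped


def rm_anova(
    table: pd.DataFrame,
    *,
    subject: str = "subject",
    factors: tuple[str, str] = ("condition", "event"),
    value: str = "value",
    gg_correction: bool = False,
) -> AnovaResult:
    """Two-way fully-within ANOVA on a long-format cell table."""
    Y, subjects, a_levels, b_levels, _ = complete_cases(
        table, subject=subject, factors=factors, value=value
    )
    n, a, b = Y.shape

    m = Y.mean()
    m_s = Y.mean(axis=(1, 2))
    m_a = Y.mean(axis=(0, 2))
    m_b = Y.mean(axis=(0, 1))
    m_ab = Y.mean(axis=0)
    m_as = Y.mean(axis=2)
    m_bs = Y.mean(axis=1)

    ss_total = float(((Y - m) ** 2).sum())
    ss_s = a * b * float(((m_s - m) ** 2).sum())
    ss_a = n * b * float(((m_a - m) ** 2).sum())
    ss_b = n * a * float(((m_b - m) ** 2).sum())
    ss_ab = n * float(((m_ab - m_a[:, None] - m_b[None, :] + m) ** 2).sum())
    ss_as = b * float(((m_as - m_a[None, :] - m_s[:, None] + m) ** 2).sum())
    ss_bs = a * float(((m_bs - m_b[None, :] - m_s[:, None] + m) ** 2).sum())
    ss_abs = ss_total - (ss_s + ss_a + ss_b + ss_ab + ss_as + ss_bs)
    ss_abs = max(ss_abs, 0.0)

    decomposition = {
        "SS_subject": ss_s,
        "SS_A": ss_a,
        "SS_B": ss_b,
        "SS_AB": ss_ab,
        "SS_AxS": ss_as,
        "SS_BxS": ss_bs,
        "SS_ABxS": ss_abs,
        "SS_total": ss_total,
    }

    ges = generalized_eta_squared(decomposition)

    labels = {"A": factors[0], "B": factors[1], "AxB": f"{factors[0]}:{factors[1]}"}
    specs = {
        "A": (ss_a, ss_as, a - 1, (a - 1) * (n - 1), "A"),
        "B": (ss_b, ss_bs, b - 1, (b - 1) * (n - 1), "B"),
        "AxB": (ss_ab, ss_abs, (a - 1) * (b - 1), (a - 1) * (b - 1) * (n - 1), "AB"),
    }
    effects = {}
    for key, (ss_eff, ss_err, dfn, dfd, _tag) in specs.items():
        if gg_correction and key in ("B", "AxB"):
            eps = _gg_epsilon(Y, key)
            dfn_c, dfd_c = dfn * eps, dfd * eps
        else:
            dfn_c, dfd_c = dfn, dfd
        if ss_err <= 0:
            F = 0.0 if ss_eff <= 1e-300 else float("inf")
            p = 1.0 if F == 0.0 else 0.0
        else:
            F = (ss_eff / dfn) / (ss_err / dfd)
            p = float(sps.f.sf(F, dfn_c, dfd_c))
        effects[labels[key]] = EffectResult(
            name=labels[key], F=float(F), df_num=dfn_c, df_den=dfd_c, p=p, ges=ges[key]
        )
    return AnovaResult(effects=effects, decomposition=decomposition, n_subjects=n)


def _gg_epsilon(Y: np.ndarray, effect: str) -> float:
    """Greenhouse-Geisser epsilon for the B or AxB within effect."""
    n, a, b = Y.shape
    if effect == "B":
        D = Y.mean(axis=1)  # n x b
    else:
        # interaction contrasts: differences across A at each b
        D = Y[:, 0, :] - Y[:, 1, :] if a == 2 else Y.reshape(n, a * b)
    S = np.cov(D, rowvar=False)
    S = np.atleast_2d(S)
    k = S.shape[0]
    mean_diag = np.trace(S) / k
    mean_all = S.mean()
    row_means = S.mean(axis=1)
    num = (k * (mean_diag - mean_all)) ** 2
    den = (k - 1) * (np.sum(S**2) - 2 * k * np.sum(row_means**2) + k**2 * mean_all**2)
    if den <= 0:
        return 1.0
    return float(min(1.0, max(num / den, 1.0 / (k - 1))))


def generalized_eta_squared(decomposition: dict) -> dict:
    """eta^2_G per effect: SS_eff / (SS_eff + SS_S + SS_AxS + SS_BxS + SS_ABxS)."""
    pooled = (
        decomposition["SS_subject"]
        + decomposition["SS_AxS"]
        + decomposition["SS_BxS"]
        + decomposition["SS_ABxS"]
    )
    out = {}
    for key, ss_key in (("A", "SS_A"), ("B", "SS_B"), ("AxB", "SS_AB")):
        ss_eff = decomposition[ss_key]
        den = ss_eff + pooled
        out[key] = 0.0 if den <= 0 else float(ss_eff / den)
    return out


def tukey_posthoc(
    table: pd.DataFrame,
    factor: str,
    *,
    subject: str = "subject",
    factors: tuple[str, str] = ("condition", "event"),
    value: str = "value",
) -> pd.DataFrame:
    """Pairwise paired-t comparisons of one factor's levels, Tukey-adjusted.

    Values are collapsed (averaged) over the other factor per subject, then
    each level pair gets a paired t with df = n - 1 and an adjusted p from
    the studentized-range distribution with k = number of levels via
    q = |t| * sqrt(2).
    """
    Y, subjects, a_levels, b_levels, _ = complete_cases(
        table, subject=subject, factors=factors, value=value
    )
    if factor == factors[0]:
        levels, M = a_levels, Y.mean(axis=2)  # n x a
    elif factor == factors[1]:
        levels, M = b_levels, Y.mean(axis=1)  # n x b
    else:
        raise ValueError(f"unknown factor {factor!r}; expected one of {factors}")
    k = len(levels)
    if k < 2:
        raise ValueError("factor needs at least 2 levels")
    n = M.shape[0]
    rows = []
    for i in range(k):
        for j in range(i + 1, k):
            d = M[:, i] - M[:, j]
            md = float(d.mean())
            sd = float(d.std(ddof=1))
            se = sd / np.sqrt(n)
            t = 0.0 if se == 0 else md / se
            if se == 0:
                p_adj = 1.0 if md == 0 else 0.0
            else:
                q = abs(t) * np.sqrt(2.0)
                p_adj = float(sps.studentized_range.sf(q, k, n - 1))
            rows.append(
                {
                    "level_a": levels[i],
                    "level_b": levels[j],
                    "mean_diff": md,
                    "t": float(t),
                    "df": n - 1,
                    "p_tukey": min(1.0, p_adj),
                }
            )
    return pd.DataFrame(rows)


def ci95(values: np.ndarray) -> tuple[float, float]:
    """Mean and 95% CI half-width (t-based); half-width NaN when n < 2."""
    x = np.asarray(values, dtype=float)
    x = x[np.isfinite(x)]
    n = x.size
    if n == 0:
        return float("nan"), float("nan")
    mean = float(x.mean())
    if n < 2:
        return mean, float("nan")
    se = x.std(ddof=1) / np.sqrt(n)
    hw = float(sps.t.ppf(0.975, n - 1) * se)
    return mean, hw
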