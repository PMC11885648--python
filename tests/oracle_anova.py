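"""Brute-force two-way within-subject ANOVA oracle.

Explicit cell-mean / grand-mean summation with plain Python loops — no
matrix shortcuts — kept deliberately independent of the package
implementation it checks.
"""

from __future__ import annotations


def brute_force_rm_anova(data: dict) -> dict:
    """``data[(subject, a, b)] = value`` for a complete balanced design.

    Returns all sums of squares plus F ratios per effect.
    """
    subjects = sorted({k[0] for k in data})
    a_levels = sorted({k[1] for k in data})
    b_levels = sorted({k[2] for k in data})
    n, a, b = len(subjects), len(a_levels), len(b_levels)

    def mean(keys):
        return sum(data[k] for k in keys) / len(keys)

    all_keys = [(s, x, y) for s in subjects for x in a_levels for y in b_levels]
    grand = mean(all_keys)

    m_s = {s: mean([(s, x, y) for x in a_levels for y in b_levels]) for s in subjects}
    m_a = {x: mean([(s, x, y) for s in subjects for y in b_levels]) for x in a_levels}
    m_b = {y: mean([(s, x, y) for s in subjects for x in a_levels]) for y in b_levels}
    m_ab = {(x, y): mean([(s, x, y) for s in subjects]) for x in a_levels for y in b_levels}
    m_as = {(s, x): mean([(s, x, y) for y in b_levels]) for s in subjects for x in a_levels}
    m_bs = {(s, y): mean([(s, x, y) for x in a_levels]) for s in subjects for y in b_levels}

    ss_total = sum((data[k] - grand) ** 2 for k in all_keys)
    ss_s = a * b * sum((m_s[s] - grand) ** 2 for s in subjects)
    ss_a = n * b * sum((m_a[x] - grand) ** 2 for x in a_levels)
    ss_b = n * a * sum((m_b[y] - grand) ** 2 for y in b_levels)
    ss_ab = n * sum(
        (m_ab[(x, y)] - m_a[x] - m_b[y] + grand) ** 2 for x in a_levels for y in b_levels
    )
    ss_as = b * sum(
        (m_as[(s, x)] - m_a[x] - m_s[s] + grand) ** 2 for s in subjects for x in a_levels
    )
    ss_bs = a * sum(
        (m_bs[(s, y)] - m_b[y] - m_s[s] + grand) ** 2 for s in subjects for y in b_levels
    )
    ss_abs = ss_total - ss_s - ss_a - ss_b - ss_ab - ss_as - ss_bs

    def f_ratio(ss_eff, df_eff, ss_err, df_err):
        if ss_err == 0:
            return 0.0
        return (ss_eff / df_eff) / (ss_err / df_err)

    return {
        "SS_subject": ss_s,
        "SS_A": ss_a,
        "SS_B": ss_b,
        "SS_AB": ss_ab,
        "SS_AxS": ss_as,
        "SS_BxS": ss_bs,
        "SS_ABxS": ss_abs,
        "SS_total": ss_total,
        "F_A": f_ratio(ss_a, a - 1, ss_as, (a - 1) * (n - 1)),
        "F_B": f_ratio(ss_b, b - 1, ss_bs, (b - 1) * (n - 1)),
        "F_AB": f_ratio(ss_ab, (a - 1) * (b - 1), ss_abs, (a - 1) * (b - 1) * (n - 1)),
    }
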