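"""Statistical layer: directional t-tests, 3x2 within-subject ANOVA with
total-variance eta-squared, Holm correction and 3.5xIQR outlier fences.

Effect sizes are eta-squared computed against the *total* sum of squares,
including between-subject variance — not partial eta-squared.  For a
within-subject design this yields markedly smaller values than
``t**2/(t**2+df)`` whenever subjects differ from each other, which is the
convention the pipeline reports throughout.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "StatResult",
    "one_sample_t",
    "paired_t",
    "rm_anova_3x2",
    "holm_correct",
    "iqr_exclude",
    "eta_squared",
]

SIDEDNESS = ("two", "greater", "less")


@dataclass(frozen=True)
class StatResult:
    """One test's outcome.  ``statistic`` is |t| or F; ``df`` is an int for
    t-tests and an (effect, error) pair for F-tests."""

    name: str
    statistic: float
    df: int | tuple[int, int]
    p: float
    eta_squared: float
    sidedness: str = "two"
    n: int = 0
    p_adjusted: float | None = None


def eta_squared(ss_effect: float, ss_total: float) -> float:
    """SS_effect / SS_total (total includes between-subject variance)."""
    if ss_total < 0 or ss_effect < 0:
        raise ValueError("sums of squares must be non-negative")
    if ss_total == 0:
        raise ZeroDivisionError("zero total sum of squares")
    return float(ss_effect / ss_total)


def one_sample_t(
    values, mu0: float = 0.0, sidedness: str = "two", name: str = "one_sample_t"
) -> StatResult:
    """One-sample t-test against ``mu0`` with a directional option.

    ``sidedness='greater'`` tests mean > mu0, ``'less'`` mean < mu0.
    The t statistic is reported as an absolute value; the p-value honors
    the direction.  Eta-squared is ``n*(mean-mu0)^2 / sum((x-mu0)^2)``.
    """
    if sidedness not in SIDEDNESS:
        raise ValueError(f"sidedness must be one of {SIDEDNESS}")
    x = np.asarray([v for v in np.ravel(values) if not np.isnan(v)], dtype=float)
    n = len(x)
    if n < 2:
        raise ValueError(f"need at least 2 values, got {n}")
    if np.ptp(x) == 0:
        if x[0] == mu0:
            # all values exactly at mu0: no variance and no deviation,
            # report a null result rather than 0/0
            return StatResult(
                name=name, statistic=0.0, df=n - 1, p=1.0,
                eta_squared=0.0, sidedness=sidedness, n=n,
            )
        raise ZeroDivisionError("zero variance: t statistic undefined")
    alternative = {"two": "two-sided", "greater": "greater", "less": "less"}[sidedness]
    res = sps.ttest_1samp(x, popmean=mu0, alternative=alternative)
    ss_effect = n * (x.mean() - mu0) ** 2
    ss_total = float(np.sum((x - mu0) ** 2))
    return StatResult(
        name=name,
        statistic=float(abs(res.statistic)),
        df=n - 1,
        p=float(res.pvalue),
        eta_squared=eta_squared(ss_effect, ss_total),
        sidedness=sidedness,
        n=n,
    )


def paired_t(a, b, sidedness: str = "two", name: str = "paired_t") -> StatResult:
    """Paired t-test (one-sample t on pairwise differences a - b).

    Pairs with a missing member are dropped listwise.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired samples must have equal length")
    keep = ~(np.isnan(a) | np.isnan(b))
    return one_sample_t(a[keep] - b[keep], 0.0, sidedness, name=name)


def rm_anova_3x2(cells: np.ndarray) -> dict[str, StatResult]:
    """Two-way fully within-subject ANOVA on a (n, 3, 2) cell array.

    Axis 1 is probe time (early, late, after), axis 2 temporal
    uncertainty (low, high).  Rows containing NaN are removed listwise.
    Returns results for ``time``, ``uncertainty`` and ``interaction``;
    each F is tested against its own effect-by-subject error term and
    eta-squared is taken against the total SS (subjects included).
    """
    cells = np.asarray(cells, dtype=float)
    if cells.ndim != 3 or cells.shape[1:] != (3, 2):
        raise ValueError(f"expected (n, 3, 2) cell array, got {cells.shape}")
    cells = cells[~np.isnan(cells).any(axis=(1, 2))]
    n = cells.shape[0]
    if n < 3:
        raise ValueError(f"need >= 3 complete subjects, got {n}")
    a, b = 3, 2
    grand = cells.mean()
    m_subj = cells.mean(axis=(1, 2))           # (n,)
    m_a = cells.mean(axis=(0, 2))              # (3,)
    m_b = cells.mean(axis=(0, 1))              # (2,)
    m_ab = cells.mean(axis=0)                  # (3, 2)
    m_as = cells.mean(axis=2)                  # (n, 3)
    m_bs = cells.mean(axis=1)                  # (n, 2)

    ss_total = float(((cells - grand) ** 2).sum())
    ss_subj = a * b * float(((m_subj - grand) ** 2).sum())
    ss_a = b * n * float(((m_a - grand) ** 2).sum())
    ss_b = a * n * float(((m_b - grand) ** 2).sum())
    ss_ab = n * float(((m_ab - m_a[:, None] - m_b[None, :] + grand) ** 2).sum())
    ss_as = b * float(
        ((m_as - m_a[None, :] - m_subj[:, None] + grand) ** 2).sum()
    )
    ss_bs = a * float(
        ((m_bs - m_b[None, :] - m_subj[:, None] + grand) ** 2).sum()
    )
    ss_abs = ss_total - (ss_subj + ss_a + ss_b + ss_ab + ss_as + ss_bs)
    # relative floor below which a sum of squares is numerical dust
    tiny = 1e-12 * max(float(np.mean(cells**2)) * cells.size, 1e-300)

    def f_test(name, ss_eff, df_eff, ss_err, df_err):
        ss_eff = 0.0 if ss_eff <= tiny else ss_eff
        ss_err = 0.0 if ss_err <= tiny else ss_err
        ms_eff = ss_eff / df_eff
        ms_err = ss_err / df_err
        F = ms_eff / ms_err if ms_err > 0 else 0.0
        p = float(sps.f.sf(F, df_eff, df_err)) if ms_err > 0 else 1.0
        # all-identical data: no variance to apportion, report a null effect
        eta = eta_squared(ss_eff, ss_total) if ss_total > 0 else 0.0
        return StatResult(
            name=name,
            statistic=float(F),
            df=(df_eff, df_err),
            p=p,
            eta_squared=eta,
            n=n,
        )

    return {
        "time": f_test("time", ss_a, a - 1, ss_as, (a - 1) * (n - 1)),
        "uncertainty": f_test("uncertainty", ss_b, b - 1, ss_bs, (b - 1) * (n - 1)),
        "interaction": f_test(
            "interaction", ss_ab, (a - 1) * (b - 1), ss_abs, (a - 1) * (b - 1) * (n - 1)
        ),
    }


def holm_correct(p_values) -> np.ndarray:
    """Holm step-down adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="holm")[1]


def iqr_exclude(values, multiplier: float = 3.5) -> tuple[np.ndarray, dict]:
    """Mask values outside ``[Q1 - m*IQR, Q3 + m*IQR]`` (strict fences).

    Quartiles use linear-interpolation (type-7) quantiles.  NaNs are
    passed through as not-retained-but-not-outliers.  Returns a boolean
    retain mask and an exclusion log.
    """
    x = np.asarray(values, dtype=float)
    finite = x[~np.isnan(x)]
    if finite.size < 4:
        raise ValueError(f"need >= 4 values to define quartiles, got {finite.size}")
    q1, q3 = np.percentile(finite, [25, 75])
    iqr = q3 - q1
    lo, hi = q1 - multiplier * iqr, q3 + multiplier * iqr
    outlier = (x < lo) | (x > hi)
    retain = ~outlier & ~np.isnan(x)
    log = {
        "q1": float(q1),
        "q3": float(q3),
        "fence_low": float(lo),
        "fence_high": float(hi),
        "n_excluded": int(outlier.sum()),
        "excluded_indices": np.flatnonzero(outlier).tolist(),
        "excluded_values": x[outlier].tolist(),
    }
    return retain, log
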