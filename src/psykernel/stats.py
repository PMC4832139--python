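"""Group-level statistics: one-way repeated-measures ANOVA and paired t.

The ANOVA uses the subject-by-condition interaction as the error term,
reports partial eta squared, Mauchly's sphericity test on the orthonormal
contrasts, and the Greenhouse–Geisser-corrected p-value.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .exceptions import InsufficientDataError


@dataclass
class RmAnovaResult:
    F: float
    df1: float
    df2: float
    p: float
    partial_eta_sq: float
    mauchly_W: float
    mauchly_p: float
    gg_epsilon: float
    corrected_p: float
    zero_error_variance: bool = False


@dataclass
class PairedTResult:
    t: float
    df: int
    p: float
    zero_variance: bool = False


def _orthonormal_contrasts(k: int) -> np.ndarray:
    """(k−1)×k orthonormal rows spanning the space orthogonal to 1."""
    helmert = np.zeros((k - 1, k))
    for i in range(k - 1):
        helmert[i, :i + 1] = 1.0
        helmert[i, i + 1] = -(i + 1.0)
        helmert[i] /= np.linalg.norm(helmert[i])
    return helmert


def rm_anova_one_way(values: np.ndarray) -> RmAnovaResult:
    """One-way repeated-measures ANOVA on a subjects × conditions matrix.

    F = MS_condition / MS_(condition×subject) with df (k−1, (k−1)(n−1));
    partial eta² = SS_cond / (SS_cond + SS_err).  Mauchly's W is computed on
    the orthonormal-contrast covariance with the standard chi-square
    approximation; epsilon is Greenhouse–Geisser and the corrected p uses
    (ε·df1, ε·df2).
    """
    y = np.asarray(values, dtype=float)
    if y.ndim != 2:
        raise ValueError("values must be a 2D subjects × conditions matrix")
    n, k = y.shape
    if n < 3 or k < 2:
        raise InsufficientDataError("need >= 3 subjects and >= 2 conditions")
    if np.isnan(y).any():
        raise ValueError("missing cells are not supported")

    grand = y.mean()
    col_means = y.mean(axis=0)
    row_means = y.mean(axis=1)
    ss_cond = n * np.sum((col_means - grand) ** 2)
    ss_subj = k * np.sum((row_means - grand) ** 2)
    ss_total = np.sum((y - grand) ** 2)
    ss_err = ss_total - ss_cond - ss_subj
    df1 = k - 1
    df2 = (k - 1) * (n - 1)
    ms_cond = ss_cond / df1
    ms_err = ss_err / df2

    zero_err = ms_err <= np.finfo(float).eps * max(1.0, abs(ss_total))
    if zero_err:
        f_stat = np.nan if ss_cond > 0 else 0.0
        p = np.nan if ss_cond > 0 else 1.0
    else:
        f_stat = ms_cond / ms_err
        p = float(sps.f.sf(f_stat, df1, df2))
    eta = ss_cond / (ss_cond + ss_err) if (ss_cond + ss_err) > 0 else 0.0

    # sphericity on the (k-1) orthonormal contrasts
    c = _orthonormal_contrasts(k)
    s_c = c @ np.cov(y, rowvar=False, ddof=1) @ c.T
    evals = np.linalg.eigvalsh(s_c)
    mean_ev = evals.mean()
    if np.all(evals > 0) and mean_ev > 0:
        w = float(np.prod(evals) / mean_ev ** (k - 1))
        chi_df = k * (k - 1) / 2 - 1
        box = (2 * (k - 1) ** 2 + (k - 1) + 2) / (6 * (k - 1) * (n - 1))
        if chi_df > 0 and w > 0:
            chi2 = -(n - 1) * (1 - box) * np.log(w)
            mauchly_p = float(sps.chi2.sf(chi2, chi_df))
        else:
            mauchly_p = 1.0  # k=2: sphericity trivially holds
        gg = float(np.sum(evals) ** 2 / ((k - 1) * np.sum(evals ** 2)))
    else:
        w, mauchly_p, gg = 0.0, 0.0, 1.0 / (k - 1)

    if zero_err or not np.isfinite(f_stat):
        corrected_p = p
    else:
        corrected_p = float(sps.f.sf(f_stat, gg * df1, gg * df2))
    return RmAnovaResult(F=float(f_stat), df1=df1, df2=df2, p=p,
                         partial_eta_sq=float(eta), mauchly_W=w,
                         mauchly_p=mauchly_p, gg_epsilon=gg,
                         corrected_p=corrected_p,
                         zero_error_variance=bool(zero_err))


def paired_t(a: np.ndarray, b: np.ndarray) -> PairedTResult:
    """Classical two-tailed paired t-test (df = n − 1).

    A zero-variance difference vector is flagged rather than raising.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("inputs must be equal-length 1D arrays")
    n = len(a)
    if n < 2:
        raise InsufficientDataError("need at least 2 pairs")
    d = a - b
    sd = d.std(ddof=1)
    df = n - 1
    if sd == 0:
        if d.mean() == 0:
            return PairedTResult(t=0.0, df=df, p=1.0, zero_variance=True)
        return PairedTResult(t=np.nan, df=df, p=np.nan, zero_variance=True)
    t = d.mean() / (sd / np.sqrt(n))
    p = float(2 * sps.t.sf(abs(t), df))
    return PairedTResult(t=float(t), df=df, p=p)


def posthoc_paired_t(values: np.ndarray, labels,
                     holm: bool = False) -> list[dict]:
    """All pairwise paired t-tests between condition columns.

    ``holm=True`` additionally reports Holm-adjusted p-values (off by
    default to match uncorrected post-hoc reporting).
    """
    y = np.asarray(values, dtype=float)
    pairs = [(i, j) for i in range(y.shape[1]) for j in range(y.shape[1])
             if i < j]
    rows = []
    for i, j in pairs:
        res = paired_t(y[:, i], y[:, j])
        rows.append({"a": labels[i], "b": labels[j], "t": res.t,
                     "df": res.df, "p": res.p,
                     "zero_variance": res.zero_variance})
    if holm:
        order = np.argsort([r["p"] for r in rows])
        m = len(rows)
        prev = 0.0
        for rank, pos in enumerate(order):
            adj = min(1.0, (m - rank) * rows[pos]["p"])
            prev = max(prev, adj)
            rows[pos]["p_holm"] = prev
    return rows
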