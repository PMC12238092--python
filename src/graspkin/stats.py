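"""Statistical validation layer: within-subject ANOVA and correlations.

The design is one-way repeated measures: every participant contributes a
mean value per rotation condition (N1..N4) for each movement parameter.
The classical decomposition removes the between-subject variance before
testing the condition effect:

    SS_total = SS_subjects + SS_conditions + SS_error
    F = MS_conditions / MS_error,  df = (k-1), (n-1)(k-1)

Sphericity is checked with Mauchly's W; when violated (p < .05) the
reported p-value uses Greenhouse-Geisser-corrected degrees of freedom
(epsilon in [1/(k-1), 1]). Effect size is partial eta squared,
SS_cond / (SS_cond + SS_err). Pairwise follow-ups are paired t-tests with
Bonferroni correction over the 6 condition pairs; the association between
wrist path length and the temporal parameters uses Spearman rank
correlation; performance drift over the session uses a quartile split of
the trial sequence.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .metrics import CONDITIONS, PARAMETERS, ConditionTable

__all__ = [
    "AnovaResult",
    "PairwiseTable",
    "CorrelationResult",
    "rm_anova",
    "gg_epsilon",
    "mauchly",
    "bonferroni_pairwise",
    "spearman",
    "quartile_drift",
]


@dataclass
class AnovaResult:
    parameter: str
    F: float
    df_effect: float
    df_error: float
    MSE: float
    p_uncorrected: float
    mauchly_W: float
    mauchly_p: float
    gg_epsilon: float
    p_gg: float
    partial_eta_sq: float
    n_subjects: int
    degenerate: bool = False

    @property
    def sphericity_violated(self) -> bool:
        return self.mauchly_p < 0.05

    @property
    def p_reported(self) -> float:
        """GG-corrected p when sphericity is violated, raw p otherwise."""
        return self.p_gg if self.sphericity_violated else self.p_uncorrected

    def as_row(self) -> dict:
        return {
            "parameter": self.parameter, "F": self.F,
            "df_effect": self.df_effect, "df_error": self.df_error,
            "MSE": self.MSE, "p_uncorrected": self.p_uncorrected,
            "mauchly_W": self.mauchly_W, "mauchly_p": self.mauchly_p,
            "gg_epsilon": self.gg_epsilon, "p_gg": self.p_gg,
            "p_reported": self.p_reported,
            "partial_eta_sq": self.partial_eta_sq, "n_subjects": self.n_subjects,
        }


@dataclass
class PairwiseTable:
    parameter: str
    table: pd.DataFrame  # columns: a, b, mean_diff, t, p_raw, p_bonferroni


@dataclass
class CorrelationResult:
    rho: float
    p: float
    n: int


def _as_matrix(data, parameter: str | None = None) -> np.ndarray:
    """Accept a ConditionTable, DataFrame or array; return complete-case
    (n_subjects, k) float matrix."""
    if isinstance(data, ConditionTable):
        if parameter is None:
            raise ValueError("parameter required with a ConditionTable")
        m = data.complete(parameter).to_numpy(float)
    elif isinstance(data, pd.DataFrame):
        m = data.dropna(axis=0, how="any").to_numpy(float)
    else:
        m = np.asarray(data, float)
        m = m[~np.isnan(m).any(axis=1)]
    if m.ndim != 2:
        raise ValueError("expected a subjects x conditions matrix")
    return m


def gg_epsilon(matrix) -> float:
    """Greenhouse-Geisser epsilon from the sample covariance of conditions.

    The closed form of the sphericity departure; bounded below by
    1/(k-1) (maximal violation) and above by 1 (sphericity holds).
    """
    m = _as_matrix(matrix)
    n, k = m.shape
    if k < 2:
        raise ValueError("need at least 2 conditions")
    if k == 2:
        return 1.0
    S = np.cov(m, rowvar=False)
    mean_diag = np.trace(S) / k
    grand = S.mean()
    row_means = S.mean(axis=1)
    num = (k * (mean_diag - grand)) ** 2
    den = (k - 1) * (
        (S ** 2).sum() - 2 * k * (row_means ** 2).sum() + k ** 2 * grand ** 2
    )
    if den <= 0:
        return 1.0
    eps = num / den
    return float(min(1.0, max(1.0 / (k - 1), eps)))


def _helmert_contrasts(k: int) -> np.ndarray:
    """Orthonormal contrast matrix, (k-1) x k."""
    C = np.zeros((k - 1, k))
    for i in range(k - 1):
        C[i, : i + 1] = 1.0
        C[i, i + 1] = -(i + 1)
        C[i] /= np.linalg.norm(C[i])
    return C


def mauchly(matrix) -> tuple[float, float]:
    """Mauchly's sphericity test: returns (W, p) via the chi-square
    approximation on the orthonormally transformed covariance."""
    m = _as_matrix(matrix)
    n, k = m.shape
    if k < 3 or n <= k - 1:
        return 1.0, 1.0  # test undefined; sphericity cannot be rejected
    C = _helmert_contrasts(k)
    Sc = C @ np.cov(m, rowvar=False) @ C.T
    d = k - 1
    det = np.linalg.det(Sc)
    tr = np.trace(Sc)
    if det <= 0 or tr <= 0:
        return 0.0, 0.0
    W = det / (tr / d) ** d
    df = d * (d + 1) // 2 - 1
    f = 1.0 - (2 * d ** 2 + d + 2) / (6.0 * d * (n - 1))
    chi2 = -(n - 1) * f * np.log(W)
    p = float(sps.chi2.sf(chi2, df))
    return float(W), p


def rm_anova(table, parameter: str | None = None) -> AnovaResult:
    """One-way repeated-measures ANOVA on a participant x condition table.

    Accepts a :class:`~graspkin.metrics.ConditionTable` plus a parameter
    name, or a complete-case matrix/DataFrame directly. Participants with
    any missing cell are excluded listwise. Both the uncorrected and the
    Greenhouse-Geisser p-value are always computed; ``p_reported`` follows
    the sphericity check.
    """
    m = _as_matrix(table, parameter)
    n, k = m.shape
    if n < 2:
        raise ValueError("need at least 2 complete participants")
    grand = m.mean()
    cond_means = m.mean(axis=0)
    subj_means = m.mean(axis=1)
    ss_total = ((m - grand) ** 2).sum()
    ss_cond = n * ((cond_means - grand) ** 2).sum()
    ss_subj = k * ((subj_means - grand) ** 2).sum()
    ss_err = ss_total - ss_cond - ss_subj
    df_eff = k - 1
    df_err = (n - 1) * (k - 1)
    ms_err = ss_err / df_err
    degenerate = ss_err <= 0 or not np.isfinite(ms_err) or ms_err == 0
    if degenerate:
        F = 0.0
        p_unc = 1.0
        # distinguish "no variance anywhere" from "perfectly consistent effect"
        tiny = 1e-10 * max(1.0, grand ** 2) * m.size
        peta = 0.0 if ss_cond <= tiny else 1.0
    else:
        F = (ss_cond / df_eff) / ms_err
        p_unc = float(sps.f.sf(F, df_eff, df_err))
        peta = ss_cond / (ss_cond + ss_err)
    eps = gg_epsilon(m)
    W, p_m = mauchly(m)
    p_gg = 1.0 if degenerate else float(sps.f.sf(F, df_eff * eps, df_err * eps))
    return AnovaResult(
        parameter=parameter or "", F=float(F), df_effect=float(df_eff),
        df_error=float(df_err), MSE=float(ms_err), p_uncorrected=p_unc,
        mauchly_W=W, mauchly_p=p_m, gg_epsilon=eps, p_gg=p_gg,
        partial_eta_sq=float(peta), n_subjects=n, degenerate=degenerate,
    )


def bonferroni_pairwise(table, parameter: str | None = None) -> PairwiseTable:
    """Paired t-tests over the 6 condition pairs, p multiplied by the
    number of comparisons and capped at 1."""
    if isinstance(table, ConditionTable):
        df = table.complete(parameter)
    else:
        df = pd.DataFrame(np.asarray(table, float), columns=list(CONDITIONS)).dropna()
    pairs = list(itertools.combinations(df.columns, 2))
    n_comp = len(pairs)
    rows = []
    for a, b in pairs:
        x, y = df[a].to_numpy(float), df[b].to_numpy(float)
        diff = x - y
        if np.allclose(diff.std(ddof=1), 0.0):
            t, p = (0.0, 1.0) if np.allclose(diff.mean(), 0) else (np.inf, 0.0)
        else:
            t, p = sps.ttest_rel(x, y)
        rows.append({
            "a": a, "b": b, "mean_diff": float(diff.mean()),
            "t": float(t), "p_raw": float(p),
            "p_bonferroni": float(min(1.0, n_comp * p)),
        })
    return PairwiseTable(parameter=parameter or "", table=pd.DataFrame(rows))


def spearman(x, y) -> CorrelationResult:
    """Spearman rank correlation (average ranks for ties, large-sample p).

    Applied to pooled trial-level data: wrist path length against each of
    the segmented temporal components.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    keep = ~(np.isnan(x) | np.isnan(y))
    x, y = x[keep], y[keep]
    if x.size < 3:
        raise ValueError("need at least 3 paired observations")
    rho, p = sps.spearmanr(x, y)
    return CorrelationResult(rho=float(rho), p=float(p), n=int(x.size))


def quartile_drift(metrics: pd.DataFrame, n_trials: int = 64) -> dict:
    """Performance drift over the session, collapsed across conditions.

    Trials are split by their position in the sequence into four quartiles
    (1-16, 17-32, 33-48, 49-64 at the default session length). Returns the
    per-quartile parameter means and, for each parameter, a paired
    first-vs-last-quartile comparison on the per-participant quartile
    means.
    """
    if n_trials % 4:
        raise ValueError("n_trials must be divisible by 4")
    df = metrics.copy()
    if (df["trial_index"] < 1).any() or (df["trial_index"] > n_trials).any():
        raise ValueError(f"trial_index must lie in 1..{n_trials}")
    q_size = n_trials // 4
    df["quartile"] = (df["trial_index"] - 1) // q_size + 1
    params = [p for p in PARAMETERS if p in df.columns]
    summary = df.groupby("quartile")[params].mean()

    first_last = []
    for p in params:
        per = df.pivot_table(index="participant_id", columns="quartile",
                             values=p, aggfunc="mean")
        if 1 not in per.columns or 4 not in per.columns:
            continue
        pair = per[[1, 4]].dropna()
        d = pair[1].to_numpy(float) - pair[4].to_numpy(float)
        if len(d) >= 2 and d.std(ddof=1) > 0:
            t, pval = sps.ttest_rel(pair[1], pair[4])
        else:
            t, pval = 0.0, 1.0
        first_last.append({
            "parameter": p,
            "mean_first": float(pair[1].mean()) if len(pair) else np.nan,
            "mean_last": float(pair[4].mean()) if len(pair) else np.nan,
            "mean_diff_first_minus_last": float(d.mean()) if len(d) else np.nan,
            "t": float(t), "p": float(pval), "n": int(len(d)),
        })
    return {"quartile_means": summary, "first_vs_last": pd.DataFrame(first_last)}
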