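"""Behavioral analyses: response tabulation and within-subject ANOVA.

The tabulation mirrors the study's response-frequency reporting: per
participant (optionally per session) counts and percentages for each of the
ten response categories, with headline accuracy counting only first-attempt
correct responses (no-response and self-corrected trials count as
incorrect).

The one-way repeated-measures ANOVA compares per-session counts across the
three sessions.  Sphericity is assessed with Mauchly's W (chi-square
approximation on orthonormal contrasts of the condition covariance); when
it is rejected at alpha = 0.05 the Greenhouse-Geisser epsilon deflates both
degrees of freedom and the corrected p-value is reported.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .session_model import EEGSession, ResponseCategory

SPHERICITY_ALPHA = 0.05


@dataclass
class ResponseTabulation:
    """Counts and percentages per response category.

    ``counts``/``percentages``: rows = the ten categories, columns = session
    indices plus "overall".  Percentages are of scored trials per column and
    sum to 100 up to rounding.  ``accuracy`` is the overall fraction of
    CORRECT trials.
    """

    counts: pd.DataFrame
    percentages: pd.DataFrame
    accuracy: float
    n_trials: int
    participant_id: str = ""

    def to_tsv(self, path) -> None:
        out = self.percentages.copy()
        out.index = [c.name for c in ResponseCategory]
        out.to_csv(path, sep="\t", float_format="%.1f")


def tabulate_responses(sessions: Sequence[EEGSession]) -> ResponseTabulation:
    """Tabulate one participant's scored trials per session and overall."""
    if not sessions or all(len(s.trials) == 0 for s in sessions):
        raise ValueError("no scored trials to tabulate")
    cats = list(ResponseCategory)
    cols = {}
    for sess in sessions:
        codes = [t.category for t in sess.trials]
        cols[f"session{sess.session_index}"] = [
            sum(c == cat for c in codes) for cat in cats
        ]
    counts = pd.DataFrame(cols, index=[int(c) for c in cats])
    counts["overall"] = counts.sum(axis=1)
    pct = 100.0 * counts / counts.sum(axis=0)
    n = int(counts["overall"].sum())
    accuracy = counts.loc[int(ResponseCategory.CORRECT), "overall"] / n
    return ResponseTabulation(
        counts=counts,
        percentages=pct,
        accuracy=float(accuracy),
        n_trials=n,
        participant_id=sessions[0].participant_id,
    )


def category_counts_matrix(
    participants: Sequence[Sequence[EEGSession]],
    category: ResponseCategory,
) -> np.ndarray:
    """participants x sessions matrix of per-session counts of ``category``
    (the ANOVA input; for accuracy use CORRECT)."""
    rows = []
    for sessions in participants:
        ordered = sorted(sessions, key=lambda s: s.session_index)
        rows.append(
            [
                sum(t.category == category for t in s.trials)
                for s in ordered
            ]
        )
    return np.asarray(rows, dtype=float)


@dataclass(frozen=True)
class RmAnovaResult:
    """One-way within-subject ANOVA with sphericity diagnostics.

    Uncorrected df are (c-1, (c-1)(s-1)).  ``epsilon`` is the
    Greenhouse-Geisser estimate, bounded by [1/(c-1), 1]; corrected df and
    p are always computed, and ``use_corrected`` says whether the Mauchly
    test (alpha = 0.05) calls for reporting them.
    """

    F: float
    df_num: float
    df_den: float
    p: float
    mauchly_W: float
    mauchly_chi2: float
    mauchly_df: int
    p_sphericity: float
    epsilon: float
    df_num_corrected: float
    df_den_corrected: float
    p_corrected: float
    use_corrected: bool
    ss_conditions: float
    ss_subjects: float
    ss_error: float

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}

    def summary(self) -> str:
        sph = (
            f"Mauchly W={self.mauchly_W:.4f}, "
            f"X2({self.mauchly_df})={self.mauchly_chi2:.3f}, "
            f"p={self.p_sphericity:.3f}"
        )
        if self.use_corrected:
            return (
                f"{sph} (violated); Greenhouse-Geisser eps={self.epsilon:.3f}, "
                f"F({self.df_num_corrected:.2f},{self.df_den_corrected:.2f})="
                f"{self.F:.3f}, p={self.p_corrected:.3f}"
            )
        return (
            f"{sph} (met); F({self.df_num:.0f},{self.df_den:.0f})="
            f"{self.F:.3f}, p={self.p:.3f}"
        )


def _orthonormal_contrasts(c: int) -> np.ndarray:
    """c x (c-1) orthonormal basis of the contrast space (Helmert-style)."""
    raw = np.zeros((c, c - 1))
    for j in range(1, c):
        raw[:j, j - 1] = 1.0
        raw[j, j - 1] = -j
    return raw / np.linalg.norm(raw, axis=0)


def rm_anova_one_way(scores: np.ndarray) -> RmAnovaResult:
    """One-way repeated-measures ANOVA on a subjects x conditions matrix."""
    X = np.asarray(scores, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2 or X.shape[1] < 2:
        raise ValueError("need >= 2 subjects and >= 2 conditions, no missing cells")
    if np.isnan(X).any():
        raise ValueError("missing cells are not supported")
    s, c = X.shape
    grand = X.mean()
    subj_means = X.mean(axis=1)
    cond_means = X.mean(axis=0)
    ss_total = float(((X - grand) ** 2).sum())
    ss_subj = float(c * ((subj_means - grand) ** 2).sum())
    ss_cond = float(s * ((cond_means - grand) ** 2).sum())
    ss_err = ss_total - ss_subj - ss_cond
    df_num = c - 1
    df_den = (c - 1) * (s - 1)
    ms_cond = ss_cond / df_num
    ms_err = ss_err / df_den
    if ss_total == 0:
        raise ValueError("constant data: no variance to analyze")
    if ms_err <= 0:
        F = 0.0 if ss_cond == 0 else float("inf")
    else:
        F = ms_cond / ms_err
    p = float(stats.f.sf(F, df_num, df_den))

    # sphericity of the condition-difference covariance
    C = _orthonormal_contrasts(c)
    S = C.T @ np.cov(X, rowvar=False, ddof=1) @ C
    eig = np.linalg.eigvalsh(S)
    mean_eig = eig.mean()
    d = c - 1
    if mean_eig <= 0:
        # no between-condition difference variance: nothing to correct
        W, chi2, p_sph, eps = 1.0, 0.0, 1.0, 1.0
        chi2_df = int(c * (c - 1) / 2 - 1)
    else:
        W = float(np.prod(eig / mean_eig))
        correction = 1.0 - (2 * d * d + d + 2) / (6.0 * d * (s - 1))
        chi2 = float(
            -(s - 1) * correction * np.log(max(W, np.finfo(float).tiny))
        )
        chi2_df = int(c * (c - 1) / 2 - 1)
        p_sph = float(stats.chi2.sf(chi2, chi2_df)) if chi2_df > 0 else 1.0
        eps = float(np.trace(S) ** 2 / (d * np.trace(S @ S)))
        eps = min(1.0, max(eps, 1.0 / d))
    df_num_c = eps * df_num
    df_den_c = eps * df_den
    p_corr = float(stats.f.sf(F, df_num_c, df_den_c))

    return RmAnovaResult(
        F=float(F),
        df_num=float(df_num),
        df_den=float(df_den),
        p=p,
        mauchly_W=W,
        mauchly_chi2=chi2,
        mauchly_df=chi2_df,
        p_sphericity=p_sph,
        epsilon=eps,
        df_num_corrected=df_num_c,
        df_den_corrected=df_den_c,
        p_corrected=p_corr,
        use_corrected=p_sph < SPHERICITY_ALPHA,
        ss_conditions=ss_cond,
        ss_subjects=ss_subj,
        ss_error=ss_err,
    )
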