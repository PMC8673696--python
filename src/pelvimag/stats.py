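"""Grand averaging and paired third-trimester vs postpartum comparison.

Each subject's kept moderate-Kegel epochs are averaged into one value per
parameter per session (the grand average), giving paired samples across
subjects.  For each parameter the paired difference (pregnancy - postpartum)
is checked for normality with the Shapiro-Wilk test and compared with a
two-sided paired Student t-test at alpha = 0.05.  When the normality check
fails, the t-test is still reported (with a warning) alongside a Wilcoxon
signed-rank p-value as a supplementary check; no multiple-testing correction
is applied across the five parameters.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sstats

__all__ = [
    "PARAMETERS",
    "PairedStatsResult",
    "grand_average",
    "shapiro_wilk",
    "paired_ttest",
    "compare_sessions",
    "results_table",
]

logger = logging.getLogger(__name__)

#: contraction parameters carried through the paired analysis
PARAMETERS = ("rms_fT", "total_power", "rpsd_low", "rpsd_middle", "rpsd_high")

_PRE = "third_trimester"
_POST = "postpartum"


@dataclass
class PairedStatsResult:
    """Paired comparison of one parameter between sessions.

    ``t`` is computed on differences d = pre - post, so a positive ``t``
    means the parameter decreased from pregnancy to postpartum.  A zero
    difference variance makes the t-test degenerate; the result is flagged
    rather than reporting a silent 0/0.
    """

    parameter: str
    n_pairs: int
    mean_pre: float
    sd_pre: float
    mean_post: float
    sd_post: float
    shapiro_w: float
    shapiro_p: float
    t: float
    df: int
    p: float
    alpha: float = 0.05
    degenerate: bool = False
    wilcoxon_p: float | None = None

    @property
    def significant(self) -> bool:
        return (not self.degenerate) and self.p < self.alpha

    def to_dict(self) -> dict:
        d = dict(self.__dict__)
        d["significant"] = self.significant
        return d


def grand_average(
    features: pd.DataFrame,
    label: str = "MK",
    excluded_subjects: list[str] | None = None,
) -> pd.DataFrame:
    """Per-(subject, session) arithmetic means of the parameters.

    Only epochs with the analyzed exercise label enter the averages.
    Subjects excluded by quality control are omitted entirely (both
    sessions).  Returns one row per (subject, session) with an ``n_epochs``
    count.
    """
    df = features[features["label"] == label]
    if excluded_subjects:
        df = df[~df["subject"].isin(set(excluded_subjects))]
    if df.empty:
        return pd.DataFrame(columns=["subject", "session", *PARAMETERS, "n_epochs"])
    grouped = df.groupby(["subject", "session"], as_index=False)
    out = grouped[list(PARAMETERS)].mean()
    out["n_epochs"] = grouped.size()["size"]
    return out


def shapiro_wilk(values: np.ndarray) -> tuple[float, float]:
    """Shapiro-Wilk normality test (W statistic, p-value).

    Requires 3 <= n <= 5000 and non-constant data.
    """
    x = np.asarray(values, dtype=float)
    if not 3 <= len(x) <= 5000:
        raise ValueError("Shapiro-Wilk requires 3 <= n <= 5000")
    if np.ptp(x) == 0:
        raise ValueError("Shapiro-Wilk undefined for a constant sample")
    res = sstats.shapiro(x)
    return float(res.statistic), float(res.pvalue)


def paired_ttest(pre: np.ndarray, post: np.ndarray) -> tuple[float, int, float, bool]:
    """Two-sided paired Student t-test on differences d = pre - post.

    Returns (t, df, p, degenerate).  Zero difference variance (including
    identical pairs) is a degenerate case: flagged, with t and p set to NaN.
    """
    pre = np.asarray(pre, dtype=float)
    post = np.asarray(post, dtype=float)
    if pre.shape != post.shape or pre.ndim != 1 or len(pre) < 2:
        raise ValueError("paired t-test needs equal-length 1-D samples, n >= 2")
    d = pre - post
    n = len(d)
    df = n - 1
    sd = float(np.std(d, ddof=1))
    if sd == 0.0:
        logger.warning("paired t-test degenerate: zero difference variance")
        return float("nan"), df, float("nan"), True
    t = float(np.mean(d) / (sd / np.sqrt(n)))
    p = float(2.0 * sstats.t.sf(abs(t), df))
    return t, df, p, False


def compare_sessions(
    summaries: pd.DataFrame,
    alpha: float = 0.05,
    parameters: tuple[str, ...] = PARAMETERS,
) -> list[PairedStatsResult]:
    """Paired pregnancy-vs-postpartum comparison of every parameter.

    Subjects lacking either session are dropped (with a logged count); at
    least 2 complete pairs are required.  Each result carries session
    means +/- SD, the Shapiro-Wilk check on the paired differences, and the
    two-sided paired t-test; a failed normality check adds a Wilcoxon
    signed-rank p-value as supplementary output.
    """
    sessions = summaries.pivot_table(
        index="subject", columns="session", values=list(parameters)
    )
    complete = sessions.dropna()
    n_dropped = len(sessions) - len(complete)
    if n_dropped:
        logger.info("dropping %d subject(s) lacking a session pair", n_dropped)
    if len(complete) < 2:
        raise ValueError("paired comparison needs at least 2 complete subject pairs")

    results = []
    for param in parameters:
        pre = complete[(param, _PRE)].to_numpy()
        post = complete[(param, _POST)].to_numpy()
        d = pre - post
        try:
            w, sp = shapiro_wilk(d)
        except ValueError:
            w, sp = float("nan"), float("nan")
        t, dof, p, degenerate = paired_ttest(pre, post)
        wilcoxon_p = None
        if np.isfinite(sp) and sp < alpha and not degenerate:
            warnings.warn(
                f"{param}: paired differences fail normality (Shapiro p={sp:.3g}); "
                "reporting Wilcoxon signed-rank as supplementary",
                stacklevel=2,
            )
            wilcoxon_p = float(sstats.wilcoxon(pre, post).pvalue)
        results.append(
            PairedStatsResult(
                parameter=param,
                n_pairs=len(d),
                mean_pre=float(np.mean(pre)),
                sd_pre=float(np.std(pre, ddof=1)),
                mean_post=float(np.mean(post)),
                sd_post=float(np.std(post, ddof=1)),
                shapiro_w=w,
                shapiro_p=sp,
                t=t,
                df=dof,
                p=p,
                alpha=alpha,
                degenerate=degenerate,
                wilcoxon_p=wilcoxon_p,
            )
        )
    return results


def results_table(results: list[PairedStatsResult]) -> pd.DataFrame:
    """Stack paired-comparison results into one row per parameter."""
    return pd.DataFrame([r.to_dict() for r in results])
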