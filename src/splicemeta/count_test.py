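"""Count-based differential splicing arm: binomial likelihood-ratio test.

Each replicate's inclusion count is modelled as

    I_r ~ Binomial(I_r + S_r, theta_g),
    theta_g = lI psi_g / (lI psi_g + lS (1 - psi_g)),

i.e. the read-level inclusion proportion implied by the group inclusion level
psi_g after effective-length distortion.  The alternative fits separate
psi_fat, psi_thin; the null a shared psi.  The statistic
2 (llik_H1 - llik_H0) is referred to a chi-square with 1 df, and p-values are
Benjamini-Hochberg corrected within each study to call events at FDR < 0.05.

This is a plain binomial LRT, not a hierarchical replicate-variance model; an
optional beta-binomial variant absorbing extra-replicate dispersion can be
selected with ``overdispersed=True``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, special, stats
from statsmodels.stats.multitest import multipletests

from .events import EventKey

logger = logging.getLogger(__name__)

_EPS = 1e-9  # boundary clamp so log(0) never occurs

__all__ = ["CountStudyCall", "lrt_das_test", "bh_fdr", "call_das_count", "count_arm"]


@dataclass(frozen=True)
class CountStudyCall:
    """One event's count-arm result in one study."""

    event_key: EventKey
    study_id: str
    delta_psi: float
    lrt_stat: float
    p_value: float
    fdr: float
    significant: bool
    arm: str = "count"


def _theta(psi: np.ndarray | float, l_inc, l_skip):
    return l_inc * psi / (l_inc * psi + l_skip * (1.0 - psi))


def _loglik(psi, inc, skip, l_inc, l_skip, rho: float = 0.0) -> float:
    theta = _theta(psi, l_inc, l_skip)
    if rho > 0.0:
        # beta-binomial with mean theta, dispersion rho
        a = theta * (1.0 - rho) / rho
        b = (1.0 - theta) * (1.0 - rho) / rho
        n = inc + skip
        ll = (
            special.betaln(inc + a, skip + b)
            - special.betaln(a, b)
            + special.gammaln(n + 1)
            - special.gammaln(inc + 1)
            - special.gammaln(skip + 1)
        )
        return float(np.sum(ll))
    return float(np.sum(inc * np.log(theta) + skip * np.log(1.0 - theta)))


def _fit_psi(inc, skip, l_inc, l_skip, rho: float = 0.0) -> tuple[float, float]:
    """Bounded 1-D ML estimate of psi; returns (psi_hat, loglik)."""
    res = optimize.minimize_scalar(
        lambda psi: -_loglik(psi, inc, skip, l_inc, l_skip, rho),
        bounds=(_EPS, 1.0 - _EPS),
        method="bounded",
        options={"xatol": 1e-8},
    )
    return float(res.x), -float(res.fun)


def lrt_das_test(
    inc_fat,
    skip_fat,
    inc_thin,
    skip_thin,
    eff_len_inclusion: float,
    eff_len_skipping: float,
    overdispersion: float = 0.0,
) -> tuple[float, float, float]:
    """Likelihood-ratio test of equal inclusion level between the two groups.

    Arguments are per-replicate count vectors and the (shared) effective
    lengths.  Returns ``(delta_psi, lrt_stat, p_value)`` where delta_psi is
    the difference of the per-group ML inclusion levels (fat minus thin) and
    the p-value comes from the chi-square(1) upper tail.
    """
    inc_fat = np.asarray(inc_fat, dtype=float)
    skip_fat = np.asarray(skip_fat, dtype=float)
    inc_thin = np.asarray(inc_thin, dtype=float)
    skip_thin = np.asarray(skip_thin, dtype=float)
    for arr in (inc_fat, skip_fat, inc_thin, skip_thin):
        if (arr < 0).any():
            raise ValueError("read counts must be non-negative")
    if inc_fat.sum() + skip_fat.sum() == 0 or inc_thin.sum() + skip_thin.sum() == 0:
        raise ValueError("each group needs at least one replicate with reads")

    li, ls = float(eff_len_inclusion), float(eff_len_skipping)
    rho = float(overdispersion)
    psi_fat, ll_fat = _fit_psi(inc_fat, skip_fat, li, ls, rho)
    psi_thin, ll_thin = _fit_psi(inc_thin, skip_thin, li, ls, rho)
    _, ll_null = _fit_psi(
        np.concatenate([inc_fat, inc_thin]),
        np.concatenate([skip_fat, skip_thin]),
        li,
        ls,
        rho,
    )
    stat = max(0.0, 2.0 * (ll_fat + ll_thin - ll_null))
    p_value = float(stats.chi2.sf(stat, df=1))
    return psi_fat - psi_thin, stat, p_value


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, in input order, clipped to 1."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def call_das_count(tests: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Attach per-study BH FDR and the significance verdict (FDR < alpha).

    ``tests`` columns: event_id, study_id, delta_psi, stat, p_value.  FDR is
    computed within each study across all of that study's tested events; the
    strict inequality FDR < alpha defines a differential call.
    """
    if tests.empty:
        out = tests.copy()
        out["fdr"] = pd.Series(dtype=float)
        out["significant"] = pd.Series(dtype=bool)
        out["arm"] = pd.Series(dtype=str)
        return out
    out = tests.copy()
    out["fdr"] = (
        out.groupby("study_id", group_keys=False)["p_value"].transform(bh_fdr)
    )
    out["significant"] = out["fdr"] < alpha
    out["arm"] = "count"
    return out


def count_arm(
    psi_counts: pd.DataFrame,
    alpha: float = 0.05,
    overdispersion: float = 0.0,
) -> pd.DataFrame:
    """Run the count arm over an annotated count table (all studies).

    ``psi_counts`` is the output of :func:`splicemeta.psi.psi_table`: one row
    per replicate with counts, group and effective lengths.  Events where a
    group has no reads in a study are skipped with a log message.  Returns
    the per-(event, study) call table with FDR and significance.
    """
    rows = []
    for (eid, study), sub in psi_counts.groupby(["event_id", "study_id"], sort=True):
        fat = sub[sub["group"] == "fat"]
        thin = sub[sub["group"] == "thin"]
        totals_fat = fat["inclusion_count"].sum() + fat["skipping_count"].sum()
        totals_thin = thin["inclusion_count"].sum() + thin["skipping_count"].sum()
        if len(fat) == 0 or len(thin) == 0 or totals_fat == 0 or totals_thin == 0:
            logger.info("count arm: skipping %s in %s (a group has no reads)", eid, study)
            continue
        delta, stat, p = lrt_das_test(
            fat["inclusion_count"].to_numpy(),
            fat["skipping_count"].to_numpy(),
            thin["inclusion_count"].to_numpy(),
            thin["skipping_count"].to_numpy(),
            float(sub["eff_len_inclusion"].iloc[0]),
            float(sub["eff_len_skipping"].iloc[0]),
            overdispersion=overdispersion,
        )
        rows.append(
            {"event_id": eid, "study_id": study, "delta_psi": delta, "stat": stat, "p_value": p}
        )
    tests = pd.DataFrame(rows, columns=["event_id", "study_id", "delta_psi", "stat", "p_value"])
    return call_das_count(tests, alpha=alpha)
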