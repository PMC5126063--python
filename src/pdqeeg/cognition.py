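"""Normative z-scoring, domain scores, overall cognitive score and the
change index of the overall cognitive score (CI-OCS).

Raw test scores are normalised against a normative table (mean, SD,
direction per test).  Lower-is-better measures (times, errors, omissions,
time ratios) are sign-flipped so every z-score is higher-is-better.  Each
domain score is the mean of its member tests' z-scores; the overall
cognitive score (OCS) is the unweighted mean of all 14 z-scores (not the
mean of domain means).  The outcome statistic is

    CI-OCS_i = (OCS_followup,i - OCS_baseline,i) / SE_diff

a reliable-change-type index.  ``SE_diff`` defaults to the cohort standard
deviation of the paired OCS differences; the Jacobson–Truax variant
(sqrt(2)*SEM from a test-retest reliability) is available when a
reliability coefficient is supplied.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .battery import DOMAINS, TESTS, tests_in_domain

logger = logging.getLogger(__name__)


def normalize_to_norms(raw: pd.DataFrame, norms: pd.DataFrame) -> pd.DataFrame:
    """z = ±(raw - mean)/sd per test; sign flipped for lower-is-better tests."""
    missing = [t for t in TESTS if t not in norms.index]
    if missing:
        raise KeyError(f"normative table lacks tests: {missing}")
    if (norms.loc[list(TESTS), "sd"] <= 0).any():
        bad = norms.index[norms["sd"] <= 0].tolist()
        raise ValueError(f"non-positive normative SD for: {bad}")
    z = pd.DataFrame(index=raw.index)
    for t in TESTS:
        if t not in raw.columns:
            raise KeyError(f"raw table lacks test column {t!r}")
        m, s, hib = norms.loc[t, "mean"], norms.loc[t, "sd"], norms.loc[t, "higher_is_better"]
        sign = 1.0 if hib else -1.0
        z[t] = sign * (raw[t] - m) / s
    return z


def domain_and_overall_scores(z: pd.DataFrame) -> pd.DataFrame:
    """Six domain means plus OCS; subjects with any missing test are dropped."""
    complete = z[list(TESTS)].notna().all(axis=1)
    if not complete.all():
        dropped = z.index[~complete].tolist()
        logger.warning("dropping %d subject(s) with missing tests: %s", len(dropped), dropped)
    zc = z.loc[complete, list(TESTS)]
    out = pd.DataFrame(index=zc.index)
    for d in DOMAINS:
        out[d] = zc[tests_in_domain(d)].mean(axis=1)
    out["ocs"] = zc.mean(axis=1)
    return out


@dataclass
class ChangeIndex:
    ci_ocs: pd.Series      # per subject, unitless
    se_diff: float         # score units


def change_index(
    ocs_baseline: pd.Series,
    ocs_followup: pd.Series,
    reliability: float | None = None,
) -> ChangeIndex:
    """Paired OCS change divided by the standard error of the difference.

    With ``reliability`` r given, SE_diff = sqrt(2) * SD_baseline * sqrt(1-r)
    (Jacobson–Truax); otherwise SE_diff is the cohort SD of the paired
    differences, which is computable from the data alone.
    """
    common = ocs_baseline.index.intersection(ocs_followup.index)
    if len(common) < 4:
        raise ValueError("need both visits for at least 4 subjects")
    diff = ocs_followup.loc[common] - ocs_baseline.loc[common]
    if reliability is None:
        se = float(diff.std(ddof=1))
    else:
        if not 0 <= reliability < 1:
            raise ValueError("reliability must lie in [0, 1)")
        se = float(np.sqrt(2.0) * ocs_baseline.loc[common].std(ddof=1) * np.sqrt(1 - reliability))
    if se <= 0 or not np.isfinite(se):
        raise ValueError("zero variance of paired differences: change index undefined")
    return ChangeIndex(ci_ocs=diff / se, se_diff=se)


def score_visits(
    raw_baseline: pd.DataFrame,
    raw_followup: pd.DataFrame,
    norms: pd.DataFrame,
) -> tuple[pd.DataFrame, pd.DataFrame, ChangeIndex]:
    """Raw two-visit tables -> per-visit profiles + CI-OCS."""
    prof_bl = domain_and_overall_scores(normalize_to_norms(raw_baseline, norms))
    prof_fu = domain_and_overall_scores(normalize_to_norms(raw_followup, norms))
    ci = change_index(prof_bl["ocs"], prof_fu["ocs"])
    return prof_bl, prof_fu, ci
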