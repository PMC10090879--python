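"""Focal-observation behaviour rates and the between-method comparison.

Focal follows yield two kinds of rate per individual:

* instantaneous (scan) rates -- scans engaged in a behaviour over total
  scans, pooled across the individual's follows;
* continuous grooming rates -- seconds spent giving/receiving grooming over
  total observation seconds.

For comparison with collar-derived budgets, the two are reconciled into a
six-behaviour rate vector summing to one: the grooming entries come from the
continuous estimates and the four non-grooming scan rates are rescaled to
fill the remainder.  Methods are then compared per behaviour across
individuals with Spearman rank correlations (are the methods ordered alike?)
and two-sided Wilcoxon signed-rank tests (is one method systematically
higher?).
"""

from __future__ import annotations

import itertools
import logging

import numpy as np
import pandas as pd
from scipy import stats

from .types import BEHAVIOURS, FocalRecord

logger = logging.getLogger(__name__)

GROOMING = ("giving_grooming", "receiving_grooming")
NON_GROOMING = tuple(b for b in BEHAVIOURS if b not in GROOMING)

#: Focal scan vocabulary mapped onto the state behaviours; scans may also
#: carry "other_social" or similar codes outside the six states.
_SCAN_TO_STATE = {b: b for b in BEHAVIOURS}


def instantaneous_rates(
    focals: list[FocalRecord],
    include_other_in_denominator: bool = False,
) -> pd.DataFrame:
    """Scan-based behaviour rates per individual.

    Scans are pooled over each individual's follows; scans outside the six
    state behaviours are excluded from the denominator by default (set
    ``include_other_in_denominator`` to keep them in).
    """
    rows = []
    for ind, recs in _by_individual(focals).items():
        scans = [b for r in recs for _, b in r.scans]
        n_state = sum(b in _SCAN_TO_STATE for b in scans)
        n_other = len(scans) - n_state
        denom = len(scans) if include_other_in_denominator else n_state
        if denom == 0:
            logger.warning("individual %s has no usable scans; omitted", ind)
            continue
        if n_other:
            logger.info("individual %s: %d non-state scans (%s denominator)",
                        ind, n_other, "in" if include_other_in_denominator else "out of")
        for beh in BEHAVIOURS:
            rows.append({"individual_id": ind, "behaviour": beh,
                         "rate": sum(b == beh for b in scans) / denom})
    return pd.DataFrame(rows)


def continuous_grooming_rates(focals: list[FocalRecord]) -> pd.DataFrame:
    """Give/receive grooming rates per individual from continuous bout data.

    Rate = total bout seconds per role / total observation seconds.
    Overlapping bouts within a follow are an error (grooming roles are
    mutually exclusive states).
    """
    rows = []
    for ind, recs in _by_individual(focals).items():
        tot = sum(r.duration_s for r in recs)
        sec = {"give": 0.0, "receive": 0.0}
        for r in recs:
            bouts = sorted(r.grooming_bouts, key=lambda b: b[1])
            for (_, _, e0), (_, s1, _) in zip(bouts, bouts[1:]):
                if s1 < e0:
                    raise ValueError(
                        f"overlapping grooming bouts in a follow of {ind}")
            for role, s, e in bouts:
                sec[role] += e - s
        rows.append({"individual_id": ind,
                     "give_rate": sec["give"] / tot,
                     "receive_rate": sec["receive"] / tot})
    return pd.DataFrame(rows)


def normalize_focal_rates(
    instantaneous: pd.DataFrame,
    grooming: pd.DataFrame,
) -> pd.DataFrame:
    """Reconcile scan and continuous rates into six rates summing to one.

    Grooming rates are taken from the continuous estimates; the four
    non-grooming scan rates are rescaled to fill 1 - (give + receive).
    """
    groom = grooming.set_index("individual_id")
    inst = instantaneous.pivot(index="individual_id", columns="behaviour",
                               values="rate")
    rows = []
    for ind in inst.index:
        if ind not in groom.index:
            logger.warning("individual %s lacks continuous data; dropped", ind)
            continue
        give = float(groom.loc[ind, "give_rate"])
        receive = float(groom.loc[ind, "receive_rate"])
        if give + receive >= 1:
            raise ValueError(f"grooming rates of {ind} sum to >= 1")
        non_groom = inst.loc[ind, list(NON_GROOMING)].to_numpy(float)
        scale = (1.0 - give - receive) / non_groom.sum() if non_groom.sum() > 0 else 0.0
        rates = dict(zip(NON_GROOMING, non_groom * scale))
        rates["giving_grooming"] = give
        rates["receiving_grooming"] = receive
        for beh in BEHAVIOURS:
            rows.append({"individual_id": ind, "behaviour": beh,
                         "method": "focal", "rate": rates[beh]})
    return pd.DataFrame(rows)


def accel_rates(budget_table: pd.DataFrame, window: str = "day_07_17") -> pd.DataFrame:
    """Per-individual accelerometer rates for one clock window.

    Proportions already exclude unclassified seconds; they are renormalised
    defensively so the six rates sum to exactly one.
    """
    sub = budget_table.loc[(budget_table["window"] == window)
                           & budget_table["behaviour"].isin(BEHAVIOURS)]
    if sub.empty:
        raise ValueError(f"budget table has no window {window!r}")
    rows = []
    for ind, grp in sub.groupby("individual_id"):
        props = grp.set_index("behaviour")["proportion"]
        total = float(props.sum())
        for beh in BEHAVIOURS:
            rows.append({"individual_id": ind, "behaviour": beh,
                         "method": "accel",
                         "rate": float(props.get(beh, 0.0)) / total if total else np.nan})
    return pd.DataFrame(rows)


def spearman_exact_p(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided exact permutation p for Spearman's rho (tie-free, small n).

    Enumerates all n! rank permutations; feasible for n <= 9.
    """
    n = len(x)
    if n > 9:
        raise ValueError("exact enumeration restricted to n <= 9")
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    denom = n * (n * n - 1)
    obs = abs(1.0 - 6.0 * ((rx - ry) ** 2).sum() / denom)
    ranks = np.array(list(itertools.permutations(range(1, n + 1))), dtype=float)
    rhos = 1.0 - 6.0 * ((ranks - rx) ** 2).sum(axis=1) / denom
    return float((np.abs(rhos) >= obs - 1e-12).mean())


def compare_methods(rates: pd.DataFrame, min_n: int = 5) -> pd.DataFrame:
    """Spearman and Wilcoxon comparison of focal versus collar rates.

    Expects a long rate table with columns individual_id, behaviour, method
    ("focal"/"accel") and rate.  Per behaviour, individuals present under
    both methods are paired; the Spearman p is exact (full permutation null)
    for tie-free samples of n <= 9 and t-approximate otherwise; the Wilcoxon
    signed-rank test is two-sided with the normal approximation, zero
    differences dropped, reporting a signed Z (positive when focal exceeds
    accel on the rank-sum balance).
    """
    wide = rates.pivot_table(index=["behaviour", "individual_id"],
                             columns="method", values="rate")
    rows = []
    for beh in BEHAVIOURS:
        if beh not in wide.index.get_level_values(0):
            continue
        sub = wide.loc[beh].dropna()
        n = len(sub)
        if n < min_n:
            logger.warning("behaviour %s has only %d paired individuals; skipped",
                           beh, n)
            continue
        f = sub["focal"].to_numpy(float)
        a = sub["accel"].to_numpy(float)
        rho = float(stats.spearmanr(f, a).statistic)
        tie_free = (len(np.unique(f)) == n) and (len(np.unique(a)) == n)
        if n <= 9 and tie_free:
            p_rho = spearman_exact_p(f, a)
        else:
            p_rho = float(stats.spearmanr(f, a).pvalue)
        d = f - a
        if np.all(d == 0):
            w_stat = w_z = w_p = float("nan")
            logger.warning("behaviour %s: all paired differences zero; "
                           "Wilcoxon test degenerate", beh)
        else:
            res = stats.wilcoxon(f, a, zero_method="wilcox", method="approx",
                                 correction=False)
            w_stat = float(res.statistic)
            # scipy's two-sided zstatistic is based on min(T+, T-) and hence
            # always non-positive; re-sign it so Z > 0 means focal > accel.
            nz = d[d != 0]
            r = stats.rankdata(np.abs(nz))
            t_plus = float(r[nz > 0].sum())
            t_minus = float(r[nz < 0].sum())
            w_z = float(np.sign(t_plus - t_minus) * abs(res.zstatistic))
            w_p = float(res.pvalue)
        rows.append({"behaviour": beh, "spearman_rho": rho, "spearman_p": p_rho,
                     "wilcoxon_statistic": w_stat, "wilcoxon_z": w_z,
                     "wilcoxon_p": w_p, "n": n})
    return pd.DataFrame(rows)


def _by_individual(focals: list[FocalRecord]) -> dict[str, list[FocalRecord]]:
    out: dict[str, list[FocalRecord]] = {}
    for r in focals:
        out.setdefault(r.individual_id, []).append(r)
    return out
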