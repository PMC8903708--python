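"""Survival stratification and gene-set over-representation.

Expression-based dichotomization (median split by default, tertile extremes
as an alternative), Kaplan-Meier product-limit estimation, the two-group
log-rank test, and hypergeometric over-representation analysis with BH
correction.  KM and log-rank computations are delegated to lifelines and
validated in the test suite against hand-worked product-limit and O/E/V
tables.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank
from scipy import stats
from statsmodels.stats.multitest import multipletests

from circscreen.errors import AnalysisError, ParseError
from circscreen.iolib import GeneSetCollection, SurvivalTable


def dichotomize_by_expression(
    table: SurvivalTable, rule: str = "median"
) -> dict[str, str]:
    """Split subjects into expression strata.

    ``median``: high iff expression > cohort median (the median itself is
    low).  ``tertile``: top third high, bottom third low, middle excluded
    from the returned mapping.
    """
    df = table.table
    if len(df) < 2:
        raise AnalysisError("need >= 2 subjects to dichotomize")
    expr = df["expression"].to_numpy(dtype=float)
    if np.all(expr == expr[0]):
        raise AnalysisError("expression is identical across subjects; cannot split")
    ids = df["subject_id"].astype(str).tolist()
    if rule == "median":
        med = float(np.median(expr))
        return {i: ("high" if e > med else "low") for i, e in zip(ids, expr)}
    if rule == "tertile":
        n = len(ids)
        third = n // 3
        order = np.argsort(expr, kind="stable")
        out: dict[str, str] = {}
        for j in order[:third]:
            out[ids[j]] = "low"
        for j in order[n - third :]:
            out[ids[j]] = "high"
        return out
    raise AnalysisError(f"unknown dichotomization rule {rule!r}")


def split_survival(
    table: SurvivalTable, strata: dict[str, str]
) -> dict[str, SurvivalTable]:
    """Partition a survival table by a subject -> stratum mapping."""
    df = table.table
    out = {}
    for level in sorted(set(strata.values())):
        ids = [i for i, s in strata.items() if s == level]
        sub = df[df["subject_id"].astype(str).isin(ids)].reset_index(drop=True)
        out[level] = SurvivalTable(table=sub)
    return out


@dataclass
class KMEstimate:
    """Product-limit estimate: S(t) = prod_{t_i <= t} (1 - d_i / n_i)."""

    event_times: np.ndarray  # sorted distinct event times
    survival: np.ndarray  # S at each event time
    at_risk: np.ndarray  # n_i just before each event time
    events: np.ndarray  # d_i at each event time

    def survival_at(self, t: float) -> float:
        s = 1.0
        for ti, si in zip(self.event_times, self.survival):
            if ti <= t:
                s = si
            else:
                break
        return float(s)


def km_estimate(times: Sequence[float], events: Sequence[int]) -> KMEstimate:
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if (times <= 0).any():
        raise AnalysisError("survival times must be positive")
    kmf = KaplanMeierFitter()
    kmf.fit(times, event_observed=events)
    tab = kmf.event_table
    tab = tab[tab["observed"] > 0]
    event_times = tab.index.to_numpy(dtype=float)
    surv = np.array([float(kmf.survival_function_at_times(t).iloc[0]) for t in event_times])
    return KMEstimate(
        event_times=event_times,
        survival=surv,
        at_risk=tab["at_risk"].to_numpy(dtype=float),
        events=tab["observed"].to_numpy(dtype=float),
    )


@dataclass
class LogrankResult:
    chi_square: float
    p: float


def logrank_test(group_a: SurvivalTable, group_b: SurvivalTable) -> LogrankResult:
    """Standard two-group log-rank test (chi-square with 1 df)."""
    if len(group_a.table) == 0 or len(group_b.table) == 0:
        raise AnalysisError("both groups must be non-empty")
    if group_a.events.sum() + group_b.events.sum() == 0:
        raise AnalysisError("no events in either group; log-rank undefined")
    res = _ll_logrank(
        group_a.times, group_b.times,
        event_observed_A=group_a.events, event_observed_B=group_b.events,
    )
    return LogrankResult(chi_square=float(res.test_statistic), p=float(res.p_value))


@dataclass
class EnrichmentResult:
    set_name: str
    overlap: int
    set_size: int
    hit_count: int
    universe_size: int
    p: float
    q: Optional[float] = None


def ora_enrichment(
    hits: Sequence[str], sets: GeneSetCollection, alpha: float = 0.05
) -> list[EnrichmentResult]:
    """Upper-tail hypergeometric over-representation of each set in the hit
    list, BH-adjusted, sorted by p (ties by set name)."""
    universe = set(sets.universe)
    hits = list(dict.fromkeys(hits))
    outside = [h for h in hits if h not in universe]
    if outside:
        raise ParseError(f"hit {outside[0]!r} is not in the universe")
    n_hits = len(hits)
    m = len(universe)
    hitset = set(hits)
    out: list[EnrichmentResult] = []
    for name, members in sorted(sets.sets.items()):
        members = set(members)
        ov = len(members & hitset)
        # P(X >= ov) with X ~ Hypergeom(M=m, K=|set|, n=n_hits)
        p = float(stats.hypergeom.sf(ov - 1, m, len(members), n_hits))
        out.append(
            EnrichmentResult(
                set_name=name,
                overlap=ov,
                set_size=len(members),
                hit_count=n_hits,
                universe_size=m,
                p=min(p, 1.0),
            )
        )
    if out:
        _, q, _, _ = multipletests([r.p for r in out], method="fdr_bh")
        for r, qq in zip(out, q):
            r.q = float(qq)
    out.sort(key=lambda r: (r.p, r.set_name))
    return out
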