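"""Abundance filtering, two-group differential expression and qPCR fold change.

The screen keeps probes expressed above an FPKM-like threshold in a minimum
number of samples, then tests each probe between two groups with a Welch
(unequal-variance) two-tailed t-test on log2(value + pseudocount), reporting
``log2_fc`` as the difference of group log2 means, BH-adjusted q alongside
the raw p, and an up/down/ns call at the linear fold-change and raw-p
thresholds of the screening design (fold change > 2, p < 0.05).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from circscreen.errors import AnalysisError
from circscreen.iolib import ExpressionDataset


@dataclass
class DEResult:
    probe_id: str
    log2_fc: float  # mean log2(group A) - mean log2(group B)
    p: float
    q: Optional[float] = None
    call: str = "ns"  # up | down | ns

    @property
    def fold_change(self) -> float:
        return float(2.0**self.log2_fc)

    @property
    def neg_log10_p(self) -> float:
        return float(-np.log10(max(self.p, 1e-300)))


def filter_expressed(
    data: ExpressionDataset, min_value: float = 1.0, min_samples: int = 3
) -> ExpressionDataset:
    """Keep probes with value > ``min_value`` in at least ``min_samples``
    samples (the screen's "FPKM > 1, expressed in >= 3 samples" filter)."""
    n_ok = (data.values.to_numpy() > min_value).sum(axis=1)
    keep = [p for p, n in zip(data.probe_ids, n_ok) if n >= min_samples]
    if not keep:
        warnings.warn("abundance filter removed every probe")
        return ExpressionDataset(
            values=data.values.iloc[:0], groups=dict(data.groups), truth=data.truth
        )
    return data.subset_probes(keep)


def differential_expression(
    data: ExpressionDataset,
    group_a: str,
    group_b: str,
    pseudocount: float = 1.0,
) -> list[DEResult]:
    """Welch two-tailed t-test per probe on log2(value + pseudocount).

    Zero-variance degenerate probes follow the convention p = 1 when the
    group means are equal and p = 0 otherwise.
    """
    sa = data.samples_in_group(group_a)
    sb = data.samples_in_group(group_b)
    if len(sa) < 2 or len(sb) < 2:
        raise AnalysisError(
            f"groups must have >= 2 samples (got {group_a}:{len(sa)}, {group_b}:{len(sb)})"
        )
    la = np.log2(data.values[sa].to_numpy(dtype=float) + pseudocount)
    lb = np.log2(data.values[sb].to_numpy(dtype=float) + pseudocount)
    mean_a, mean_b = la.mean(axis=1), lb.mean(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        t, p = stats.ttest_ind(la, lb, axis=1, equal_var=False)
    p = np.asarray(p, dtype=float)
    degenerate = (la.var(axis=1) == 0) & (lb.var(axis=1) == 0)
    p[degenerate & (mean_a == mean_b)] = 1.0
    p[degenerate & (mean_a != mean_b)] = 0.0
    p = np.nan_to_num(p, nan=1.0)
    _, q, _, _ = multipletests(p, method="fdr_bh")
    return [
        DEResult(probe_id=pid, log2_fc=float(fa - fb), p=float(pp), q=float(qq))
        for pid, fa, fb, pp, qq in zip(data.probe_ids, mean_a, mean_b, p, q)
    ]


def classify_de(
    results: list[DEResult], fc_thresh: float = 2.0, p_thresh: float = 0.05
) -> list[DEResult]:
    """Call up/down/ns at linear fold change > ``fc_thresh`` (or < 1/thresh)
    and raw p < ``p_thresh``; q is reported but not used for the call, since
    the screening design's stated cutoff is on raw p."""
    if fc_thresh <= 0 or p_thresh <= 0:
        raise AnalysisError("thresholds must be positive")
    for r in results:
        fc = r.fold_change
        if r.p < p_thresh and fc > fc_thresh:
            r.call = "up"
        elif r.p < p_thresh and fc < 1.0 / fc_thresh:
            r.call = "down"
        else:
            r.call = "ns"
    return results


def ddct_fold_change(
    ct_target_case: float,
    ct_ref_case: float,
    ct_target_ctrl: float,
    ct_ref_ctrl: float,
) -> float:
    """Relative qPCR quantification: 2**(-ddCt) with
    ddCt = (Ct_target,case - Ct_ref,case) - (Ct_target,ctrl - Ct_ref,ctrl)."""
    for v in (ct_target_case, ct_ref_case, ct_target_ctrl, ct_ref_ctrl):
        if not np.isfinite(v):
            raise AnalysisError("Ct values must be finite")
    ddct = (ct_target_case - ct_ref_case) - (ct_target_ctrl - ct_ref_ctrl)
    return float(2.0**-ddct)
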