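"""Alternative-splicing classification, PSI quantification and differential
splicing with RIP-target intersection.

Event types follow the standard taxonomy: SE (skipped exon), A5SS/A3SS
(alternative 5'/3' splice site, strand-aware), RI (retained intron), MXE
(mutually exclusive exons); isoform pairs differing by more than one simple
event are reported as "complex" rather than force-fitted to a type.

PSI (percent spliced in) is estimated from inclusion vs skipping junction
counts with effective-length normalization:
``psi = (I/l_inc) / (I/l_inc + S/l_skip)``; for a skipped exon the inclusion
isoform contributes two junctions and the skipping isoform one, hence the
default effective lengths (2, 1).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from circscreen.errors import AnalysisError, ContractError
from circscreen.iolib import TranscriptModel


@dataclass
class AsEvent:
    """One splicing event with per-sample junction counts and, after
    differential analysis, PSI and test statistics."""

    event_id: str
    gene_id: str
    event_type: str  # SE | A5SS | A3SS | RI | MXE | none | complex
    inclusion_counts: dict[str, int]
    skipping_counts: dict[str, int]
    eff_len_inc: int = 2
    eff_len_skip: int = 1
    psi: dict[str, Optional[float]] = field(default_factory=dict)
    delta_psi: Optional[float] = None
    p: Optional[float] = None
    q: Optional[float] = None
    significant: bool = False


# synthdata builds count tables out of these records
AsEventCounts = AsEvent


@dataclass
class AsCountTable:
    """A collection of AS events plus the sample -> condition map."""

    events: list[AsEvent]
    condition_of: dict[str, str]
    truth: Optional[dict] = None


@dataclass
class AsClassification:
    event_type: str
    # index (within the isoform that carries it) of the exon involved, if any
    exon_index: Optional[int] = None
    # "a" if the distinguishing exon/segment belongs to iso_a, "b" otherwise
    orientation: Optional[str] = None


def classify_as_event(iso_a: TranscriptModel, iso_b: TranscriptModel) -> AsClassification:
    """Classify the splicing difference between two isoforms of one gene.

    Requires both isoforms on the same strand.  Returns ``none`` for
    identical exon sets and ``complex`` for multi-event differences.
    """
    if iso_a.strand != iso_b.strand:
        raise ContractError(
            f"{iso_a.transcript_id} vs {iso_b.transcript_id}: differing strands"
        )
    a, b = iso_a.exons, iso_b.exons
    if a == b:
        return AsClassification("none")
    if len(a) == len(b) + 1:
        res = _skipped_or_retained(a, b)
        if res is not None:
            t, idx = res
            return AsClassification(t, exon_index=idx, orientation="a")
    if len(b) == len(a) + 1:
        res = _skipped_or_retained(b, a)
        if res is not None:
            t, idx = res
            return AsClassification(t, exon_index=idx, orientation="b")
    if len(a) == len(b):
        res = _altss_or_mxe(a, b, iso_a.strand)
        if res is not None:
            return res
    return AsClassification("complex")


def _skipped_or_retained(long, short):
    """``long`` has one exon more than ``short``: SE if removing one internal
    exon of ``long`` yields ``short``; RI if ``short`` merges two adjacent
    exons of ``long`` across their intron."""
    n = len(long)
    for i in range(n):
        if long[:i] + long[i + 1 :] == short:
            if 0 < i < n - 1:  # internal exon with both flanks identical
                return ("SE", i)
            return None
    # retained intron: short[j] spans long[i] + long[i+1]
    for i in range(n - 1):
        merged = (long[i][0], long[i + 1][1])
        if long[:i] + [merged] + long[i + 2 :] == short:
            return ("RI", i)
    return None


def _altss_or_mxe(a, b, strand):
    diffs = [i for i, (ea, eb) in enumerate(zip(a, b)) if ea != eb]
    if len(diffs) != 1:
        return None
    i = diffs[0]
    ea, eb = a[i], b[i]
    if ea[0] == eb[0] and ea[1] != eb[1]:
        # 3' (right) boundary differs: donor end on +, acceptor end on -
        t = "A5SS" if strand == "+" else "A3SS"
        return AsClassification(t, exon_index=i, orientation="a" if ea[1] > eb[1] else "b")
    if ea[1] == eb[1] and ea[0] != eb[0]:
        t = "A3SS" if strand == "+" else "A5SS"
        return AsClassification(t, exon_index=i, orientation="a" if ea[0] < eb[0] else "b")
    # neither boundary shared: mutually exclusive if internal and disjoint
    internal = 0 < i < len(a) - 1
    disjoint = ea[1] < eb[0] or eb[1] < ea[0]
    if internal and disjoint:
        return AsClassification("MXE", exon_index=i)
    return None


def compute_psi(
    inclusion_count: float,
    skipping_count: float,
    eff_len_inc: int = 2,
    eff_len_skip: int = 1,
) -> Optional[float]:
    """Effective-length-normalized percent spliced in; None when both counts
    are zero (PSI undefined)."""
    if inclusion_count < 0 or skipping_count < 0:
        raise ContractError("junction counts must be non-negative")
    if eff_len_inc <= 0 or eff_len_skip <= 0:
        raise ContractError("effective lengths must be positive")
    if inclusion_count == 0 and skipping_count == 0:
        return None
    inc = inclusion_count / eff_len_inc
    skp = skipping_count / eff_len_skip
    return inc / (inc + skp)


def differential_splicing(
    table: AsCountTable,
    cond1: str = "cond1",
    cond2: str = "cond2",
    alpha: float = 0.05,
) -> list[AsEvent]:
    """Two-sided Fisher exact test on pooled (inclusion, skipping) counts per
    condition, BH-adjusted across events; fills per-sample PSI and
    ``delta_psi = mean PSI(cond2) - mean PSI(cond1)``.

    Events with zero total count are excluded with a warning.  Pooled counts
    are used because the generator's replicate numbers are small; per-sample
    PSI values are still reported for inspection.
    """
    samples1 = [s for s, c in table.condition_of.items() if c == cond1]
    samples2 = [s for s, c in table.condition_of.items() if c == cond2]
    if not samples1 or not samples2:
        raise AnalysisError(f"need >= 1 replicate in both {cond1!r} and {cond2!r}")
    kept: list[AsEvent] = []
    pvals: list[float] = []
    for ev in table.events:
        i1 = sum(ev.inclusion_counts.get(s, 0) for s in samples1)
        s1 = sum(ev.skipping_counts.get(s, 0) for s in samples1)
        i2 = sum(ev.inclusion_counts.get(s, 0) for s in samples2)
        s2 = sum(ev.skipping_counts.get(s, 0) for s in samples2)
        if i1 + s1 + i2 + s2 == 0:
            warnings.warn(f"{ev.event_id}: zero total junction count, excluded")
            continue
        for s in samples1 + samples2:
            ev.psi[s] = compute_psi(
                ev.inclusion_counts.get(s, 0),
                ev.skipping_counts.get(s, 0),
                ev.eff_len_inc,
                ev.eff_len_skip,
            )
        psi1 = [ev.psi[s] for s in samples1 if ev.psi[s] is not None]
        psi2 = [ev.psi[s] for s in samples2 if ev.psi[s] is not None]
        ev.delta_psi = (
            float(np.mean(psi2) - np.mean(psi1)) if psi1 and psi2 else None
        )
        _, p = stats.fisher_exact([[i1, s1], [i2, s2]], alternative="two-sided")
        ev.p = float(p)
        pvals.append(ev.p)
        kept.append(ev)
    if kept:
        _, qvals, _, _ = multipletests(pvals, method="fdr_bh")
        for ev, q in zip(kept, qvals):
            ev.q = float(q)
            ev.significant = ev.q < alpha
    return kept


def summarize_categories(events: Sequence[AsEvent]) -> dict[str, dict]:
    """Per-type counts and percentages among the given (typed) events,
    formatted as in a category-summary figure: "count/total (pct%)"."""
    total = len(events)
    out: dict[str, dict] = {}
    if total == 0:
        return out
    for ev in events:
        t = ev.event_type
        out.setdefault(t, {"count": 0})["count"] += 1
    for t, rec in out.items():
        pct = 100.0 * rec["count"] / total
        rec["percent"] = pct
        rec["label"] = f"{rec['count']}/{total} ({pct:.2f}%)"
    return out


@dataclass
class RipTargetSet:
    """Transcripts bound in an RNA-immunoprecipitation experiment."""

    transcript_ids: set[str]
    enrichment: Optional[dict[str, float]] = None

    def __post_init__(self) -> None:
        self.transcript_ids = set(self.transcript_ids)


def intersect_rip_targets(
    events: Sequence[AsEvent], rip: RipTargetSet
) -> list[AsEvent]:
    """Significant events whose gene/transcript is RIP-bound, ranked by
    |delta PSI| descending (ties by event id): candidate direct targets."""
    cand = [
        ev
        for ev in events
        if ev.significant and ev.gene_id in rip.transcript_ids and ev.delta_psi is not None
    ]
    return sorted(cand, key=lambda ev: (-abs(ev.delta_psi), ev.event_id))
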