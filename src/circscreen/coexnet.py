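"""From-scratch weighted co-expression network core.

An unsigned weighted network is built from pairwise Pearson correlations of
log2 expression profiles: adjacency ``a_ij = |cor(i,j)|**beta`` with the
soft-threshold power ``beta`` chosen by the scale-free topology criterion.
Topological overlap (shared-neighborhood similarity) turns the adjacency
into the TOM, whose dissimilarity ``1 - TOM`` is clustered by average
linkage; a static tree cut yields modules labeled by descending size with
WGCNA-style color names ("turquoise" = largest, "grey" = unassigned).
Module eigengenes (first principal components) are correlated with a binary
sample trait to flag trait-associated modules.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from circscreen.errors import AnalysisError, ContractError
from circscreen.iolib import ExpressionDataset

MODULE_COLORS = [
    "turquoise", "blue", "brown", "yellow", "green", "red", "black",
    "pink", "magenta", "purple", "greenyellow", "tan", "salmon", "cyan",
    "midnightblue", "lightcyan", "grey60", "lightgreen", "lightyellow",
    "royalblue", "darkred", "darkgreen", "darkturquoise", "darkgrey",
]
GREY = "grey"


def _log_matrix(data: ExpressionDataset, pseudocount: float = 1.0):
    """log2 expression matrix with zero-variance probes dropped (warned)."""
    x = np.log2(data.values.to_numpy(dtype=float) + pseudocount)
    var = x.var(axis=1)
    keep = var > 0
    if not keep.all():
        dropped = [p for p, k in zip(data.probe_ids, keep) if not k]
        warnings.warn(f"excluding {len(dropped)} constant probe(s): {dropped[:5]}")
    probes = [p for p, k in zip(data.probe_ids, keep) if k]
    return x[keep], probes


def adjacency_matrix(data: ExpressionDataset, power: int = 6) -> pd.DataFrame:
    """Unsigned adjacency |Pearson cor|**power with zero diagonal."""
    x, probes = _log_matrix(data)
    cor = np.corrcoef(x)
    adj = np.abs(cor) ** power
    np.fill_diagonal(adj, 0.0)
    return pd.DataFrame(adj, index=probes, columns=probes)


@dataclass
class SoftThresholdScan:
    powers: list[int]
    fit_r2: list[float]
    mean_connectivity: list[float]
    chosen_power: int


def soft_threshold_scan(
    data: ExpressionDataset,
    powers: Optional[list[int]] = None,
    r2_goal: float = 0.85,
    n_bins: int = 10,
) -> SoftThresholdScan:
    """Scale-free topology criterion for the soft-threshold power.

    For each power the connectivity distribution p(k) is binned into
    ``n_bins`` (>= 8) log-spaced bins and log10 p(k) regressed on
    log10 k; the chosen power is the smallest one whose fit R^2 reaches
    ``r2_goal``, falling back to the argmax when none does.
    """
    if powers is None:
        powers = list(range(1, 21))
    x, _ = _log_matrix(data)
    if x.shape[1] < 4:
        raise AnalysisError("need >= 4 samples for a meaningful correlation network")
    if n_bins < 8:
        raise AnalysisError("scale-free fit needs >= 8 connectivity bins")
    abscor = np.abs(np.corrcoef(x))
    np.fill_diagonal(abscor, 0.0)
    r2s: list[float] = []
    ks: list[float] = []
    for beta in powers:
        adj = abscor**beta
        k = adj.sum(axis=1)
        ks.append(float(k.mean()))
        r2s.append(_scale_free_r2(k, n_bins))
    chosen = None
    for beta, r2 in zip(powers, r2s):
        if r2 >= r2_goal:
            chosen = beta
            break
    if chosen is None:
        chosen = powers[int(np.argmax(r2s))]
    return SoftThresholdScan(
        powers=list(powers), fit_r2=r2s, mean_connectivity=ks, chosen_power=chosen
    )


def _scale_free_r2(k: np.ndarray, n_bins: int) -> float:
    k = k[k > 0]
    if k.size < 2 or k.max() == k.min():
        return 0.0
    edges = np.logspace(np.log10(k.min()), np.log10(k.max()), n_bins + 1)
    edges[-1] *= 1 + 1e-12
    counts, _ = np.histogram(k, bins=edges)
    centers = np.array(
        [k[(k >= lo) & (k < hi)].mean() if c > 0 else np.nan
         for lo, hi, c in zip(edges[:-1], edges[1:], counts)]
    )
    mask = counts > 0
    if mask.sum() < 3:
        return 0.0
    logk = np.log10(centers[mask])
    logp = np.log10(counts[mask] / counts.sum())
    slope, intercept, r, _, _ = stats.linregress(logk, logp)
    return float(r**2)


def topological_overlap(adjacency: pd.DataFrame) -> pd.DataFrame:
    """TOM_ij = (sum_u a_iu a_uj + a_ij) / (min(k_i, k_j) + 1 - a_ij), TOM_ii=1.

    Measures how much two nodes share network neighbors in addition to their
    direct connection; modules are clusters of high mutual overlap.
    """
    a = adjacency.to_numpy(dtype=float)
    if a.shape[0] != a.shape[1] or not np.allclose(a, a.T, atol=1e-12):
        raise ContractError("adjacency must be square and symmetric")
    if a.min() < 0 or a.max() > 1:
        raise ContractError("adjacency values must lie in [0,1]")
    if not np.allclose(np.diag(a), 0.0):
        raise ContractError("adjacency must have zero diagonal")
    k = a.sum(axis=1)
    shared = a @ a  # sum_u a_iu a_uj (diagonal u terms are zero-safe: a_ii = 0)
    denom = np.minimum.outer(k, k) + 1.0 - a
    tom = (shared + a) / denom
    np.fill_diagonal(tom, 1.0)
    return pd.DataFrame(tom, index=adjacency.index, columns=adjacency.columns)


@dataclass
class ModuleAssignment:
    modules: dict[str, str]  # probe -> color label ("grey" = unassigned)
    eigengenes: Optional[pd.DataFrame] = None  # module x sample
    linkage: Optional[np.ndarray] = None
    cut_height: Optional[float] = None

    def members(self, module: str) -> list[str]:
        return [p for p, m in self.modules.items() if m == module]

    @property
    def module_names(self) -> list[str]:
        """Non-grey module labels, largest first (ties by color precedence)."""
        sizes: dict[str, int] = {}
        for m in self.modules.values():
            if m != GREY:
                sizes[m] = sizes.get(m, 0) + 1

        def rank(m: str):
            idx = MODULE_COLORS.index(m) if m in MODULE_COLORS else len(MODULE_COLORS)
            return (-sizes[m], idx, m)

        return sorted(sizes, key=rank)


def detect_modules(
    tom: pd.DataFrame,
    min_module_size: int = 10,
    cut_rule: str = "gap",
    cut_quantile: float = 0.25,
) -> ModuleAssignment:
    """Average-linkage clustering of 1 - TOM with a static tree cut.

    ``cut_rule="gap"`` (default) cuts in the middle of the largest gap
    between consecutive merge heights in the upper half of the dendrogram:
    modular data shows a clear gap between within-module merges and the
    near-1 joins of unrelated clusters, while unstructured data has densely
    packed heights so the cut lands near the top and every cluster below it
    stays small (grey).  ``cut_rule="quantile"`` cuts at the
    ``cut_quantile`` quantile of merge heights instead.

    Clusters smaller than ``min_module_size`` become grey (unassigned).
    Labels are WGCNA-style colors assigned in decreasing size order
    (ties broken by the lexicographically smallest member probe id), so
    "turquoise" is always the largest module.
    """
    probes = list(tom.index)
    n = len(probes)
    if n < min_module_size:
        warnings.warn("fewer probes than min_module_size; all grey")
        return ModuleAssignment(modules={p: GREY for p in probes})
    dissim = 1.0 - tom.to_numpy(dtype=float)
    np.fill_diagonal(dissim, 0.0)
    dissim = np.clip((dissim + dissim.T) / 2.0, 0.0, None)
    z = hierarchy.linkage(squareform(dissim, checks=False), method="average")
    heights = z[:, 2]
    if cut_rule == "gap":
        hs = np.sort(heights)
        upper = hs[hs > np.quantile(hs, 0.5)]
        if upper.size < 2:
            cut = float(hs[-1])
        else:
            gaps = np.diff(upper)
            i = int(np.argmax(gaps))
            cut = float((upper[i] + upper[i + 1]) / 2.0)
    elif cut_rule == "quantile":
        cut = float(np.quantile(heights, cut_quantile))
    else:
        raise AnalysisError(f"unknown cut_rule {cut_rule!r}")
    labels = hierarchy.fcluster(z, t=cut, criterion="distance")
    clusters: dict[int, list[str]] = {}
    for p, lab in zip(probes, labels):
        clusters.setdefault(int(lab), []).append(p)
    sized = [
        members
        for members in clusters.values()
        if len(members) >= min_module_size
    ]
    sized.sort(key=lambda ms: (-len(ms), min(ms)))
    modules = {p: GREY for p in probes}
    for color, members in zip(MODULE_COLORS, sized):
        for p in members:
            modules[p] = color
    if len(sized) > len(MODULE_COLORS):
        for i, members in enumerate(sized[len(MODULE_COLORS):]):
            for p in members:
                modules[p] = f"module_{len(MODULE_COLORS) + i + 1}"
    return ModuleAssignment(modules=modules, linkage=z, cut_height=cut)


def module_eigengenes(
    data: ExpressionDataset, assignment: ModuleAssignment
) -> pd.DataFrame:
    """First principal component of each module's per-probe z-scored log2
    submatrix, unit variance, sign-oriented so the eigengene's mean
    correlation with its member probes is positive.  Returns module x sample."""
    x, probes = _log_matrix(data)
    idx = {p: i for i, p in enumerate(probes)}
    rows = {}
    for module in assignment.module_names:
        members = [p for p in assignment.members(module) if p in idx]
        sub = x[[idx[p] for p in members]]
        sd = sub.std(axis=1, ddof=0, keepdims=True)
        z = (sub - sub.mean(axis=1, keepdims=True)) / np.where(sd > 0, sd, 1.0)
        if z.shape[0] == 1:
            eig = z[0]
        else:
            u, s, vt = np.linalg.svd(z, full_matrices=False)
            eig = vt[0]
        eig = eig / eig.std(ddof=0)
        member_cor = np.array([np.corrcoef(eig, row)[0, 1] for row in z if row.std() > 0])
        if member_cor.size and member_cor.mean() < 0:
            eig = -eig
        rows[module] = eig
    return pd.DataFrame(rows, index=data.sample_ids).T


@dataclass
class TraitAssociation:
    module: str
    correlation: float
    p: float
    trait_up: bool


def module_trait_association(
    eigengenes: pd.DataFrame, trait: dict[str, int], alpha: float = 0.05
) -> list[TraitAssociation]:
    """Pearson correlation of each module eigengene with a 0/1 sample trait;
    two-sided p from the t-transform with n-2 df; a module is "trait-up"
    when correlation > 0 and p < ``alpha``."""
    samples = list(eigengenes.columns)
    missing = [s for s in samples if s not in trait]
    if missing:
        raise AnalysisError(f"trait undefined for samples {missing[:5]}")
    y = np.array([trait[s] for s in samples], dtype=float)
    if np.all(y == y[0]):
        raise AnalysisError("trait is constant across samples")
    out = []
    n = len(samples)
    for module in eigengenes.index:
        e = eigengenes.loc[module].to_numpy(dtype=float)
        r = float(np.corrcoef(e, y)[0, 1])
        r_c = min(max(r, -1.0), 1.0)
        if abs(r_c) == 1.0:
            p = 0.0
        else:
            t = r_c * np.sqrt((n - 2) / (1 - r_c**2))
            p = float(2 * stats.t.sf(abs(t), df=n - 2))
        out.append(TraitAssociation(module, r, p, trait_up=(r > 0 and p < alpha)))
    return out
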