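"""Seeded generators for every input the screening pipeline consumes.

Each generator is a pure function of its config (including the seed) and
emits the statistical structure the downstream analysis assumes:

* expression matrices with latent-factor co-expression modules, planted
  trait-upregulated modules and fold-change spikes, over a 3 NPC / 5 IgD /
  5 IgG sample design;
* circular RNA sequences with a planted AUG-initiated ORF of a chosen
  product length, including rolling-circle ORFs whose coding span exceeds
  the circle length (the canonical fixture: a 1733-nt circle, IRES at
  201-374, encoding a 603-aa product across the back-splice junction);
* alternative-splicing junction-count tables with binomial counts around
  condition-specific true PSI values;
* survival cohorts whose hazard depends on dichotomized expression;
* gene-set collections with one planted over-represented set.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from circscreen import circorf
from circscreen.circorf import CircularTranscript, find_circular_orfs
from circscreen.errors import ConfigError, GenerationError
from circscreen.iolib import ExpressionDataset, GeneSetCollection, SurvivalTable
from circscreen.splicing import AsCountTable, AsEventCounts

_NT = np.array(list("ACGU"))

DEFAULT_GROUP_SIZES = {"NPC": 3, "IgD": 5, "IgG": 5}


# ---------------------------------------------------------------------------
# expression


@dataclass
class ExprSimConfig:
    """Configuration for the co-expression / differential-expression generator.

    Module members share one Gaussian latent factor per module with loading
    sqrt(within_module_cor), giving exact within-module correlation on the
    log scale; values are emitted on a linear FPKM-like scale (2**gaussian).
    The first ``n_igd_up_modules`` modules are trait-associated: their
    factors carry standardized group patterns (see the field comments
    below), planting the IgD-upregulated modules of the study design.
    """

    n_probes: int = 400
    group_sizes: dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_GROUP_SIZES)
    )
    n_modules: int = 7
    module_sizes: Optional[list[int]] = None
    within_module_cor: float = 0.7
    n_igd_up_modules: int = 2
    # Trait-associated modules carry the group signal inside their latent
    # factor: factor = a*t + sqrt(1-a^2)*z with a = trait_factor_cor and t a
    # standardized group pattern.  The first trait module uses an
    # IgD-specific pattern (NPC = IgG < IgD), the second a malignancy-graded
    # pattern (NPC < IgG < IgD); their residuals are anti-correlated exactly
    # enough to make the two factors uncorrelated, so the two trait modules
    # remain distinct co-expression modules.  Per-probe loading amplitudes
    # (trait_amplitude scaled by U(0.8, 1.2)) give heterogeneous per-probe
    # fold changes while preserving within_module_cor exactly.
    trait_factor_cor: float = 0.8
    trait_amplitude: float = 1.3
    igd_graded_level: float = 1.5  # IgD level of the graded pattern (IgG = 1)
    # per-probe group-specific log2 deviations (sd, relative to NPC) for
    # trait-module probes: each probe's own differential magnitude on top of
    # the shared module factor, as on a real array where hub probes carry
    # individually distinctive group contrasts
    trait_probe_sd: float = 1.2
    de_spec: list[tuple[Sequence[int], float, str]] = field(default_factory=list)
    noise_sd: float = 1.0
    baseline_log2_range: tuple[float, float] = (1.0, 6.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.module_sizes is None:
            self.module_sizes = [40] * self.n_modules
        if len(self.module_sizes) != self.n_modules:
            raise ConfigError(
                f"module_sizes has {len(self.module_sizes)} entries, expected n_modules={self.n_modules}"
            )
        if sum(self.module_sizes) > self.n_probes:
            raise ConfigError(
                f"sum(module_sizes)={sum(self.module_sizes)} exceeds n_probes={self.n_probes}"
            )
        if not 0.0 < self.within_module_cor < 1.0:
            raise ConfigError(
                f"within_module_cor={self.within_module_cor} must lie in (0,1)"
            )
        if self.n_igd_up_modules > self.n_modules:
            raise ConfigError("n_igd_up_modules exceeds n_modules")
        if self.noise_sd <= 0:
            raise ConfigError(f"noise_sd={self.noise_sd} must be positive")
        for g, n in self.group_sizes.items():
            if n < 1:
                raise ConfigError(f"group_sizes[{g}]={n} must be >= 1")


def gen_expression(config: ExprSimConfig) -> ExpressionDataset:
    """Simulate a probe x sample linear-scale expression matrix.

    Log2 signal = per-probe baseline + noise_sd * amplitude * (sqrt(c)*factor
    + sqrt(1-c)*noise) for module probes (c = within_module_cor); trait
    modules additionally carry per-probe group deviations, and probes listed
    in ``de_spec`` are shifted by their stated log2 fold change in the target
    group.  Ground truth (module labels, IgD-up modules, DE flags) is stored
    in ``truth``.
    """
    rng = np.random.default_rng(config.seed)
    groups: dict[str, str] = {}
    sample_ids: list[str] = []
    for g, n in config.group_sizes.items():
        for i in range(n):
            sid = f"{g}_{i + 1}"
            sample_ids.append(sid)
            groups[sid] = g
    n_samples = len(sample_ids)
    probe_ids = [f"probe_{i + 1:05d}" for i in range(config.n_probes)]

    baselines = rng.uniform(*config.baseline_log2_range, size=config.n_probes)
    log2x = np.tile(baselines[:, None], (1, n_samples)) + config.noise_sd * rng.normal(
        size=(config.n_probes, n_samples)
    )

    c = config.within_module_cor
    module_of = np.full(config.n_probes, "", dtype=object)
    igd_mask = np.array([groups[s] == "IgD" for s in sample_ids])
    mm_mask = np.array([groups[s] in ("IgD", "IgG") for s in sample_ids])

    def standardize(v: np.ndarray) -> np.ndarray:
        sd = v.std()
        return (v - v.mean()) / sd if sd > 0 else v - v.mean()

    # standardized group patterns for the trait-module factors
    t_igd = standardize(igd_mask.astype(float))
    t_graded = standardize(
        mm_mask.astype(float) + (config.igd_graded_level - 1.0) * igd_mask
    )
    a = config.trait_factor_cor
    trait_factors: list[np.ndarray] = []
    if config.n_igd_up_modules >= 1:
        z1 = rng.normal(size=n_samples)
        trait_factors.append(a * t_igd + np.sqrt(1 - a**2) * z1)
    if config.n_igd_up_modules >= 2:
        # residual anti-correlation cancels the shared trait component,
        # keeping the two trait factors (hence modules) as uncorrelated as
        # the residual budget allows (rho is clipped at -1, leaving a small
        # documented residual cross-correlation when trait_factor_cor is high)
        rho_t = float(np.mean(t_igd * t_graded))
        rho = max(-(a**2) * rho_t / (1 - a**2), -1.0)
        z2 = rho * z1 + np.sqrt(1 - rho**2) * rng.normal(size=n_samples)
        trait_factors.append(a * t_graded + np.sqrt(1 - a**2) * z2)
    for extra in range(2, config.n_igd_up_modules):
        z = rng.normal(size=n_samples)
        t = t_igd if extra % 2 == 0 else t_graded
        trait_factors.append(a * t + np.sqrt(1 - a**2) * z)

    pos = 0
    igd_up_modules: list[str] = []
    for m, size in enumerate(config.module_sizes):
        label = f"M{m + 1}"
        if m < config.n_igd_up_modules:
            factor = trait_factors[m]
            amplitude = config.trait_amplitude * rng.uniform(0.8, 1.2, size=size)
            igd_up_modules.append(label)
        else:
            factor = rng.normal(size=n_samples)
            amplitude = np.ones(size)
        noise = rng.normal(size=(size, n_samples))
        log2x[pos : pos + size] = baselines[
            pos : pos + size, None
        ] + config.noise_sd * amplitude[:, None] * (
            np.sqrt(c) * factor[None, :] + np.sqrt(1 - c) * noise
        )
        if m < config.n_igd_up_modules and config.trait_probe_sd > 0:
            d_igd = rng.normal(0, config.trait_probe_sd, size=size)
            d_igg = rng.normal(0, config.trait_probe_sd, size=size)
            igg_mask = mm_mask & ~igd_mask
            log2x[pos : pos + size][:, igd_mask] += d_igd[:, None]
            log2x[pos : pos + size][:, igg_mask] += d_igg[:, None]
        module_of[pos : pos + size] = label
        pos += size

    de_flags: dict[str, float] = {}
    for probe_set, log2fc, target_group in config.de_spec:
        if target_group not in config.group_sizes:
            raise ConfigError(f"de_spec target group {target_group!r} unknown")
        gmask = np.array([groups[s] == target_group for s in sample_ids])
        for p in probe_set:
            if not 0 <= p < config.n_probes:
                raise ConfigError(f"de_spec probe index {p} out of range")
            log2x[p, gmask] += log2fc
            de_flags[probe_ids[p]] = log2fc

    values = pd.DataFrame(
        np.power(2.0, log2x), index=probe_ids, columns=sample_ids
    )
    truth = {
        "module": dict(zip(probe_ids, module_of)),
        "igd_up_modules": igd_up_modules,
        "de_log2fc": de_flags,
    }
    return ExpressionDataset(values=values, groups=groups, truth=truth)


def default_expression_config(seed: int = 0) -> ExprSimConfig:
    """The study-design default: 3 NPC / 5 IgD / 5 IgG samples."""
    return ExprSimConfig(seed=seed)


def coexpression_preset(seed: int = 0) -> ExprSimConfig:
    """Module-recovery preset: 7 modules (first 2 IgD-up) over 48 samples.

    Planted-module recovery by topological-overlap clustering needs more
    samples than the 13-sample microarray design provides; this preset keeps
    the design's structure (fewest NPC, two IgD-upregulated modules among
    seven) at a cohort size where recovery is statistically possible.
    """
    return ExprSimConfig(
        n_probes=400,
        group_sizes={"NPC": 12, "IgD": 18, "IgG": 18},
        n_modules=7,
        module_sizes=[40] * 7,
        within_module_cor=0.7,
        n_igd_up_modules=2,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# circular ORFs


@dataclass
class OrfSpec:
    """Spec for planting one AUG-initiated ORF on a circle.

    If ``3*(product_length_aa+1) > circle_length`` the planted ORF's coding
    span exceeds the circle, so translation must cross the back-splice
    junction and re-read sequence in a shifted frame (rolling circle).
    """

    circle_length: int = 1733
    start_pos: int = 380
    product_length_aa: int = 603
    ires_interval: Optional[tuple[int, int]] = None
    seed: int = 0

    def __post_init__(self) -> None:
        if not 1 <= self.start_pos <= self.circle_length:
            raise ConfigError(
                f"start_pos={self.start_pos} outside 1..{self.circle_length}"
            )
        if self.product_length_aa < 1:
            raise ConfigError("product_length_aa must be >= 1")
        if self.circle_length < 3:
            raise ConfigError("circle_length must be >= 3")
        if self.ires_interval is not None:
            s, e = self.ires_interval
            if not 1 <= s <= e <= self.circle_length:
                raise ConfigError(f"ires_interval {self.ires_interval} outside the circle")


def gen_circle(spec: OrfSpec, circle_id: str = "circ_synthetic") -> CircularTranscript:
    """Construct a circle whose first in-frame stop after the planted AUG
    completes exactly ``product_length_aa`` codons.

    Constraint-satisfaction construction: the AUG and stop codon positions
    are fixed (projected to circular coordinates, so a rolling-circle stop
    may overlap earlier-frame codons), then unconstrained positions are
    re-randomized until no premature in-frame stop, no upstream in-frame AUG
    within the first traversal, and the ORF finder verifiably recovers the
    planted call.  Raises GenerationError when the constraints collide
    (e.g. the stop codon lands on the AUG with incompatible bases).
    """
    L = spec.circle_length
    N = spec.product_length_aa
    start0 = spec.start_pos - 1
    rng = np.random.default_rng(spec.seed)

    stop_positions = [(start0 + 3 * N + j) % L for j in range(3)]
    aug_positions = [(start0 + j) % L for j in range(3)]

    for stop_codon in circorf.STOP_CODONS:
        constraints: dict[int, str] = {}
        ok = True
        for p, nt in zip(aug_positions, "AUG"):
            if constraints.get(p, nt) != nt:
                ok = False
                break
            constraints[p] = nt
        if ok:
            for p, nt in zip(stop_positions, stop_codon):
                if constraints.get(p, nt) != nt:
                    ok = False
                    break
                constraints[p] = nt
        if not ok:
            continue
        seq = _fill_circle(constraints, L, start0, N, stop_codon, rng)
        if seq is not None:
            circ = CircularTranscript(
                id=circle_id,
                sequence=seq,
                circular=True,
                ires=spec.ires_interval,
            )
            if _verify_planted(circ, spec):
                return circ
    raise GenerationError(
        f"infeasible ORF spec: cannot place a {N}-codon ORF at {spec.start_pos} "
        f"on a {L}-nt circle without constraint collisions"
    )


def _fill_circle(
    constraints: dict[int, str],
    L: int,
    start0: int,
    n_codons: int,
    stop_codon: str,
    rng: np.random.Generator,
    max_outer: int = 30,
) -> Optional[str]:
    free = [p for p in range(L) if p not in constraints]
    for _ in range(max_outer):
        arr = rng.choice(_NT, size=L)
        for p, nt in constraints.items():
            arr[p] = nt
        if _repair(arr, L, start0, n_codons, constraints, rng):
            return "".join(arr)
        if not free:
            return None
    return None


def _repair(
    arr: np.ndarray,
    L: int,
    start0: int,
    n_codons: int,
    constraints: dict[int, str],
    rng: np.random.Generator,
    max_iter: int = 4000,
) -> bool:
    """Mutate free positions until the planted reading has no premature stop
    and no upstream in-frame AUG within the first traversal."""
    for _ in range(max_iter):
        bad_positions: list[int] = []
        # premature in-frame stops within the coding span (codons 1..N-1)
        for i in range(1, n_codons):
            ps = [(start0 + 3 * i + j) % L for j in range(3)]
            codon = "".join(arr[p] for p in ps)
            if codon in circorf.STOP_CODONS:
                cand = [p for p in ps if p not in constraints]
                if not cand:
                    return False
                bad_positions.append(cand[0])
        # upstream same-frame AUGs within the first traversal
        for k in range(1, (L - 1) // 3 + 1):
            ps = [(start0 - 3 * k + j) % L for j in range(3)]
            codon = "".join(arr[p] for p in ps)
            if codon == "AUG":
                cand = [p for p in ps if p not in constraints]
                if not cand:
                    return False
                bad_positions.append(cand[0])
        if not bad_positions:
            return True
        for p in set(bad_positions):
            arr[p] = rng.choice(_NT)
    return False


def _verify_planted(circ: CircularTranscript, spec: OrfSpec) -> bool:
    calls = find_circular_orfs(
        circ,
        max_traversals=max(4, (3 * (spec.product_length_aa + 1)) // len(circ) + 2),
        min_length_aa=1,
    )
    for c in calls:
        if c.start == spec.start_pos and c.length_aa == spec.product_length_aa:
            return True
    return False


def circhnrnpu_preset(seed: int = 0) -> CircularTranscript:
    """The packaged fixture circle: 1733 nt, IRES 201-374, IRES-proximal AUG
    at 380, 603-aa product whose 1812-nt coding span crosses the back-splice
    junction (stop first reached on the second traversal)."""
    return gen_circle(
        OrfSpec(ires_interval=(201, 374), seed=seed), circle_id="circHNRNPU_synthetic"
    )


# ---------------------------------------------------------------------------
# alternative splicing


AS_TYPES = ("SE", "A5SS", "A3SS", "RI", "MXE")

DEFAULT_CATEGORY_PROBS = {"SE": 0.60, "A3SS": 0.12, "A5SS": 0.10, "RI": 0.10, "MXE": 0.08}


@dataclass
class AsSimConfig:
    """Binomial junction-count generator around condition-specific true PSI.

    ``psi_cond1``/``psi_cond2`` may be scalars (broadcast) or per-event
    sequences.  Counts: inclusion ~ Binomial(depth, q) with q the
    effective-length-weighted inclusion probability, so the estimated PSI is
    consistent for the true PSI as depth grows.
    """

    n_events: int = 200
    category_probs: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CATEGORY_PROBS)
    )
    psi_cond1: float | Sequence[float] = 0.5
    psi_cond2: float | Sequence[float] = 0.5
    depth: float = 50
    n_replicates: int = 3
    eff_len_inc: int = 2
    eff_len_skip: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        total = sum(self.category_probs.values())
        if abs(total - 1.0) > 1e-9:
            raise ConfigError(f"category_probs sums to {total}, expected 1")
        if self.depth <= 0:
            raise ConfigError(f"depth={self.depth} must be > 0")
        for name in ("psi_cond1", "psi_cond2"):
            v = np.atleast_1d(np.asarray(getattr(self, name), dtype=float))
            if np.any((v < 0) | (v > 1)):
                raise ConfigError(f"{name} values must lie in [0,1]")
            if v.size not in (1, self.n_events):
                raise ConfigError(
                    f"{name} has {v.size} entries, expected 1 or n_events={self.n_events}"
                )


def gen_as_counts(config: AsSimConfig) -> AsCountTable:
    """Simulate per-event, per-replicate inclusion/skipping junction counts."""
    rng = np.random.default_rng(config.seed)
    psi1 = np.broadcast_to(
        np.atleast_1d(np.asarray(config.psi_cond1, dtype=float)), (config.n_events,)
    )
    psi2 = np.broadcast_to(
        np.atleast_1d(np.asarray(config.psi_cond2, dtype=float)), (config.n_events,)
    )
    types = list(config.category_probs)
    probs = np.array([config.category_probs[t] for t in types])
    event_types = rng.choice(types, size=config.n_events, p=probs)
    depth = int(round(config.depth))

    def q_of(psi: np.ndarray) -> np.ndarray:
        num = psi * config.eff_len_inc
        return num / (num + (1 - psi) * config.eff_len_skip)

    q1, q2 = q_of(psi1), q_of(psi2)
    events: list[AsEventCounts] = []
    condition_of: dict[str, str] = {}
    samples1 = [f"cond1_r{r + 1}" for r in range(config.n_replicates)]
    samples2 = [f"cond2_r{r + 1}" for r in range(config.n_replicates)]
    for s in samples1:
        condition_of[s] = "cond1"
    for s in samples2:
        condition_of[s] = "cond2"
    inc1 = rng.binomial(depth, q1[:, None], size=(config.n_events, config.n_replicates))
    inc2 = rng.binomial(depth, q2[:, None], size=(config.n_events, config.n_replicates))
    for e in range(config.n_events):
        inclusion = {}
        skipping = {}
        for r, s in enumerate(samples1):
            inclusion[s] = int(inc1[e, r])
            skipping[s] = depth - int(inc1[e, r])
        for r, s in enumerate(samples2):
            inclusion[s] = int(inc2[e, r])
            skipping[s] = depth - int(inc2[e, r])
        events.append(
            AsEventCounts(
                event_id=f"event_{e + 1:05d}",
                gene_id=f"gene_{e + 1:05d}",
                event_type=str(event_types[e]),
                inclusion_counts=inclusion,
                skipping_counts=skipping,
                eff_len_inc=config.eff_len_inc,
                eff_len_skip=config.eff_len_skip,
            )
        )
    truth = {"psi_cond1": psi1.copy(), "psi_cond2": psi2.copy()}
    return AsCountTable(events=events, condition_of=condition_of, truth=truth)


def as_preset(seed: int = 0, n_events: int = 400, n_differential: int = 40) -> AsSimConfig:
    """Default AS preset: mostly null events plus planted differential ones
    (|delta PSI| = 0.4 in the first ``n_differential`` events)."""
    rng = np.random.default_rng(seed)
    psi1 = rng.uniform(0.25, 0.75, size=n_events)
    psi2 = psi1.copy()
    sign = np.where(psi1[:n_differential] < 0.5, 1.0, -1.0)
    psi2[:n_differential] = np.clip(psi1[:n_differential] + 0.4 * sign, 0.0, 1.0)
    return AsSimConfig(
        n_events=n_events, psi_cond1=psi1, psi_cond2=psi2, depth=80, seed=seed
    )


# ---------------------------------------------------------------------------
# survival


@dataclass
class SurvSimConfig:
    """Exponential survival with hazard multiplied by ``hazard_ratio`` for
    subjects whose (log-normal) expression exceeds the cohort median, plus
    independent Uniform(0, b) censoring with b solved so that the expected
    censored fraction equals ``censor_fraction``."""

    n_subjects: int = 200
    hazard_ratio: float = 2.0
    baseline_scale: float = 60.0
    censor_fraction: float = 0.2
    expr_log_mean: float = 2.0
    expr_log_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.hazard_ratio <= 0:
            raise ConfigError("hazard_ratio must be > 0")
        if not 0 <= self.censor_fraction < 1:
            raise ConfigError("censor_fraction must lie in [0,1)")
        if self.n_subjects < 2:
            raise ConfigError("n_subjects must be >= 2")
        if self.baseline_scale <= 0:
            raise ConfigError("baseline_scale must be > 0")


def _censor_bound(lam_lo: float, lam_hi: float, target: float) -> float:
    """Upper bound b of Uniform(0,b) censoring such that P(C < T) = target
    when T is an equal mixture of Exp(lam_lo) and Exp(lam_hi)."""

    def pc(b: float) -> float:
        def one(lam: float) -> float:
            return (1 - np.exp(-lam * b)) / (lam * b)

        return 0.5 * (one(lam_lo) + one(lam_hi))

    # pc is decreasing in b from 1 to 0
    hi = 1.0
    while pc(hi) > target:
        hi *= 2
        if hi > 1e9:
            break
    return brentq(lambda b: pc(b) - target, 1e-9, hi)


def gen_survival(config: SurvSimConfig) -> SurvivalTable:
    """Simulate a survival cohort with expression-linked hazard."""
    rng = np.random.default_rng(config.seed)
    expr = rng.lognormal(config.expr_log_mean, config.expr_log_sd, config.n_subjects)
    high = expr > np.median(expr)
    lam = (1.0 / config.baseline_scale) * np.where(high, config.hazard_ratio, 1.0)
    t_event = rng.exponential(1.0 / lam)
    if config.censor_fraction > 0:
        b = _censor_bound(
            1.0 / config.baseline_scale,
            config.hazard_ratio / config.baseline_scale,
            config.censor_fraction,
        )
        c = rng.uniform(0, b, config.n_subjects)
        time = np.minimum(t_event, c)
        event = (t_event <= c).astype(int)
    else:
        time = t_event
        event = np.ones(config.n_subjects, dtype=int)
    time = np.maximum(time, 1e-9)
    return SurvivalTable(
        table=pd.DataFrame(
            {
                "subject_id": [f"subj_{i + 1:04d}" for i in range(config.n_subjects)],
                "time": time,
                "event": event,
                "expression": expr,
            }
        )
    )


# ---------------------------------------------------------------------------
# gene sets


def gen_genesets(
    universe_size: int,
    n_sets: int,
    planted: Optional[tuple[int, int]] = None,
    n_hits: int = 10,
    set_size_range: tuple[int, int] = (5, 25),
    seed: int = 0,
) -> tuple[GeneSetCollection, list[str]]:
    """Random gene-set collection plus one planted over-represented set.

    ``planted = (set_size, n_overlap)`` plants a set containing ``n_overlap``
    members of the returned hit list (the first ``n_hits`` universe genes).
    Returns ``(collection, hits)``; the planted set name is recorded in
    ``collection.truth``.
    """
    if planted is not None:
        size, overlap = planted
        if size > universe_size:
            raise ConfigError(f"planted set size {size} exceeds universe {universe_size}")
        if overlap > min(size, n_hits):
            raise ConfigError("planted overlap exceeds set size or hit count")
    if n_hits > universe_size:
        raise ConfigError("n_hits exceeds universe size")
    if set_size_range[1] > universe_size:
        set_size_range = (min(set_size_range[0], universe_size), universe_size)
    rng = np.random.default_rng(seed)
    universe = [f"g{i + 1:04d}" for i in range(universe_size)]
    hits = universe[:n_hits]
    sets: dict[str, list[str]] = {}
    for i in range(n_sets):
        size = int(rng.integers(set_size_range[0], set_size_range[1] + 1))
        members = rng.choice(universe, size=size, replace=False)
        sets[f"random_set_{i + 1:03d}"] = sorted(members)
    truth: dict = {"planted_set": None, "hits": hits}
    if planted is not None:
        size, overlap = planted
        members = list(rng.choice(hits, size=overlap, replace=False))
        non_hits = [g for g in universe if g not in hits]
        members += list(rng.choice(non_hits, size=size - overlap, replace=False))
        sets["planted_set"] = sorted(members)
        truth["planted_set"] = "planted_set"
    return GeneSetCollection(sets=sets, universe=universe, truth=truth), hits
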