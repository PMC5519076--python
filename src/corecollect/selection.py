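"""Greedy core-collection selection.

Each round: among the remaining samples that would still add coverage,
restrict to the stratum with the fewest missing calls, pick the one with the
highest coverage score C_j (ties: minimum diversity score D_j; residual ties
go to the first sample in input order by default, or to a seeded uniform
random draw with ``tie_break="random"`` — the deterministic default is what
makes repeated runs return the identical core, even when a collection holds
fully interchangeable duplicate accessions), mark its (marker, class) pairs
covered, drop it and
every remaining sample with a byte-identical call vector, and update the
cumulative coverage CV.  Selection stops when CV reaches the target, when a
step's CV gain falls below the delta threshold, when no remaining sample
adds coverage, when the pool is exhausted, or when an optional size cap is
hit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .genotype_io import GenotypeMatrix
from .scoring import CoverageState, MarkerClassTable, build_class_table, coverage_scores, diversity_score

__all__ = ["SelectionConfig", "StepRecord", "SelectionResult", "select_core", "random_baseline"]

#: decimal places at which two scores are considered tied
TIE_DECIMALS = 12


@dataclass
class SelectionConfig:
    """Stopping and reproducibility parameters for the greedy loop.

    ``target_cv_percent`` and ``delta_percent`` are in percentage points:
    the defaults stop at 99% coverage or when a step gains less than 0.01
    percentage points.
    """

    target_cv_percent: float = 99.0
    delta_percent: float = 0.01
    seed: int = 0
    max_core_size: int | None = None
    tie_break: str = "order"

    def __post_init__(self):
        if not (0.0 < self.target_cv_percent <= 100.0):
            raise ValueError("target_cv_percent must lie in (0, 100]")
        if self.delta_percent < 0.0:
            raise ValueError("delta_percent must be >= 0")
        if self.max_core_size is not None and self.max_core_size < 1:
            raise ValueError("max_core_size must be >= 1")
        if self.tie_break not in ("order", "random"):
            raise ValueError("tie_break must be 'order' or 'random'")


@dataclass
class StepRecord:
    step: int
    sample_id: str
    coverage_score: float
    diversity_score: float | None
    cumulative_cv_percent: float
    removed_duplicates: list[str]


@dataclass
class SelectionResult:
    core_ids: list[str]
    trace: list[StepRecord]
    stop_reason: str
    seed: int
    config: SelectionConfig | None = None
    final_cv_percent: float = field(init=False)

    def __post_init__(self):
        self.final_cv_percent = self.trace[-1].cumulative_cv_percent if self.trace else 0.0


def _duplicate_mask(T: MarkerClassTable, j: int, remaining: np.ndarray) -> np.ndarray:
    """Remaining samples whose full call vector equals sample j's (incl. missing)."""
    same = (T.codes == T.codes[j]).all(axis=1)
    return same & remaining


def select_core(G: GenotypeMatrix, cfg: SelectionConfig | None = None) -> SelectionResult:
    """Run the greedy coverage-maximising selection on the full collection.

    Frequencies f are computed once on the entire collection and held fixed;
    covered (marker, class) contributions are masked out in later rounds, so
    each accepted pick strictly increases CV.
    """
    cfg = cfg or SelectionConfig()
    if G.n_samples == 0 or G.n_markers == 0:
        raise ValueError("empty genotype matrix")
    T = build_class_table(G)
    if not T.informative.any():
        raise ValueError("all markers are uninformative (every call missing)")
    rng = np.random.default_rng(cfg.seed)
    S = CoverageState.empty(T)
    remaining = np.ones(G.n_samples, dtype=bool)
    misscnt = np.asarray(G.missing_counts)
    core_ids: list[str] = []
    trace: list[StepRecord] = []
    cv_prev = 0.0
    stop_reason = "samples_exhausted"
    while remaining.any():
        rem_idx = np.where(remaining)[0]
        c_all = coverage_scores(T, S, rem_idx)
        if c_all.max() <= 0.0:
            stop_reason = "no_gain"
            break
        # prefer the least-missing stratum that still adds coverage
        gain_ok = c_all > 0.0
        strata = np.sort(np.unique(misscnt[rem_idx[gain_ok]]))
        for mc in strata:
            in_pool = gain_ok & (misscnt[rem_idx] == mc)
            if c_all[in_pool].max() > 0.0:
                break
        pool_idx = rem_idx[in_pool]
        pool_c = c_all[in_pool]
        best = pool_c.max()
        tie = np.round(pool_c, TIE_DECIMALS) == np.round(best, TIE_DECIMALS)
        tie_idx = pool_idx[tie]
        d_chosen: float | None = None
        if len(tie_idx) == 1:
            j = int(tie_idx[0])
            c_j = float(pool_c[tie][0])
        else:
            tie_c = pool_c[tie]
            d = np.array(
                [diversity_score(G, T, S, int(t), float(c)) for t, c in zip(tie_idx, tie_c)]
            )
            dmin = d.min()
            still = np.round(d, TIE_DECIMALS) == np.round(dmin, TIE_DECIMALS)
            finalists = tie_idx[still]
            if cfg.tie_break == "random" and len(finalists) > 1:
                pick = int(rng.integers(len(finalists)))
            else:
                pick = 0  # first in input order: fully reproducible
            j = int(finalists[pick])
            c_j = float(tie_c[still][pick])
            d_chosen = float(d[still][pick])
        S.cover_sample(T, j)
        dup = _duplicate_mask(T, j, remaining)
        dup[j] = False
        removed = [G.sample_ids[int(k)] for k in np.where(dup)[0]]
        remaining[j] = False
        remaining[dup] = False
        core_ids.append(G.sample_ids[j])
        cv = S.cv_percent(T)
        trace.append(
            StepRecord(
                step=len(core_ids),
                sample_id=G.sample_ids[j],
                coverage_score=c_j,
                diversity_score=d_chosen,
                cumulative_cv_percent=cv,
                removed_duplicates=removed,
            )
        )
        gain = cv - cv_prev
        cv_prev = cv
        if cv >= cfg.target_cv_percent:
            stop_reason = "target_reached"
            break
        if gain < cfg.delta_percent:
            stop_reason = "delta_below_threshold"
            break
        if cfg.max_core_size is not None and len(core_ids) >= cfg.max_core_size:
            stop_reason = "size_cap"
            break
    return SelectionResult(core_ids=core_ids, trace=trace, stop_reason=stop_reason, seed=cfg.seed, config=cfg)


def random_baseline(G: GenotypeMatrix, k: int, seed: int = 0) -> SelectionResult:
    """Uniform random subset of k distinct samples, with a cumulative CV trace.

    The baseline the coverage curve of the greedy core is compared against.
    """
    if not (1 <= k <= G.n_samples):
        raise ValueError(f"k={k} out of range [1, {G.n_samples}]")
    T = build_class_table(G)
    rng = np.random.default_rng(seed)
    picks = rng.choice(G.n_samples, size=k, replace=False)
    S = CoverageState.empty(T)
    trace: list[StepRecord] = []
    for step, j in enumerate(picks, start=1):
        c_j = float(coverage_scores(T, S, [int(j)])[0])
        S.cover_sample(T, int(j))
        trace.append(
            StepRecord(
                step=step,
                sample_id=G.sample_ids[int(j)],
                coverage_score=c_j,
                diversity_score=None,
                cumulative_cv_percent=S.cv_percent(T),
                removed_duplicates=[],
            )
        )
    return SelectionResult(
        core_ids=[G.sample_ids[int(j)] for j in picks],
        trace=trace,
        stop_reason="size_cap",
        seed=seed,
    )
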