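"""Iterative Stochastic Elimination (ISE) filter-ensemble classifier.

The classifier is an ensemble of *filters*.  A filter is a conjunction of
4–5 closed numeric ranges on distinct physico-chemical descriptors; a
molecule "passes" a filter only if all its referenced descriptor values lie
inside the ranges.  Filters are scored with the Matthews Correlation
Coefficient (MCC), which stays informative under the extreme class imbalance
typical of virtual screening (actives diluted ~1:200 in inactives):

    MCC = (TP·TN − FP·FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN))

Model construction per training fold:

1. Each descriptor's observed range is discretized into ``n_divisions``
   equal divisions, giving n(n−1)/2 contiguous candidate sub-ranges; the
   single sub-range with the best MCC becomes that descriptor's pool entry.
2. While the number of possible filter combinations is at or above
   ``exhaustive_threshold``: sample a large number of random filters from
   the pool, score them, and eliminate pool ranges that are statistically
   over-represented in the worst MCC decile and under-represented in the
   best decile.
3. Once the combination count drops below the threshold, enumerate and
   score every remaining combination exhaustively.
4. Keep filters with MCC within 20% of the fold's top MCC, capped at 1000.

A 5-fold protocol trains one ensemble per fold and scores each held-out
fifth, so every learning-set molecule receives exactly one out-of-fold
score; the fold ensembles are then merged, near-duplicate filters removed,
and the keep rule re-applied.

Molecules are scored with the Molecular Bioactivity Index (MBI): the mean
over all filters of a reward for passing (the filter's efficiency factor)
minus a penalty for failing (its inefficiency factor).  In the default
``proportion`` mode efficiency = TP/(TP+FP) and inefficiency = TN/(TN+FN),
which bounds MBI in [−1, 1]; a literal ``ratio`` mode (TP/FP and TN/FN with
add-one smoothing on zero denominators) is available via the configuration.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

MODEL_FORMAT_VERSION = 1


# ---------------------------------------------------------------------------
# basic statistics
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")


def mcc(counts: ConfusionCounts) -> float:
    """Matthews Correlation Coefficient; 0 by convention if any denominator factor is 0."""
    tp, fp, tn, fn = counts.tp, counts.fp, counts.tn, counts.fn
    if tp + fp + tn + fn == 0:
        raise ValueError("all confusion counts are zero")
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if denom == 0:
        return 0.0
    return (tp * tn - fp * fn) / math.sqrt(denom)


def _mcc_arrays(tp: np.ndarray, fp: np.ndarray, n_act: int, n_inact: int) -> np.ndarray:
    """Vectorized MCC for arrays of tp/fp given fixed class sizes."""
    tp = tp.astype(np.float64)
    fp = fp.astype(np.float64)
    fn = n_act - tp
    tn = n_inact - fp
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(denom > 0, (tp * tn - fp * fn) / np.sqrt(np.maximum(denom, 1e-300)), 0.0)
    return out


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DescriptorRange:
    """Closed interval [lo, hi] on one named descriptor; bounds lie on the grid."""

    descriptor: str
    lo: float
    hi: float

    def __post_init__(self) -> None:
        if self.lo > self.hi:
            raise ValueError(f"lo > hi for {self.descriptor}")

    def contains(self, value: float) -> bool:
        return self.lo <= value <= self.hi


@dataclass(frozen=True)
class Filter:
    """Conjunction of ranges on distinct descriptors with its training statistics."""

    ranges: tuple[DescriptorRange, ...]
    counts: ConfusionCounts
    mcc: float
    efficiency: float
    inefficiency: float

    def __post_init__(self) -> None:
        names = [r.descriptor for r in self.ranges]
        if len(set(names)) != len(names):
            raise ValueError("filter descriptors must be distinct")

    @property
    def descriptors(self) -> tuple[str, ...]:
        return tuple(r.descriptor for r in self.ranges)


@dataclass(frozen=True)
class ISEConfig:
    """Tunable parameters of the ISE search (defaults documented in docs/methods.md)."""

    n_divisions: int = 100
    filter_sizes: tuple[int, ...] = (4, 5)
    sample_size: int = 50_000
    decile_fraction: float = 0.10
    alpha: float = 2.0  # worst-decile over-representation multiplier
    beta: float = 0.5  # best-decile under-representation multiplier
    exhaustive_threshold: int = 10**6
    keep_mode: str = "cap"  # "cap": top max_filters; "fraction": MCC >= mcc_fraction * top
    mcc_fraction: float = 0.8
    max_filters: int = 1000
    n_folds: int = 5
    mbi_mode: str = "proportion"  # or "ratio"
    range_slack_scale: float = 0.75  # near-optimum band for single-range selection
    similarity_jaccard: float = 0.8
    max_iterations: int = 50
    min_expected: float = 5.0

    def __post_init__(self) -> None:
        if self.n_divisions < 2:
            raise ValueError("n_divisions must be >= 2")
        if not (0 < self.decile_fraction < 0.5):
            raise ValueError("decile_fraction must be in (0, 0.5)")
        if self.mbi_mode not in ("proportion", "ratio"):
            raise ValueError("mbi_mode must be 'proportion' or 'ratio'")
        if self.keep_mode not in ("cap", "fraction"):
            raise ValueError("keep_mode must be 'cap' or 'fraction'")
        if min(self.sample_size, self.exhaustive_threshold, self.max_filters, self.n_folds) <= 0:
            raise ValueError("config values must be positive")


@dataclass
class ISEModel:
    """Merged filter ensemble plus the metadata needed to reapply it."""

    filters: list[Filter]
    descriptor_names: list[str]
    config: ISEConfig
    seed: int
    fold_of_filter: list[int] = field(default_factory=list)
    fold_assignment: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.filters:
            raise ValueError("model must contain at least one filter")


# ---------------------------------------------------------------------------
# range enumeration and per-descriptor optimum
# ---------------------------------------------------------------------------


def enumerate_subranges(n_divisions: int) -> list[tuple[int, int]]:
    """All contiguous sub-ranges on a grid with ``n_divisions`` divisions.

    A sub-range is a pair of distinct grid boundary indices (lo, hi) with
    0 <= lo < hi <= n_divisions, excluding the full range's duplicates by
    construction; the count is n(n−1)/2 for n = n_divisions.
    """
    if n_divisions < 2:
        raise ValueError("n_divisions must be >= 2")
    n = n_divisions
    # pairs of division indices: the classic n*(n-1)/2 internal ranges
    return [(lo, hi) for lo in range(n - 1) for hi in range(lo + 1, n)]


def filter_space_size(n_descriptors: int, sizes: Iterable[int] = (5,)) -> int:
    """Number of distinct descriptor combinations for the given filter sizes."""
    return sum(math.comb(n_descriptors, k) for k in set(sizes))


def best_range_per_descriptor(
    values: np.ndarray,
    labels: np.ndarray,
    n_divisions: int = 100,
    slack_scale: float = 0.75,
) -> tuple[tuple[float, float], float]:
    """Scan all sub-ranges of one descriptor for the best single-range MCC.

    The observed min–max span is cut into ``n_divisions`` equal divisions and
    every contiguous closed sub-range [edge_i, edge_j] is scored as a
    one-range filter.  The maximum of an MCC scan over ~5000 overlapping
    windows is a scan statistic: with only tens of actives, the literal
    argmax is typically a chance-narrow window well inside the true active
    region, which cripples generalization.  The selector therefore treats
    every window whose MCC is within a sampling-noise band of the maximum —
    relative slack ``slack_scale / sqrt(n_actives) * (1 - best_mcc)``, which
    vanishes as the best window approaches perfection — as statistically
    indistinguishable from it, and returns the union span of those windows
    as the consensus range.  ``slack_scale=0`` recovers the literal argmax
    (ties broken to the narrowest window, then the lowest lower bound).

    Returns ``((lo, hi), mcc_of_returned_range)``.  A constant descriptor
    raises ``ValueError`` (callers exclude it from the pool).
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    if not labels.any() or labels.all():
        raise ValueError("both classes must be present")
    vmin, vmax = values.min(), values.max()
    if vmin == vmax:
        raise ValueError("constant descriptor")
    edges = np.linspace(vmin, vmax, n_divisions + 1)
    act = np.sort(values[labels])
    inact = np.sort(values[~labels])
    n_act, n_inact = act.size, inact.size
    # counts in closed [edges[i], edges[j]]: right-side minus left-side ranks
    act_r = np.searchsorted(act, edges, side="right")
    act_l = np.searchsorted(act, edges, side="left")
    in_r = np.searchsorted(inact, edges, side="right")
    in_l = np.searchsorted(inact, edges, side="left")
    tp = act_r[None, :] - act_l[:, None]  # tp[i, j]
    fp = in_r[None, :] - in_l[:, None]
    m = _mcc_arrays(np.maximum(tp, 0), np.maximum(fp, 0), n_act, n_inact)
    i_idx, j_idx = np.meshgrid(np.arange(n_divisions + 1), np.arange(n_divisions + 1), indexing="ij")
    valid = j_idx > i_idx
    m = np.where(valid, m, -np.inf)
    best = m.max()
    slack = slack_scale / math.sqrt(n_act) * (1.0 - min(best, 1.0))
    if slack_scale > 0 and best > 0:
        cand = np.argwhere(m >= best * (1.0 - slack))
        i, j = int(cand[:, 0].min()), int(cand[:, 1].max())
    else:
        cand = np.argwhere(np.isclose(m, best, rtol=0, atol=1e-12))
        widths = cand[:, 1] - cand[:, 0]
        order = np.lexsort((cand[:, 0], widths))
        i, j = (int(x) for x in cand[order[0]])
    tp_ij = int(act_r[j] - act_l[i])
    fp_ij = int(in_r[j] - in_l[i])
    chosen = mcc(ConfusionCounts(tp=tp_ij, fp=fp_ij, tn=n_inact - fp_ij, fn=n_act - tp_ij))
    return (float(edges[i]), float(edges[j])), float(chosen)


def build_range_pool(
    data: pd.DataFrame,
    labels: np.ndarray,
    cfg: ISEConfig,
) -> list[DescriptorRange]:
    """Best single range per descriptor over the training data (constant columns skipped)."""
    pool: list[DescriptorRange] = []
    for name in data.columns:
        try:
            (lo, hi), _ = best_range_per_descriptor(
                data[name].to_numpy(), labels, cfg.n_divisions, cfg.range_slack_scale
            )
        except ValueError:
            logger.warning("descriptor %s is constant or degenerate; excluded from pool", name)
            continue
        pool.append(DescriptorRange(name, lo, hi))
    return pool


# ---------------------------------------------------------------------------
# filter evaluation
# ---------------------------------------------------------------------------


def evaluate_filter(
    ranges: Sequence[DescriptorRange],
    data: pd.DataFrame,
    labels: np.ndarray,
) -> tuple[ConfusionCounts, float]:
    """Pass/fail every molecule through a conjunction of closed ranges."""
    labels = np.asarray(labels, dtype=bool)
    passed = np.ones(len(data), dtype=bool)
    for r in ranges:
        if r.descriptor not in data.columns:
            raise KeyError(f"missing descriptor column {r.descriptor!r}")
        v = data[r.descriptor].to_numpy(dtype=float)
        passed &= (v >= r.lo) & (v <= r.hi)
    counts = ConfusionCounts(
        tp=int(np.count_nonzero(passed & labels)),
        fp=int(np.count_nonzero(passed & ~labels)),
        tn=int(np.count_nonzero(~passed & ~labels)),
        fn=int(np.count_nonzero(~passed & labels)),
    )
    return counts, mcc(counts)


def _pass_masks(
    pool: Sequence[DescriptorRange], data: pd.DataFrame, labels: np.ndarray
) -> tuple[list[int], list[int], int, int]:
    """Per-range pass masks as Python big-ints (one bit per molecule, by class)."""
    labels = np.asarray(labels, dtype=bool)
    act_masks: list[int] = []
    inact_masks: list[int] = []
    for r in pool:
        v = data[r.descriptor].to_numpy(dtype=float)
        ok = (v >= r.lo) & (v <= r.hi)
        act_masks.append(int.from_bytes(np.packbits(ok[labels]).tobytes(), "big"))
        inact_masks.append(int.from_bytes(np.packbits(ok[~labels]).tobytes(), "big"))
    return act_masks, inact_masks, int(labels.sum()), int((~labels).sum())


def _make_filter(
    pool: Sequence[DescriptorRange],
    combo: tuple[int, ...],
    tp: int,
    fp: int,
    n_act: int,
    n_inact: int,
    mode: str,
) -> Filter:
    counts = ConfusionCounts(tp=tp, fp=fp, tn=n_inact - fp, fn=n_act - tp)
    eff, ineff = _efficiency_factors(counts, mode)
    return Filter(
        ranges=tuple(pool[i] for i in combo),
        counts=counts,
        mcc=mcc(counts),
        efficiency=eff,
        inefficiency=ineff,
    )


def _efficiency_factors(counts: ConfusionCounts, mode: str) -> tuple[float, float]:
    tp, fp, tn, fn = counts.tp, counts.fp, counts.tn, counts.fn
    if mode == "proportion":
        eff = tp / (tp + fp) if tp + fp else 0.0
        ineff = tn / (tn + fn) if tn + fn else 0.0
    else:  # literal ratio with add-one smoothing on zero denominators
        eff = tp / fp if fp else tp / 1.0
        ineff = tn / fn if fn else tn / 1.0
    return eff, ineff


# ---------------------------------------------------------------------------
# stochastic phase: sampling and biased-range elimination
# ---------------------------------------------------------------------------


def sample_filters(
    pool_size: int,
    sizes: Sequence[int],
    count: int,
    rng: np.random.Generator,
) -> list[tuple[int, ...]]:
    """Random filters as sorted index-tuples into the pool; reproducible under the rng."""
    if pool_size < max(sizes):
        raise ValueError("pool too small for requested filter sizes")
    sizes_arr = np.asarray(sorted(set(sizes)))
    out: list[tuple[int, ...]] = []
    choice_sizes = rng.choice(sizes_arr, size=count)
    for k in choice_sizes:
        out.append(tuple(sorted(rng.choice(pool_size, size=int(k), replace=False).tolist())))
    return out


def eliminate_ranges(
    scored_sample: Sequence[tuple[tuple[int, ...], float]],
    pool: Sequence[DescriptorRange],
    cfg: ISEConfig,
) -> tuple[list[int], list[dict]]:
    """Drop pool ranges biased toward bad filters.

    A range is eliminated iff its appearance count in the worst MCC decile
    exceeds ``alpha`` times its expected count AND its count in the best
    decile is below ``beta`` times expected, where expected = total sample
    appearances × decile fraction.  Returns surviving pool indices and a log.
    If every range would survive trivially because expected appearances are
    below ``min_expected`` the elimination is skipped (callers warn).
    """
    n = len(scored_sample)
    k = max(1, int(round(n * cfg.decile_fraction)))
    order = np.argsort([s[1] for s in scored_sample], kind="stable")
    worst = set(order[:k].tolist())
    best = set(order[-k:].tolist())
    total = np.zeros(len(pool), dtype=np.int64)
    worst_ct = np.zeros(len(pool), dtype=np.int64)
    best_ct = np.zeros(len(pool), dtype=np.int64)
    for idx, (combo, _) in enumerate(scored_sample):
        for j in combo:
            total[j] += 1
            if idx in worst:
                worst_ct[j] += 1
            if idx in best:
                best_ct[j] += 1
    expected = total * cfg.decile_fraction
    if (expected < cfg.min_expected).all():
        return list(range(len(pool))), [{"skipped": "expected decile appearances below minimum"}]
    keep: list[int] = []
    log: list[dict] = []
    for j in range(len(pool)):
        eliminate = (
            expected[j] >= cfg.min_expected
            and worst_ct[j] > cfg.alpha * expected[j]
            and best_ct[j] < cfg.beta * expected[j]
        )
        if eliminate:
            log.append(
                {
                    "descriptor": pool[j].descriptor,
                    "worst": int(worst_ct[j]),
                    "best": int(best_ct[j]),
                    "expected": float(expected[j]),
                }
            )
        else:
            keep.append(j)
    if not keep:
        # never empty the pool entirely: retain everything and report
        logger.warning("elimination would empty the pool; keeping all ranges")
        return list(range(len(pool))), [{"skipped": "elimination would empty pool"}]
    return keep, log


# ---------------------------------------------------------------------------
# fold search
# ---------------------------------------------------------------------------


def _exhaustive_combos(
    act_masks: list[int],
    inact_masks: list[int],
    sizes: Sequence[int],
) -> list[tuple[tuple[int, ...], int, int]]:
    """Score every size-k combination; depth-first with shared prefix ANDs."""
    sizes_set = set(sizes)
    max_size = max(sizes_set)
    n = len(act_masks)
    results: list[tuple[tuple[int, ...], int, int]] = []

    def rec(start: int, combo: tuple[int, ...], cur_a: int, cur_i: int) -> None:
        depth = len(combo)
        for j in range(start, n):
            na = cur_a & act_masks[j]
            ni = cur_i & inact_masks[j]
            d = depth + 1
            if d in sizes_set:
                results.append((combo + (j,), na.bit_count(), ni.bit_count()))
            if d < max_size:
                rec(j + 1, combo + (j,), na, ni)

    # Python ints: -1 has all bits set, so ANDing with the per-range masks
    # confines support to the molecule bits without tracking the bit width.
    rec(0, (), -1, -1)
    return results


def run_ise_fold(
    data: pd.DataFrame,
    labels: np.ndarray,
    cfg: ISEConfig,
    rng: np.random.Generator,
) -> list[Filter]:
    """One fold's full ISE search: sample → score → eliminate, then exhaustive finish."""
    labels = np.asarray(labels, dtype=bool)
    if not labels.any():
        raise ValueError("training data has no actives")
    if labels.all():
        raise ValueError("training data has no inactives")
    pool = build_range_pool(data, labels, cfg)
    if len(pool) < max(cfg.filter_sizes):
        raise ValueError("fewer usable descriptors than the filter size")
    act_masks, inact_masks, n_act, n_inact = _pass_masks(pool, data, labels)

    for iteration in range(cfg.max_iterations):
        n_comb = filter_space_size(len(pool), cfg.filter_sizes)
        if n_comb < cfg.exhaustive_threshold:
            break
        combos = sample_filters(len(pool), cfg.filter_sizes, cfg.sample_size, rng)
        scored = []
        for combo in combos:
            a = -1
            b = -1
            for j in combo:
                a &= act_masks[j]
                b &= inact_masks[j]
            tp, fp = a.bit_count(), b.bit_count()
            counts = ConfusionCounts(tp=tp, fp=fp, tn=n_inact - fp, fn=n_act - tp)
            scored.append((combo, mcc(counts)))
        keep_idx, elim_log = eliminate_ranges(scored, pool, cfg)
        if len(keep_idx) == len(pool):
            if elim_log and "skipped" in elim_log[0]:
                logger.warning("iteration %d: elimination skipped (%s)", iteration, elim_log[0])
            else:
                logger.info("iteration %d: no range met the elimination rule", iteration)
            # nothing eliminated but the space is still too large: drop the
            # single most worst-decile-biased range to guarantee convergence
            stats = _bias_statistics(scored, len(pool), cfg)
            drop = int(np.argmax(stats))
            logger.info("forcing elimination of most worst-biased range %s", pool[drop].descriptor)
            keep_idx = [j for j in range(len(pool)) if j != drop]
        pool = [pool[j] for j in keep_idx]
        act_masks = [act_masks[j] for j in keep_idx]
        inact_masks = [inact_masks[j] for j in keep_idx]
    else:
        raise RuntimeError(
            f"ISE did not converge below {cfg.exhaustive_threshold} combinations "
            f"within {cfg.max_iterations} iterations (pool size {len(pool)})"
        )

    results = _exhaustive_combos(act_masks, inact_masks, cfg.filter_sizes)
    tp_arr = np.array([r[1] for r in results], dtype=np.int64)
    fp_arr = np.array([r[2] for r in results], dtype=np.int64)
    mccs = _mcc_arrays(tp_arr, fp_arr, n_act, n_inact)
    return _apply_keep_rule(
        [
            _make_filter(pool, results[i][0], int(tp_arr[i]), int(fp_arr[i]), n_act, n_inact, cfg.mbi_mode)
            for i in _top_indices(mccs, cfg)
        ],
        cfg,
    )


def _bias_statistics(
    scored: Sequence[tuple[tuple[int, ...], float]], pool_size: int, cfg: ISEConfig
) -> np.ndarray:
    """Worst-decile excess (observed − expected) per pool range, for tie-forcing."""
    n = len(scored)
    k = max(1, int(round(n * cfg.decile_fraction)))
    order = np.argsort([s[1] for s in scored], kind="stable")
    worst = set(order[:k].tolist())
    total = np.zeros(pool_size)
    worst_ct = np.zeros(pool_size)
    for idx, (combo, _) in enumerate(scored):
        for j in combo:
            total[j] += 1
            if idx in worst:
                worst_ct[j] += 1
    return worst_ct - total * cfg.decile_fraction


def _top_indices(mccs: np.ndarray, cfg: ISEConfig) -> list[int]:
    """Indices surviving the keep rule.

    The ensemble-selection rule has two branches: filters within
    ``mcc_fraction`` of the top MCC (``keep_mode="fraction"``), or the top
    ``max_filters`` overall (``keep_mode="cap"``, the default).  The cap
    branch fills the ensemble to ``max_filters`` so that MBI averaging has a
    graded ensemble to work with, and bounds it when the fraction branch
    would over-select; the fraction branch, always additionally capped, is
    retained for fidelity experiments.  Non-positive MCC is never kept
    (except a lone best filter, since the ensemble must be non-empty).
    """
    if mccs.size == 0:
        return []
    order = np.lexsort((np.arange(mccs.size), -mccs))
    n_keep = min(cfg.max_filters, mccs.size)
    if cfg.keep_mode == "fraction":
        top = mccs[order[0]]
        n_keep = min(n_keep, int(np.count_nonzero(mccs >= cfg.mcc_fraction * top)))
    keep = [int(i) for i in order[:n_keep] if mccs[i] > 0]
    return keep or [int(order[0])]


def _apply_keep_rule(filters: list[Filter], cfg: ISEConfig) -> list[Filter]:
    if not filters:
        return filters
    filters = sorted(
        filters, key=lambda f: (-f.mcc, f.descriptors, tuple((r.lo, r.hi) for r in f.ranges))
    )
    n_keep = cfg.max_filters
    if cfg.keep_mode == "fraction":
        top = filters[0].mcc
        n_keep = min(n_keep, sum(1 for f in filters if f.mcc >= cfg.mcc_fraction * top))
    kept = [f for f in filters[:n_keep] if f.mcc > 0]
    return kept or filters[:1]


# ---------------------------------------------------------------------------
# 5-fold protocol and model assembly
# ---------------------------------------------------------------------------


def _interval_jaccard(a: DescriptorRange, b: DescriptorRange) -> float:
    lo = max(a.lo, b.lo)
    hi = min(a.hi, b.hi)
    inter = max(0.0, hi - lo)
    union = max(a.hi, b.hi) - min(a.lo, b.lo)
    if union == 0:
        return 1.0  # two identical degenerate intervals
    return inter / union


def _similar_filters(a: Filter, b: Filter, jaccard_min: float) -> bool:
    if a.descriptors != b.descriptors:
        # compare as sets; ranges stored sorted by descriptor below
        if set(a.descriptors) != set(b.descriptors):
            return False
    ra = {r.descriptor: r for r in a.ranges}
    rb = {r.descriptor: r for r in b.ranges}
    return all(_interval_jaccard(ra[d], rb[d]) >= jaccard_min for d in ra)


def merge_fold_filters(
    fold_ensembles: Sequence[Sequence[Filter]], cfg: ISEConfig
) -> tuple[list[Filter], list[int]]:
    """Concatenate fold ensembles, drop near-duplicate filters, re-apply the keep rule.

    Two filters are near-duplicates iff they use the same descriptor set and
    every pair of corresponding ranges overlaps with interval Jaccard at or
    above ``similarity_jaccard``; the higher-MCC one survives.
    """
    tagged = [
        (f, fold) for fold, ensemble in enumerate(fold_ensembles) for f in ensemble
    ]
    tagged.sort(key=lambda t: (-t[0].mcc, t[1], t[0].descriptors, tuple((r.lo, r.hi) for r in t[0].ranges)))
    kept: list[tuple[Filter, int]] = []
    # only filters over the same descriptor set can be near-duplicates
    by_key: dict[tuple[str, ...], list[Filter]] = {}
    for f, fold in tagged:
        key = tuple(sorted(f.descriptors))
        if any(_similar_filters(f, g, cfg.similarity_jaccard) for g in by_key.get(key, ())):
            continue
        by_key.setdefault(key, []).append(f)
        kept.append((f, fold))
    if not kept:
        return [], []
    n_keep = cfg.max_filters
    if cfg.keep_mode == "fraction":
        top = kept[0][0].mcc
        n_keep = min(n_keep, sum(1 for f, _ in kept if f.mcc >= cfg.mcc_fraction * top))
    kept = kept[: max(n_keep, 1)]
    return [f for f, _ in kept], [fold for _, fold in kept]


def stratified_folds(
    labels: np.ndarray, n_folds: int, rng: np.random.Generator
) -> np.ndarray:
    """Random stratified fold assignment; round-robin deal within each class."""
    labels = np.asarray(labels, dtype=bool)
    fold = np.empty(labels.size, dtype=np.int64)
    for cls in (True, False):
        idx = np.flatnonzero(labels == cls)
        perm = rng.permutation(idx)
        fold[perm] = np.arange(perm.size) % n_folds
    return fold


def build_model(
    data: pd.DataFrame,
    labels: Sequence[int] | np.ndarray,
    cfg: ISEConfig | None = None,
    seed: int = 0,
) -> tuple[ISEModel, pd.DataFrame]:
    """Full cross-validated model build.

    *data* is a descriptor DataFrame indexed by molecule id (a ``label``
    column, if present, is ignored in favour of *labels*).  Returns the
    merged :class:`ISEModel` and a DataFrame of held-out scores with columns
    ``mbi``, ``label``, ``fold`` — every molecule is scored exactly once by
    the model of the fold that held it out.
    """
    cfg = cfg or ISEConfig()
    labels = np.asarray(labels, dtype=bool)
    feat = data.drop(columns=["label"], errors="ignore")
    n_act = int(labels.sum())
    if n_act < cfg.n_folds:
        raise ValueError(f"need at least n_folds={cfg.n_folds} actives, got {n_act}")
    rng = np.random.default_rng(seed)

    for attempt in range(10):
        fold = stratified_folds(labels, cfg.n_folds, rng)
        ok = all(
            labels[fold == f].any() and (~labels[fold == f]).any() for f in range(cfg.n_folds)
        )
        if ok:
            break
        logger.warning("fold split attempt %d left a fold single-class; redrawing", attempt + 1)
    else:
        raise RuntimeError("could not draw a stratified split with both classes per fold")

    ensembles: list[list[Filter]] = []
    held_out_mbi = np.full(len(feat), np.nan)
    for f in range(cfg.n_folds):
        train = fold != f
        ensemble = run_ise_fold(feat.loc[train], labels[train], cfg, rng)
        ensembles.append(ensemble)
        test_scores = _mbi_matrix(ensemble, feat.loc[~train])
        held_out_mbi[~train] = test_scores

    filters, fold_of_filter = merge_fold_filters(ensembles, cfg)
    model = ISEModel(
        filters=filters,
        descriptor_names=list(feat.columns),
        config=cfg,
        seed=seed,
        fold_of_filter=fold_of_filter,
        fold_assignment={str(mid): int(fv) for mid, fv in zip(feat.index, fold)},
    )
    scores = pd.DataFrame(
        {"mbi": held_out_mbi, "label": labels.astype(int), "fold": fold},
        index=feat.index,
    )
    return model, scores


# ---------------------------------------------------------------------------
# scoring
# ---------------------------------------------------------------------------


def _mbi_matrix(filters: Sequence[Filter], data: pd.DataFrame) -> np.ndarray:
    """MBI per row of *data* under an ensemble (vectorized over molecules)."""
    n = len(filters)
    total = np.zeros(len(data))
    cols = {name: data[name].to_numpy(dtype=float) for name in data.columns}
    for f in filters:
        passed = np.ones(len(data), dtype=bool)
        for r in f.ranges:
            v = cols[r.descriptor]
            passed &= (v >= r.lo) & (v <= r.hi)
        total += np.where(passed, f.efficiency, -f.inefficiency)
    return total / n


def mbi_score(descriptors: dict[str, float], model: ISEModel) -> dict:
    """Score one molecule; returns ``{'mbi': float, 'passes': [bool per filter]}``."""
    passes = []
    total = 0.0
    for f in model.filters:
        ok = all(r.contains(descriptors[r.descriptor]) for r in f.ranges)
        passes.append(ok)
        total += f.efficiency if ok else -f.inefficiency
    return {"mbi": total / len(model.filters), "passes": passes}


def score_molecules(model: ISEModel, data: pd.DataFrame) -> pd.DataFrame:
    """MBI for every row of a descriptor DataFrame (NaN descriptors excluded with a warning)."""
    feat = data.drop(columns=["label"], errors="ignore")
    needed = {r.descriptor for f in model.filters for r in f.ranges}
    missing = needed - set(feat.columns)
    if missing:
        raise KeyError(f"missing descriptor columns: {sorted(missing)}")
    bad = feat[sorted(needed)].isna().any(axis=1)
    if bad.any():
        logger.warning("excluding %d molecules with NaN descriptors from scoring", int(bad.sum()))
    out = pd.DataFrame(index=feat.index, columns=["mbi"], dtype=float)
    out.loc[~bad, "mbi"] = _mbi_matrix(model.filters, feat.loc[~bad])
    return out


# ---------------------------------------------------------------------------
# evaluation
# ---------------------------------------------------------------------------


def roc_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """ROC AUC via the Mann–Whitney rank statistic with tie-averaging."""
    from scipy.stats import rankdata

    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    n_pos = int(labels.sum())
    n_neg = labels.size - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC undefined for single-class labels")
    ranks = rankdata(scores)
    return (ranks[labels].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)


def score_table(
    scores: np.ndarray,
    labels: np.ndarray,
    cutoffs: Sequence[float],
) -> tuple[pd.DataFrame, float]:
    """TP/FP counts strictly above each MBI cutoff, plus the overall ROC AUC."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    rows = []
    for c in cutoffs:
        above = scores > c
        rows.append(
            {
                "cutoff": c,
                "tp": int(np.count_nonzero(above & labels)),
                "fp": int(np.count_nonzero(above & ~labels)),
            }
        )
    return pd.DataFrame(rows), roc_auc(scores, labels)


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------


def model_to_json(model: ISEModel) -> str:
    payload = {
        "format_version": MODEL_FORMAT_VERSION,
        "seed": model.seed,
        "descriptor_names": model.descriptor_names,
        "config": asdict(model.config),
        "fold_of_filter": model.fold_of_filter,
        "fold_assignment": model.fold_assignment,
        "filters": [
            {
                "ranges": [
                    {"descriptor": r.descriptor, "lo": r.lo, "hi": r.hi} for r in f.ranges
                ],
                "counts": asdict(f.counts),
                "mcc": f.mcc,
                "efficiency": f.efficiency,
                "inefficiency": f.inefficiency,
            }
            for f in model.filters
        ],
    }
    return json.dumps(payload, indent=1, sort_keys=True)


def save_model(model: ISEModel, path: str | Path) -> None:
    Path(path).write_text(model_to_json(model))


def load_model(path: str | Path) -> ISEModel:
    payload = json.loads(Path(path).read_text())
    if payload.get("format_version") != MODEL_FORMAT_VERSION:
        raise ValueError(f"unsupported model format: {payload.get('format_version')}")
    cfg_d = payload["config"]
    cfg_d["filter_sizes"] = tuple(cfg_d["filter_sizes"])
    cfg = ISEConfig(**cfg_d)
    filters = [
        Filter(
            ranges=tuple(DescriptorRange(**r) for r in f["ranges"]),
            counts=ConfusionCounts(**f["counts"]),
            mcc=f["mcc"],
            efficiency=f["efficiency"],
            inefficiency=f["inefficiency"],
        )
        for f in payload["filters"]
    ]
    return ISEModel(
        filters=filters,
        descriptor_names=payload["descriptor_names"],
        config=cfg,
        seed=payload["seed"],
        fold_of_filter=payload.get("fold_of_filter", []),
        fold_assignment=payload.get("fold_assignment", {}),
    )
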