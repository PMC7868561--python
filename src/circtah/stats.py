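"""Enrichment statistics: hypergeometric overlap, permutation null,
preranked GSEA and the knockdown down-regulation filter.

Conventions used throughout:

* upper-tail (enrichment) p-values for both overlap tests;
* empirical permutation p with the add-one correction,
  p = (#null >= observed + 1) / (draws + 1), so p is never exactly 0;
* knockdown fold change FC = mean(control) / mean(knockdown), with
  down-regulation declared when FC >= threshold (default 1.4).  The
  threshold, like its direction, is a parameter.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import warnings

import numpy as np
from scipy import stats as sps


@dataclass
class OverlapTest:
    universe: int
    a: int
    b: int
    overlap: int
    p_value: float


@dataclass
class PermutationResult:
    observed: int
    draws: int
    null_mean: float
    null_sd: float
    p_value: float
    seed: int
    null_counts: np.ndarray = field(repr=False, default=None)


@dataclass
class GseaResult:
    es: float
    p_value: float
    leading_edge: list[str]
    null_es: np.ndarray = field(repr=False, default=None)


def hypergeometric_overlap(universe: int, a: int, b: int, k: int) -> OverlapTest:
    """Exact upper-tail P(X >= k) for the overlap of two sets of sizes a, b
    drawn from a universe of the given size."""
    if a > universe or b > universe:
        raise ValueError("set sizes exceed universe")
    if k > min(a, b):
        raise ValueError("overlap exceeds the smaller set")
    if k < 0:
        raise ValueError("overlap must be >= 0")
    p = float(sps.hypergeom.sf(k - 1, universe, a, b))
    return OverlapTest(universe, a, b, k, min(p, 1.0))


def permutation_overlap(
    universe_ids,
    test_set,
    reference_set,
    draws: int = 20_000,
    seed: int = 0,
) -> PermutationResult:
    """Permutation null for the overlap of ``test_set`` with ``reference_set``.

    Each draw samples ``len(test_set)`` ids without replacement from
    ``universe_ids`` and records the overlap with the reference.  The
    universe can be the full catalog or any subset (e.g. only TF-bound
    circRNAs); the two null models differ only in the ids passed here.
    """
    universe = np.asarray(list(universe_ids))
    n = len(universe)
    test = set(test_set)
    k = len(test)
    if k > n:
        raise ValueError("test set size exceeds universe")
    if draws < 100:
        warnings.warn("fewer than 100 draws gives an unstable empirical p")
    ref = set(reference_set)
    observed = len(test & ref)
    in_ref = np.fromiter((u in ref for u in universe), dtype=bool, count=n)
    rng = np.random.default_rng(seed)
    null = np.empty(draws, dtype=np.int64)
    for i in range(draws):
        idx = rng.choice(n, size=k, replace=False, shuffle=False)
        null[i] = int(in_ref[idx].sum())
    p = (float(np.sum(null >= observed)) + 1.0) / (draws + 1.0)
    return PermutationResult(
        observed=int(observed),
        draws=draws,
        null_mean=float(null.mean()),
        null_sd=float(null.std(ddof=1)) if draws > 1 else 0.0,
        p_value=p,
        seed=seed,
        null_counts=null,
    )


def rank_by_tstat(a: np.ndarray, b: np.ndarray, feature_ids) -> "pd.DataFrame":
    """Rank features by the Welch two-sample t statistic (condition a vs b).

    ``a`` and ``b`` are features × samples matrices.  Features with zero
    variance in both groups and equal means get t = 0.  The list is sorted
    by descending t, ties broken by feature id for determinism.
    """
    import pandas as pd

    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape[1] < 2 or b.shape[1] < 2:
        raise ValueError("need >= 2 samples per condition")
    with np.errstate(divide="ignore", invalid="ignore"):
        t, _ = sps.ttest_ind(a, b, axis=1, equal_var=False)
    t = np.where(np.isnan(t), 0.0, t)
    df = pd.DataFrame({"feature_id": list(feature_ids), "t": t})
    df = df.sort_values(["t", "feature_id"], ascending=[False, True], kind="stable")
    return df.reset_index(drop=True)


def _running_es(scores: np.ndarray, is_hit: np.ndarray, p: float) -> tuple[float, int]:
    """Weighted Kolmogorov–Smirnov running sum; returns (extreme ES, index)."""
    n = len(scores)
    nh = int(is_hit.sum())
    w = np.abs(scores) ** p
    hit_w = np.where(is_hit, w, 0.0)
    denom = hit_w.sum()
    if denom == 0:  # all hit scores are 0: fall back to unweighted hits
        hit_w = is_hit.astype(float)
        denom = hit_w.sum()
    miss = np.where(is_hit, 0.0, 1.0 / (n - nh))
    run = np.cumsum(hit_w / denom - miss)
    i = int(np.argmax(np.abs(run)))
    return float(run[i]), i


def gsea_preranked(
    ranked_ids,
    scores,
    feature_set,
    p: float = 1.0,
    permutations: int = 1000,
    seed: int = 0,
) -> GseaResult:
    """Preranked GSEA enrichment score with a set-permutation p-value.

    Hits are weighted by |score|^p (normalised to sum 1), misses decrement
    by 1/(N − set size); ES is the running-sum extremum.  The p-value
    compares |ES| against random same-size sets whose null ES has the same
    sign as the observed one (add-one corrected).
    """
    ranked_ids = list(ranked_ids)
    scores = np.asarray(scores, dtype=float)
    n = len(ranked_ids)
    fs = set(feature_set)
    if not fs:
        raise ValueError("empty feature set")
    if not fs <= set(ranked_ids):
        raise ValueError("feature set not contained in the ranked list")
    if len(fs) >= n:
        raise ValueError("feature set must be a proper subset of the list")
    is_hit = np.fromiter((fid in fs for fid in ranked_ids), dtype=bool, count=n)
    es, i_ext = _running_es(scores, is_hit, p)
    if es >= 0:
        leading = [fid for fid, h in zip(ranked_ids[: i_ext + 1], is_hit) if h]
    else:
        leading = [
            fid for fid, h in zip(ranked_ids[i_ext:], is_hit[i_ext:]) if h
        ]
    rng = np.random.default_rng(seed)
    nh = len(fs)
    null = np.empty(permutations, dtype=float)
    for j in range(permutations):
        idx = rng.choice(n, size=nh, replace=False, shuffle=False)
        mask = np.zeros(n, dtype=bool)
        mask[idx] = True
        null[j], _ = _running_es(scores, mask, p)
    same_sign = null >= 0 if es >= 0 else null <= 0
    n_same = int(same_sign.sum())
    n_extreme = int(np.sum(np.abs(null[same_sign]) >= abs(es)))
    p_value = (n_extreme + 1.0) / (n_same + 1.0)
    return GseaResult(es=es, p_value=p_value, leading_edge=leading, null_es=null)


def down_regulated_filter(
    knockdown: np.ndarray,
    control: np.ndarray,
    feature_ids,
    threshold: float = 1.4,
) -> set[str]:
    """Features down-regulated after knockdown.

    FC = mean(control) / mean(knockdown) per feature; down ⇔ FC >= threshold.
    A zero knockdown mean gives FC = +inf and the feature is included.
    """
    kd = np.asarray(knockdown, dtype=float)
    ct = np.asarray(control, dtype=float)
    ids = list(feature_ids)
    if kd.shape[0] != ct.shape[0] or kd.shape[0] != len(ids):
        raise ValueError("mismatched feature dimensions")
    kd_mean = kd.mean(axis=1)
    ct_mean = ct.mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        fc = np.where(kd_mean > 0, ct_mean / kd_mean, np.inf)
    return {fid for fid, f in zip(ids, fc) if f >= threshold}
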