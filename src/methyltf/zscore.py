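"""Target-set Z statistic and the threshold sweep that extremizes it.

For one TF, every unique score value t partitions the gene universe into a
putative target set (score strictly greater than t) and the rest.  The Z
statistic of a target set of size k with mean log expression m is

    Z = (m - mu) / (sigma / sqrt(k)),

the one-sample Z of the target mean against the cohort background — so a
large |Z| marks thresholds at which the TF's high-scoring genes are
coherently over- (Z > 0) or under-expressed (Z < 0).  The sweep evaluates
every admissible threshold and reports the Z of maximal absolute value
with its sign preserved (written Z_m), together with the best threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence, Tuple, Union

import numpy as np

from .containers import ExpressionVector, ValidationError


def zscore(target_values, background: ExpressionVector) -> float:
    """One-sample Z of a target subset's mean against the background."""
    vals = np.asarray(target_values, dtype=float)
    if vals.size == 0:
        raise ValidationError("zscore undefined for an empty target set")
    k = vals.size
    return float((vals.mean() - background.mu) / (background.sigma / np.sqrt(k)))


@dataclass
class ZCurve:
    """Threshold sweep result for one TF.

    ``thresholds`` are ascending unique score values; ``k[i]`` genes score
    strictly above ``thresholds[i]`` (weakly decreasing in t); ``z`` holds
    the statistic at each admissible threshold.  ``empty`` marks a TF with
    no admissible threshold; such TFs are excluded downstream.  The
    extremum convention: ``z_m`` is the Z of maximal absolute value, sign
    preserved; ties on |Z| break toward larger k, then smaller threshold.
    """

    tf_id: str
    thresholds: np.ndarray
    k: np.ndarray
    z: np.ndarray
    z_m: float
    t_star: float
    k_star: int
    n_universe: int
    empty: bool = False


def _sweep_kernel(
    scores: np.ndarray,
    expr_vals: np.ndarray,
    mu: float,
    sigma: float,
    k_min: int,
    k_max: float,
) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Z at every admissible strict cut; returns ascending (t, k, z)."""
    order = np.argsort(-scores, kind="stable")
    s = scores[order]
    e = expr_vals[order]
    csum = np.cumsum(e)
    # first occurrence of each unique value in the descending order
    first = np.flatnonzero(np.concatenate(([True], s[1:] != s[:-1])))
    thr = s[first]
    k = first  # number of genes strictly greater than thr
    ok = (k >= k_min) & (k <= k_max)
    thr, k = thr[ok], k[ok]
    if thr.size == 0:
        return thr, k, thr
    means = csum[k - 1] / k
    z = (means - mu) / (sigma / np.sqrt(k))
    rev = slice(None, None, -1)  # ascending threshold order
    return thr[rev], k[rev], z[rev]


def sweep_thresholds(
    scores: Union[Mapping[str, float], Tuple[Sequence[str], np.ndarray]],
    expr: ExpressionVector,
    k_min: int = 10,
    k_max_frac: float = 0.5,
    tf_id: str = "?",
) -> ZCurve:
    """Sweep all candidate match/binding-score thresholds for one TF.

    ``scores`` maps gene_id -> score (NaN marks degenerate genes, which are
    dropped).  The universe is the intersection of scored genes with the
    expression table; candidate thresholds are the sorted unique scores;
    target sets use a strict cut (score > t).  Thresholds with fewer than
    ``k_min`` or more than ``k_max_frac * n`` targets are excluded — the
    normal approximation behind Z needs a reasonably sized target set, and
    near-total target sets carry no contrast.
    """
    if k_min < 2:
        raise ValueError("k_min must be >= 2")
    if isinstance(scores, Mapping):
        gene_ids = list(scores)
        vals = np.array([scores[g] for g in gene_ids], dtype=float)
    else:
        gene_ids, vals = list(scores[0]), np.asarray(scores[1], dtype=float)
    keep = [
        i
        for i, g in enumerate(gene_ids)
        if g in expr and not np.isnan(vals[i])
    ]
    universe = np.array(keep, dtype=int)
    n = universe.size
    empty_curve = ZCurve(
        tf_id, np.empty(0), np.empty(0, int), np.empty(0), np.nan, np.nan, 0, n, True
    )
    if n == 0:
        return empty_curve
    s = vals[universe]
    e = np.array([expr[gene_ids[i]] for i in universe])
    thr, k, z = _sweep_kernel(s, e, expr.mu, expr.sigma, k_min, k_max_frac * n)
    if thr.size == 0:
        return empty_curve
    pick = np.lexsort((thr, -k, -np.abs(z)))[0]
    return ZCurve(
        tf_id,
        thr,
        k.astype(int),
        z,
        float(z[pick]),
        float(thr[pick]),
        int(k[pick]),
        n,
        False,
    )
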