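"""Grid search over the methylation model and the active-TF classification.

For each TF three extremized Z statistics are compared:

* ``Z_m_o`` — from sequence-only match scores (no methylation);
* ``Z_m_p`` — the extreme over a (C, S) grid of sense-model binding scores,
  where methylation attenuates binding;
* ``Z_m_q`` — the same search under the antisense (mirror) model, a
  wrong-signed control.

A TF is called functionally active when (1) |Z_m_p| beats |Z_m_o| by at
least a ratio margin (fixed, or derived as a percentile of the cohort's
|Z_m_p|/|Z_m_o| ratios), and (2) every grid cell's |Z_m_q| stays strictly
below |Z_m_o|.  The first standard demands that modeling methylation
sharpens the binding-expression link; the second rejects TFs whose gain is
reproduced by the wrong-signed model and hence is not methylation-specific.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.stats import wilcoxon

from .containers import ExpressionVector, MethylationTrack, PromoterSet, PWM
from .model import ModelParams, SiteTable, collect_sites
from .zscore import ZCurve, _sweep_kernel, sweep_thresholds

logger = logging.getLogger(__name__)

DEFAULT_C_GRID = tuple(np.round(np.arange(-2.0, 2.0001, 0.05), 10))
DEFAULT_S_GRID = (0.01, 0.05, 0.1)


@dataclass
class GridResult:
    """Z_m over a (C, S) grid for one TF and orientation.

    ``z_m[i, j]`` corresponds to ``(C_values[i], S_values[j])``; NaN marks
    cells with no admissible threshold.  The extreme is the cell of maximal
    |Z_m| (sign preserved); ties break toward smaller |C| then smaller S —
    the weakest model that achieves the extremum.
    """

    tf_id: str
    orientation: str
    C_values: np.ndarray
    S_values: np.ndarray
    z_m: np.ndarray
    extreme_z: float
    C_star: float
    S_star: float

    @property
    def empty(self) -> bool:
        return bool(np.all(np.isnan(self.z_m)))

    def max_abs_z(self) -> float:
        if self.empty:
            return np.nan
        return float(np.nanmax(np.abs(self.z_m)))

    def curve(self, steepness: float) -> np.ndarray:
        """The C -> Z_m slice at one steepness value."""
        j = int(np.argmin(np.abs(self.S_values - steepness)))
        return self.z_m[:, j]


def _select_extreme(
    z_m: np.ndarray, C_values: np.ndarray, S_values: np.ndarray
) -> Tuple[float, float, float]:
    ok = ~np.isnan(z_m)
    if not np.any(ok):
        return np.nan, np.nan, np.nan
    ci, sj = np.nonzero(ok)
    zs = z_m[ci, sj]
    order = np.lexsort((S_values[sj], np.abs(C_values[ci]), -np.abs(zs)))
    b = order[0]
    return float(zs[b]), float(C_values[ci[b]]), float(S_values[sj[b]])


def grid_search(
    table: SiteTable,
    expr: ExpressionVector,
    C_grid: Sequence[float] = DEFAULT_C_GRID,
    S_grid: Sequence[float] = DEFAULT_S_GRID,
    orientation: str = "sense",
    k_min: int = 10,
    k_max_frac: float = 0.5,
    missing_policy: str = "neutral",
) -> GridResult:
    """Z_m for every (C, S): binding scores -> threshold sweep -> extremum."""
    C_values = np.asarray(C_grid, dtype=float)
    S_values = np.asarray(S_grid, dtype=float)
    if C_values.size == 0 or S_values.size == 0:
        raise ValueError("C and S grids must be nonempty")
    if np.any(S_values <= 0):
        raise ValueError("all S values must be > 0")
    # fix the gene universe once: scored genes present in the expression set
    in_expr = np.array([g in expr for g in table.gene_ids])
    e_all = np.array([expr[g] if ok else np.nan for g, ok in zip(table.gene_ids, in_expr)])
    z_m = np.full((C_values.size, S_values.size), np.nan)
    for j, S in enumerate(S_values):
        for i, C in enumerate(C_values):
            params = ModelParams(center=C, steepness=S, orientation=orientation)
            b = table.binding_scores(params, missing_policy)
            ok = in_expr & ~np.isnan(b)
            n = int(ok.sum())
            if n == 0:
                continue
            thr, k, z = _sweep_kernel(
                b[ok], e_all[ok], expr.mu, expr.sigma, k_min, k_max_frac * n
            )
            if thr.size == 0:
                continue
            pick = np.lexsort((thr, -k, -np.abs(z)))[0]
            z_m[i, j] = z[pick]
    extreme, C_star, S_star = _select_extreme(z_m, C_values, S_values)
    return GridResult(
        table.tf_id, orientation, C_values, S_values, z_m, extreme, C_star, S_star
    )


@dataclass
class ActivityCall:
    """Verdict for one TF."""

    tf_id: str
    tf_name: str
    z_m_o: float
    z_m_p: float
    C_star: float
    S_star: float
    max_abs_z_m_q: float
    ratio: float
    active: bool
    direction: str
    sign_flip: bool = False


def classify(
    tf_id: str,
    tf_name: str,
    z_m_o: float,
    sense: GridResult,
    antisense: GridResult,
    ratio_margin: float = 0.10,
) -> ActivityCall:
    """Apply the two activity standards to one TF.

    Standards operate on absolute values with the sign carried as a
    direction label (positive = activator, negative = repressor, from the
    sign of Z_m_o).  A sign disagreement between Z_m_o and the extreme
    Z_m_p is flagged for manual review but does not change the call.
    """
    if np.isnan(z_m_o):
        raise ValueError(f"{tf_id}: Z_m_o undefined")
    z_m_p = sense.extreme_z
    max_q = antisense.max_abs_z()
    ratio = abs(z_m_p) / abs(z_m_o) if abs(z_m_o) > 0 else np.inf
    gain_ok = abs(z_m_p) >= (1.0 + ratio_margin) * abs(z_m_o)
    # The second standard is a for-all over the grid (an empty antisense
    # grid is vacuously satisfied).  Only strict exceedance vetoes: grid
    # corners where the antisense sigmoid saturates to E = 1 degenerate to
    # the no-effect limit and reproduce the match-score Z exactly, and
    # merely reproducing the baseline is no evidence for the wrong-signed
    # model.  |Z_m_q| equal to |Z_m_o| from a *different* target set would
    # also be tolerated, but two distinct gene sets tie in Z only on a
    # measure-zero coincidence.
    control_ok = bool(np.isnan(max_q)) or max_q <= abs(z_m_o)
    return ActivityCall(
        tf_id=tf_id,
        tf_name=tf_name,
        z_m_o=float(z_m_o),
        z_m_p=float(z_m_p),
        C_star=sense.C_star,
        S_star=sense.S_star,
        max_abs_z_m_q=float(max_q) if not np.isnan(max_q) else np.nan,
        ratio=float(ratio),
        active=bool(gain_ok and control_ok and not np.isnan(z_m_p)),
        direction="positive" if z_m_o >= 0 else "negative",
        sign_flip=bool(not np.isnan(z_m_p) and np.sign(z_m_p) != np.sign(z_m_o)),
    )


def derive_ratio_margin(
    ratios: Sequence[float], percentile: float = 0.9, default: float = 0.10
) -> float:
    """Margin = (empirical percentile of |Z_m_p|/|Z_m_o| ratios) - 1.

    Uses the linear-interpolation percentile definition and floors the
    margin at 0.  With fewer than 10 ratios the empirical percentile is too
    unstable; the fixed default is returned with a warning.
    """
    arr = np.asarray([r for r in ratios if np.isfinite(r)], dtype=float)
    if arr.size < 10:
        logger.warning(
            "only %d ratios available; falling back to fixed margin %.2f",
            arr.size,
            default,
        )
        return default
    return max(0.0, float(np.quantile(arr, percentile)) - 1.0)


@dataclass
class WilcoxonReport:
    statistic: float
    pvalue: float
    n: int
    degenerate: bool = False


def compare_distributions(
    z_m_o: Sequence[float], z_m_p: Sequence[float]
) -> WilcoxonReport:
    """Paired two-sided Wilcoxon signed-rank test of Z_m_p against Z_m_o."""
    a = np.asarray(z_m_o, dtype=float)
    b = np.asarray(z_m_p, dtype=float)
    if a.shape != b.shape or a.size < 6:
        raise ValueError("need paired lists of equal length >= 6")
    if np.allclose(a, b):
        return WilcoxonReport(0.0, 1.0, a.size, degenerate=True)
    stat, p = wilcoxon(b, a, alternative="two-sided")
    return WilcoxonReport(float(stat), float(p), a.size)


_TABLE_COLUMNS = ["rank", "tf_id", "tf_name", "z_m_o", "z_m_p", "C", "S"]


def rank_and_report(
    calls: Sequence[ActivityCall], dedup: bool = True
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Ranked tables of active TFs: (positive, negative).

    Positive-direction TFs sort by extreme Z_m_p descending; negatives by
    |Z_m_p| descending.  With ``dedup``, one entry per tf_name survives —
    the one with the largest |Z_m_p| — so near-identical matrices for the
    same factor appear once.
    """
    active = [c for c in calls if c.active]
    if dedup:
        best: Dict[str, ActivityCall] = {}
        for c in active:
            prev = best.get(c.tf_name)
            if prev is None or abs(c.z_m_p) > abs(prev.z_m_p):
                best[c.tf_name] = c
        active = list(best.values())

    def table(rows: List[ActivityCall]) -> pd.DataFrame:
        data = [
            (r + 1, c.tf_id, c.tf_name, c.z_m_o, c.z_m_p, c.C_star, c.S_star)
            for r, c in enumerate(rows)
        ]
        return pd.DataFrame(data, columns=_TABLE_COLUMNS)

    pos = sorted(
        (c for c in active if c.direction == "positive"),
        key=lambda c: -c.z_m_p,
    )
    neg = sorted(
        (c for c in active if c.direction == "negative"),
        key=lambda c: -abs(c.z_m_p),
    )
    return table(pos), table(neg)


@dataclass
class ScreenConfig:
    """Everything tunable about the screen, with the defaults used throughout.

    ``ratio_margin`` is either a fixed fraction (default 0.10, the margin
    the activity standard is usually quoted with) or the string
    ``"percentile"``, which derives the margin from the cohort's own
    |Z_m_p|/|Z_m_o| ratio distribution (falling back to the fixed default
    when fewer than 10 TFs survive).  Percentile derivation presumes a
    large compendium in which most TFs carry a substantial |Z_m_o|; in
    small or null-heavy cohorts, near-zero denominators inflate the upper
    ratio percentiles and the derived margin loses meaning, hence the
    fixed default.
    """

    strands: str = "both"
    k_min: int = 10
    k_max_frac: float = 0.5
    C_grid: Sequence[float] = DEFAULT_C_GRID
    S_grid: Sequence[float] = DEFAULT_S_GRID
    top_k: int = 50
    missing_policy: str = "neutral"
    ratio_margin: object = 0.10
    ratio_percentile: float = 0.9


@dataclass
class ScreenResult:
    calls: List[ActivityCall]
    excluded: Dict[str, str]
    margin: float
    wilcoxon: Optional[WilcoxonReport]
    positive_table: pd.DataFrame
    negative_table: pd.DataFrame
    z_curves: Dict[str, ZCurve]
    grids: Dict[str, Tuple[GridResult, GridResult]]

    @property
    def active(self) -> List[ActivityCall]:
        return [c for c in self.calls if c.active]


def run_screen(
    pwms: Sequence[PWM],
    promoters: PromoterSet,
    track: MethylationTrack,
    expr: ExpressionVector,
    config: ScreenConfig = ScreenConfig(),
) -> ScreenResult:
    """End-to-end screen: scan, sweep, grid-search both orientations, classify."""
    universe = [g for g in promoters.gene_ids if g in expr]
    mismatch = 1.0 - len(universe) / max(len(promoters), 1)
    if mismatch > 0:
        logger.info(
            "gene universe: %d promoters, %d with expression (%.1f%% dropped)",
            len(promoters),
            len(universe),
            100 * mismatch,
        )
    z_curves: Dict[str, ZCurve] = {}
    grids: Dict[str, Tuple[GridResult, GridResult]] = {}
    excluded: Dict[str, str] = {}
    pending: List[Tuple[PWM, float, GridResult, GridResult]] = []
    for pwm in pwms:
        n_sites = max(len(p) for p in promoters) - pwm.length + 1
        if config.top_k < n_sites:
            logger.debug(
                "%s: retaining top %d of up to %d sites per gene (approximation)",
                pwm.tf_id,
                config.top_k,
                n_sites,
            )
        table = collect_sites(
            pwm, promoters, track, top_k=config.top_k, strands=config.strands
        )
        curve = sweep_thresholds(
            (table.gene_ids, table.match_scores()),
            expr,
            k_min=config.k_min,
            k_max_frac=config.k_max_frac,
            tf_id=pwm.tf_id,
        )
        if curve.empty:
            excluded[pwm.tf_id] = "no admissible match-score threshold"
            continue
        z_curves[pwm.tf_id] = curve
        kwargs = dict(
            C_grid=config.C_grid,
            S_grid=config.S_grid,
            k_min=config.k_min,
            k_max_frac=config.k_max_frac,
            missing_policy=config.missing_policy,
        )
        sense = grid_search(table, expr, orientation="sense", **kwargs)
        anti = grid_search(table, expr, orientation="antisense", **kwargs)
        if sense.empty:
            excluded[pwm.tf_id] = "sense grid has no admissible cell"
            continue
        grids[pwm.tf_id] = (sense, anti)
        pending.append((pwm, curve.z_m, sense, anti))

    ratios = [abs(s.extreme_z) / abs(z) for _, z, s, _ in pending if abs(z) > 0]
    if config.ratio_margin == "percentile":
        margin = derive_ratio_margin(ratios, percentile=config.ratio_percentile)
    else:
        margin = float(config.ratio_margin)

    calls = [
        classify(pwm.tf_id, pwm.tf_name, z_m_o, sense, anti, ratio_margin=margin)
        for pwm, z_m_o, sense, anti in pending
    ]
    wilcox = None
    if len(calls) >= 6:
        wilcox = compare_distributions(
            [c.z_m_o for c in calls], [c.z_m_p for c in calls]
        )
    pos, neg = rank_and_report(calls)
    return ScreenResult(calls, excluded, margin, wilcox, pos, neg, z_curves, grids)
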