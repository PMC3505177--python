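"""Sigmoid methylation-effect model and methylation-weighted binding scores.

The effect of a site's methylation level M on TF binding is modeled as a
logistic attenuation in (0, 1) with two per-TF parameters: a center C (the
log2-ratio level at which half the binding ability is lost) and a
steepness S > 0 (the width of the transition; S = 0.01 is nearly a step).

* sense orientation:      E = expit(-(M - C) / S)  — decreasing in M,
  encoding that promoter methylation weakens binding;
* antisense orientation:  E = expit(+(M - C) / S)  — the exact mirror
  (sense + antisense = 1), a deliberately wrong-signed control used by the
  screen to reject TFs whose apparent signal is not methylation-specific.

A site's binding value is its sequence match value times its effect; the
binding score of a (TF, gene) pair is the maximum of that product over
sites, so the winning site may differ from the best sequence match.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
from scipy.special import expit

from .containers import MethylationTrack, PromoterSet, PWM, ValidationError
from .scan import ScoreMatrix, SiteScores, match_values

ORIENTATIONS = ("sense", "antisense")
MISSING_POLICIES = ("neutral", "skip")


@dataclass(frozen=True)
class ModelParams:
    """Parameters of the methylation-effect sigmoid for one TF."""

    center: float
    steepness: float
    orientation: str = "sense"

    def __post_init__(self) -> None:
        if not self.steepness > 0:
            raise ValidationError(f"steepness must be > 0, got {self.steepness}")
        if self.orientation not in ORIENTATIONS:
            raise ValidationError(f"orientation must be one of {ORIENTATIONS}")


def effect_sense(M, center: float, steepness: float):
    """Attenuation that decreases with methylation (inverse S-curve).

    ``expit`` evaluates the logistic in a branch-safe form, so exponents of
    +/-400 (S = 0.01 with |M - C| up to 4) saturate cleanly to 0 or 1.
    """
    return expit(-(np.asarray(M, dtype=float) - center) / steepness)


def effect_antisense(M, center: float, steepness: float):
    """Mirror model, increasing with methylation; sense + antisense = 1."""
    return expit((np.asarray(M, dtype=float) - center) / steepness)


def effect(M, params: ModelParams):
    fn = effect_sense if params.orientation == "sense" else effect_antisense
    return fn(M, params.center, params.steepness)


def site_methylation(
    track: MethylationTrack, gene_id: str, site_index: int, L: int
) -> Tuple[float, float]:
    """Mean methylation of the L-bp site window, with the fraction present.

    Returns ``(NaN, 0.0)`` when no base in the window has data.
    """
    means, frac = track.window_means(gene_id, np.array([site_index]), L)
    return float(means[0]), float(frac[0])


def _apply_effect(
    A: np.ndarray, M: np.ndarray, params: ModelParams, missing_policy: str
) -> np.ndarray:
    """Per-site A*E with the missing-methylation policy applied.

    NaN in ``A`` marks padding (no site) and propagates; NaN in ``M`` with a
    real A marks missing methylation: neutral -> E = 1, skip -> site removed.
    """
    if missing_policy not in MISSING_POLICIES:
        raise ValueError(f"missing_policy must be one of {MISSING_POLICIES}")
    missing = np.isnan(M) & ~np.isnan(A)
    E = effect(np.where(np.isnan(M), 0.0, M), params)
    if missing_policy == "neutral":
        E = np.where(missing, 1.0, E)
        return A * E
    out = A * E
    out[missing] = np.nan
    return out


def binding_score(
    sites: SiteScores,
    track: MethylationTrack,
    params: ModelParams,
    missing_policy: str = "neutral",
) -> Tuple[float, Optional[Tuple[int, int]]]:
    """Maximum of match value x methylation effect over a gene's sites.

    Tie-break matches :func:`methyltf.scan.match_score` (smallest site
    index, sense before revcomp).  Returns ``(-inf, None)`` when no site
    survives (empty input, or all sites skipped under the skip policy).
    """
    if len(sites) == 0:
        return float("-inf"), None
    if sites.gene_id in track:
        M, _ = track.window_means(sites.gene_id, sites.site_index, sites.motif_length)
    else:
        M = np.full(len(sites), np.nan)
    weighted = _apply_effect(sites.match_value, M, params, missing_policy)
    ok = ~np.isnan(weighted)
    if not np.any(ok):
        return float("-inf"), None
    order = np.lexsort((sites.strand[ok], sites.site_index[ok], -weighted[ok]))
    best = np.flatnonzero(ok)[order[0]]
    return float(weighted[best]), (
        int(sites.site_index[best]),
        int(sites.strand[best]),
    )


class SiteTable:
    """Retained candidate sites of one TF across all genes, as padded arrays.

    Rows are genes; columns hold up to ``top_k`` sites ordered by
    (site_index, sense-first) so that first-occurrence argmax reproduces the
    documented tie-break.  ``A`` is NaN where a row has fewer sites; ``M``
    is NaN for padding *and* for genuinely missing methylation (the two are
    told apart via ``A``).
    """

    def __init__(
        self,
        tf_id: str,
        motif_length: int,
        gene_ids: Sequence[str],
        A: np.ndarray,
        M: np.ndarray,
        site_index: np.ndarray,
        strand: np.ndarray,
    ) -> None:
        self.tf_id = tf_id
        self.motif_length = motif_length
        self.gene_ids = list(gene_ids)
        self.A = A
        self.M = M
        self.site_index = site_index
        self.strand = strand

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    def binding_scores(
        self, params: ModelParams, missing_policy: str = "neutral"
    ) -> np.ndarray:
        """Binding score per gene under one parameter setting (NaN = degenerate)."""
        weighted = _apply_effect(self.A, self.M, params, missing_policy)
        all_nan = np.all(np.isnan(weighted), axis=1)
        with np.errstate(all="ignore"):
            out = np.where(all_nan, np.nan, np.nanmax(weighted, axis=1))
        return out

    def match_scores(self) -> np.ndarray:
        """Sequence-only match score per gene (max A, NaN = degenerate)."""
        all_nan = np.all(np.isnan(self.A), axis=1)
        with np.errstate(all="ignore"):
            return np.where(all_nan, np.nan, np.nanmax(self.A, axis=1))


def collect_sites(
    pwm: PWM,
    promoters: PromoterSet,
    track: Optional[MethylationTrack] = None,
    top_k: int = 50,
    strands: str = "both",
) -> SiteTable:
    """Scan all promoters for one TF, retaining the top-K sites per gene.

    All candidate sites, not only each gene's best sequence match, feed the
    binding score so its max-over-sites of A x E is computed correctly;
    ``top_k`` bounds memory (retention below the full site count is an
    approximation and is logged by the caller).  Genes shorter than the
    motif contribute an all-NaN row.
    """
    gene_ids = promoters.gene_ids
    L = pwm.length
    k_cap = max(1, top_k)
    A = np.full((len(gene_ids), k_cap), np.nan)
    M = np.full((len(gene_ids), k_cap), np.nan)
    site_idx = np.full((len(gene_ids), k_cap), -1, dtype=np.int64)
    strand = np.zeros((len(gene_ids), k_cap), dtype=np.uint8)
    for g, gene_id in enumerate(gene_ids):
        sites = match_values(pwm, promoters[gene_id], strands=strands)
        if len(sites) == 0:
            continue
        if len(sites) > k_cap:
            order = np.lexsort((sites.strand, sites.site_index, -sites.match_value))
            keep = order[:k_cap]
        else:
            keep = np.arange(len(sites))
        # store in (site_index, sense-first) order for deterministic argmax
        sub = np.lexsort((sites.strand[keep], sites.site_index[keep]))
        keep = keep[sub]
        m = len(keep)
        A[g, :m] = sites.match_value[keep]
        site_idx[g, :m] = sites.site_index[keep]
        strand[g, :m] = sites.strand[keep]
        if track is not None and gene_id in track:
            means, _ = track.window_means(gene_id, sites.site_index[keep], L)
            M[g, :m] = means
    return SiteTable(pwm.tf_id, L, gene_ids, A, M, site_idx, strand)


def binding_matrix(
    tables: Sequence[SiteTable],
    params: ModelParams,
    missing_policy: str = "neutral",
) -> ScoreMatrix:
    """Binding scores for all TFs under one (C, S, orientation)."""
    if not tables:
        raise ValueError("binding_matrix needs at least one SiteTable")
    gene_ids = tables[0].gene_ids
    values = np.vstack([t.binding_scores(params, missing_policy) for t in tables])
    # argmax bookkeeping per cell
    T, G = values.shape
    argmax_site = np.full((T, G), -1, dtype=np.int64)
    argmax_strand = np.zeros((T, G), dtype=np.uint8)
    for t, table in enumerate(tables):
        weighted = _apply_effect(table.A, table.M, params, missing_policy)
        filled = np.where(np.isnan(weighted), -np.inf, weighted)
        best = np.argmax(filled, axis=1)
        ok = ~np.isnan(values[t])
        rows = np.flatnonzero(ok)
        argmax_site[t, rows] = table.site_index[rows, best[rows]]
        argmax_strand[t, rows] = table.strand[rows, best[rows]]
    return ScoreMatrix([t.tf_id for t in tables], list(gene_ids), values, argmax_site, argmax_strand)
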