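"""PWM promoter scanning: per-site match values and per-gene match scores.

A promoter of length N scanned with a motif of length L yields N - L + 1
candidate sites per strand.  The match value of a site is the one-hot dot
product between the window and the PWM (an N base contributes weight 0).
The match score of a (TF, gene) pair is the maximum match value over all
sites and scanned strands; ties break toward the smallest site index with
sense before reverse-complement, so the argmax site — which downstream
methylation lookup depends on — is deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .containers import PromoterSet, PWM

SENSE = 0
REVCOMP = 1
_STRAND_LABEL = {SENSE: "sense", REVCOMP: "revcomp"}

# base codes: A=0 C=1 G=2 T=3 N=4
_LUT = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _LUT[ord(_b)] = _i
    _LUT[ord(_b.lower())] = _i
#: complement of each base code (N maps to N)
_COMP = np.array([3, 2, 1, 0, 4], dtype=np.uint8)


def encode_sequence(seq: str) -> np.ndarray:
    """Encode ACGTN into uint8 codes (anything else counts as N)."""
    return _LUT[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def _padded_weights(pwm: PWM) -> np.ndarray:
    """PWM weights with a fifth, all-zero column for N."""
    w5 = np.zeros((pwm.length, 5))
    w5[:, :4] = pwm.weights
    return w5


def _window_sums(codes: np.ndarray, w5: np.ndarray) -> np.ndarray:
    """Match values of every window; ``codes`` may be 1-D or (genes, N)."""
    L = w5.shape[0]
    n_sites = codes.shape[-1] - L + 1
    out = np.zeros(codes.shape[:-1] + (n_sites,))
    for l in range(L):
        out += w5[l, codes[..., l : l + n_sites]]
    return out


@dataclass
class SiteScores:
    """All candidate sites of one (TF, gene) pair.

    ``site_index`` is the 0-based promoter offset of a site's first base —
    for reverse-complement hits this is still the leftmost base in promoter
    coordinates, so the methylated window is [site_index, site_index + L)
    on either strand.
    """

    tf_id: str
    gene_id: str
    motif_length: int
    site_index: np.ndarray
    strand: np.ndarray  # SENSE / REVCOMP codes
    match_value: np.ndarray

    def __len__(self) -> int:
        return len(self.site_index)

    def strand_labels(self) -> List[str]:
        return [_STRAND_LABEL[s] for s in self.strand]


def match_values(pwm: PWM, promoter, strands: str = "both") -> SiteScores:
    """Score every window of a promoter against a PWM.

    ``promoter`` may be a :class:`~methyltf.containers.Promoter` or a plain
    sequence string.  A promoter shorter than the motif yields an empty
    site list (the gene is handled by the degenerate-gene policy upstream).
    """
    if strands not in ("sense", "both"):
        raise ValueError(f"strands must be 'sense' or 'both', got {strands!r}")
    gene_id = getattr(promoter, "gene_id", "?")
    seq = getattr(promoter, "sequence", promoter)
    codes = encode_sequence(seq)
    L = pwm.length
    n = codes.shape[0]
    if n < L:
        empty = np.empty(0)
        return SiteScores(
            pwm.tf_id, gene_id, L, empty.astype(int), empty.astype(np.uint8), empty
        )
    w5 = _padded_weights(pwm)
    vals = [_window_sums(codes, w5)]
    idx = [np.arange(n - L + 1)]
    strand_arr = [np.zeros(n - L + 1, dtype=np.uint8)]
    if strands == "both":
        rc = _COMP[codes][::-1]
        rc_vals = _window_sums(rc, w5)
        # window starting at k' on the reverse complement covers promoter
        # positions [n - L - k', n - k'), i.e. leftmost base n - L - k'
        vals.append(rc_vals)
        idx.append(n - L - np.arange(n - L + 1))
        strand_arr.append(np.ones(n - L + 1, dtype=np.uint8))
    return SiteScores(
        pwm.tf_id,
        gene_id,
        L,
        np.concatenate(idx),
        np.concatenate(strand_arr),
        np.concatenate(vals),
    )


def match_score(sites: SiteScores) -> Tuple[float, Optional[Tuple[int, int]]]:
    """Maximum match value and its site, ``(score, (site_index, strand))``.

    Ties break toward the smallest site index, sense before revcomp.  An
    empty site list returns ``(-inf, None)``; the caller decides whether
    that gene enters the threshold analysis.
    """
    if len(sites) == 0:
        return float("-inf"), None
    order = np.lexsort((sites.strand, sites.site_index, -sites.match_value))
    best = order[0]
    return float(sites.match_value[best]), (
        int(sites.site_index[best]),
        int(sites.strand[best]),
    )


@dataclass
class ScoreMatrix:
    """TF x gene matrix of match (or binding) scores.

    ``values[t, g]`` is NaN for degenerate pairs (promoter shorter than the
    motif, or no retainable site) — those genes are excluded from the TF's
    threshold analysis rather than given a sentinel score.  ``argmax_site``
    and ``argmax_strand`` record the winning site of each cell (-1 where
    degenerate).
    """

    tf_ids: List[str]
    gene_ids: List[str]
    values: np.ndarray
    argmax_site: np.ndarray
    argmax_strand: np.ndarray
    skipped: Dict[str, List[str]] = field(default_factory=dict)

    def row(self, tf_id: str) -> np.ndarray:
        return self.values[self.tf_ids.index(tf_id)]

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(self.values, index=self.tf_ids, columns=self.gene_ids)


def _argmax_with_ties(sense: np.ndarray, rc_rev: np.ndarray) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Row-wise max over interleaved (site_index asc, sense-first) columns.

    ``sense[g, k]`` is the sense window at offset k; ``rc_rev[g, k]`` the
    revcomp window whose leftmost promoter base is also k.  Interleaving
    makes ``argmax``'s first-occurrence rule implement the tie-break.
    """
    g, ns = sense.shape
    if rc_rev is None:
        comb = sense
        per_site = 1
    else:
        comb = np.empty((g, 2 * ns))
        comb[:, 0::2] = sense
        comb[:, 1::2] = rc_rev
        per_site = 2
    flat = np.argmax(comb, axis=1)
    return (
        comb[np.arange(g), flat],
        flat // per_site,
        (flat % per_site).astype(np.uint8),
    )


def scan_all(
    pwms: Sequence[PWM], promoters: PromoterSet, strands: str = "both"
) -> ScoreMatrix:
    """Match scores for every (TF, gene) pair.

    Genes are grouped by promoter length so each group scans as one matrix
    operation; results are bit-identical to per-pair :func:`match_score`.
    """
    if not pwms or len(promoters) == 0:
        raise ValueError("scan_all needs at least one PWM and one promoter")
    gene_ids = promoters.gene_ids
    gene_pos = {g: i for i, g in enumerate(gene_ids)}
    by_len: Dict[int, List[str]] = {}
    for p in promoters:
        by_len.setdefault(len(p), []).append(p.gene_id)
    enc = {
        n: (genes, np.vstack([encode_sequence(promoters[g].sequence) for g in genes]))
        for n, genes in by_len.items()
    }

    T, G = len(pwms), len(gene_ids)
    values = np.full((T, G), np.nan)
    argmax_site = np.full((T, G), -1, dtype=np.int64)
    argmax_strand = np.zeros((T, G), dtype=np.uint8)
    skipped: Dict[str, List[str]] = {}
    for t, pwm in enumerate(pwms):
        L = pwm.length
        w5 = _padded_weights(pwm)
        for n, (genes, codes2d) in enc.items():
            cols = [gene_pos[g] for g in genes]
            if n < L:
                skipped.setdefault(pwm.tf_id, []).extend(genes)
                continue
            sense = _window_sums(codes2d, w5)
            rc_rev = None
            if strands == "both":
                rc = _COMP[codes2d][:, ::-1]
                rc_rev = _window_sums(rc, w5)[:, ::-1]
            best, site, strand = _argmax_with_ties(sense, rc_rev)
            values[t, cols] = best
            argmax_site[t, cols] = site
            argmax_strand[t, cols] = strand
    return ScoreMatrix(
        [p.tf_id for p in pwms], gene_ids, values, argmax_site, argmax_strand, skipped
    )
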