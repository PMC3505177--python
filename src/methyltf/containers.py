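"""Core data containers shared across the pipeline.

Conventions used throughout:

* genomic coordinates are 0-based, half-open;
* promoter sequences are stored 5'->3' on the gene's sense strand, so
  local index 0 is always the most-upstream base of the window;
* methylation values live on the MeDIP log2-ratio scale and are aligned
  index-for-index with the promoter sequence (``NaN`` marks missing data);
* expression values are on a log scale.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, Iterator, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

BASES = "ACGT"
PROMOTER_ALPHABET = frozenset("ACGTN")

#: IUPAC ambiguity codes other than N that are collapsed to N on load.
_IUPAC_AMBIGUOUS = set("RYSWKMBDHV")


class ValidationError(ValueError):
    """An input object violates one of its documented invariants."""


@dataclass(frozen=True)
class PWM:
    """A position weight matrix for one transcription factor.

    ``weights`` has one row per motif position and four columns in the
    fixed order A, C, G, T.  Weights are taken verbatim from the source
    file (counts, frequencies or scores) but must be finite and
    nonnegative: the downstream binding score multiplies each window's
    match value by an attenuation in (0, 1), which only makes sense for
    nonnegative weights.
    """

    tf_id: str
    tf_name: str
    weights: np.ndarray

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if w.ndim != 2 or w.shape[1] != 4 or w.shape[0] < 1:
            raise ValidationError(
                f"PWM {self.tf_id!r}: weights must be an Lx4 matrix, got shape {w.shape}"
            )
        if not np.all(np.isfinite(w)):
            raise ValidationError(f"PWM {self.tf_id!r}: weights must be finite")
        if np.any(w < 0):
            raise ValidationError(f"PWM {self.tf_id!r}: negative weight encountered")
        object.__setattr__(self, "weights", w)

    @property
    def length(self) -> int:
        """Motif length L in bp."""
        return self.weights.shape[0]

    def normalized(self) -> "PWM":
        """Return a copy with each row rescaled to sum to one (count -> frequency)."""
        sums = self.weights.sum(axis=1, keepdims=True)
        if np.any(sums <= 0):
            raise ValidationError(f"PWM {self.tf_id!r}: cannot normalize a zero row")
        return PWM(self.tf_id, self.tf_name, self.weights / sums)

    def consensus(self) -> str:
        """Highest-weight base at each position (ties -> alphabetically first)."""
        return "".join(BASES[i] for i in np.argmax(self.weights, axis=1))


@dataclass
class Promoter:
    """One gene's promoter window.

    Genomic provenance (``chrom``/``start``/``end``/``strand``) is optional:
    it is required only when per-base methylation must be projected from
    genome-coordinate tracks onto the promoter.
    """

    gene_id: str
    sequence: str
    strand: str = "+"
    chrom: Optional[str] = None
    start: Optional[int] = None
    end: Optional[int] = None
    clipped: bool = False

    @property
    def has_provenance(self) -> bool:
        return self.chrom is not None and self.start is not None and self.end is not None

    def __len__(self) -> int:
        return len(self.sequence)


def sanitize_sequence(seq: str, gene_id: str = "?") -> str:
    """Uppercase and collapse non-N IUPAC ambiguity codes to N (with a warning)."""
    seq = seq.upper()
    extra = set(seq) - PROMOTER_ALPHABET
    if extra:
        bad = extra - _IUPAC_AMBIGUOUS
        if bad:
            raise ValidationError(
                f"promoter {gene_id!r}: illegal sequence characters {sorted(bad)}"
            )
        logger.warning(
            "promoter %s: ambiguity codes %s mapped to N", gene_id, sorted(extra)
        )
        seq = "".join("N" if c in extra else c for c in seq)
    return seq


class PromoterSet:
    """Per-gene promoter sequences sharing one TSS-relative window definition."""

    def __init__(
        self,
        promoters: Sequence[Promoter],
        upstream_bp: Optional[int] = None,
        downstream_bp: Optional[int] = None,
        skip_report: Optional[Sequence[Tuple[str, str]]] = None,
    ) -> None:
        self.upstream_bp = upstream_bp
        self.downstream_bp = downstream_bp
        #: genes dropped during extraction, as (gene_id, reason) pairs
        self.skip_report: list[Tuple[str, str]] = list(skip_report or [])
        self._entries: Dict[str, Promoter] = {}
        for p in promoters:
            if p.gene_id in self._entries:
                raise ValidationError(f"duplicate gene_id {p.gene_id!r} in PromoterSet")
            if len(p.sequence) < 1:
                raise ValidationError(f"promoter {p.gene_id!r}: empty sequence")
            p.sequence = sanitize_sequence(p.sequence, p.gene_id)
            self._entries[p.gene_id] = p

    def __len__(self) -> int:
        return len(self._entries)

    def __iter__(self) -> Iterator[Promoter]:
        return iter(self._entries.values())

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self._entries

    def __getitem__(self, gene_id: str) -> Promoter:
        return self._entries[gene_id]

    @property
    def gene_ids(self) -> list[str]:
        return list(self._entries)


class MethylationTrack:
    """Per-base methylation levels aligned with a :class:`PromoterSet`.

    Values are log2 ratios; missing positions are NaN.  Vector lengths are
    checked against the promoter set on construction.
    """

    def __init__(
        self,
        values: Mapping[str, np.ndarray],
        promoters: Optional[PromoterSet] = None,
    ) -> None:
        self._values: Dict[str, np.ndarray] = {}
        for gene_id, vec in values.items():
            arr = np.asarray(vec, dtype=float)
            present = ~np.isnan(arr)
            if not np.all(np.isfinite(arr[present])):
                raise ValidationError(f"methylation for {gene_id!r}: non-finite value")
            if promoters is not None:
                if gene_id not in promoters:
                    raise ValidationError(
                        f"methylation for unknown gene {gene_id!r}"
                    )
                n = len(promoters[gene_id])
                if arr.shape != (n,):
                    raise ValidationError(
                        f"methylation for {gene_id!r}: length {arr.shape} != promoter length {n}"
                    )
            self._values[gene_id] = arr
        # lazy per-gene cumulative sums for fast window means
        self._cum: Dict[str, Tuple[np.ndarray, np.ndarray]] = {}

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self._values

    def __getitem__(self, gene_id: str) -> np.ndarray:
        return self._values[gene_id]

    @property
    def gene_ids(self) -> list[str]:
        return list(self._values)

    def coverage(self, gene_id: str) -> float:
        """Fraction of promoter positions that carry a methylation value."""
        v = self._values[gene_id]
        return float(np.mean(~np.isnan(v)))

    def _cumsums(self, gene_id: str) -> Tuple[np.ndarray, np.ndarray]:
        cached = self._cum.get(gene_id)
        if cached is None:
            v = self._values[gene_id]
            present = ~np.isnan(v)
            csum = np.concatenate([[0.0], np.cumsum(np.where(present, v, 0.0))])
            ccnt = np.concatenate([[0], np.cumsum(present.astype(np.int64))])
            cached = (csum, ccnt)
            self._cum[gene_id] = cached
        return cached

    def window_means(
        self, gene_id: str, starts: np.ndarray, length: int
    ) -> Tuple[np.ndarray, np.ndarray]:
        """Mean of present values over windows [start, start+length).

        Returns ``(means, fraction_present)``; windows with no data get NaN.
        """
        starts = np.asarray(starts, dtype=np.int64)
        n = self._values[gene_id].shape[0]
        if starts.size and (starts.min() < 0 or starts.max() + length > n):
            raise ValidationError(
                f"methylation window out of bounds for {gene_id!r}"
            )
        csum, ccnt = self._cumsums(gene_id)
        tot = csum[starts + length] - csum[starts]
        cnt = ccnt[starts + length] - ccnt[starts]
        with np.errstate(invalid="ignore"):
            means = np.where(cnt > 0, tot / np.maximum(cnt, 1), np.nan)
        return means, cnt / float(length)


class ExpressionVector:
    """Per-gene log expression values with the cohort mean and SD.

    The Z statistic compares a target subset's mean against this global
    background, so ``mu``/``sigma`` are fixed at construction (after any
    low-expression filtering) rather than recomputed per subset.
    """

    def __init__(self, values: pd.Series) -> None:
        values = pd.Series(values, dtype=float)
        if values.index.has_duplicates:
            dup = values.index[values.index.duplicated()][0]
            raise ValidationError(f"duplicate gene_id {dup!r} in expression table")
        if not np.all(np.isfinite(values.to_numpy())):
            raise ValidationError("expression values must be finite")
        if len(values) < 2:
            raise ValidationError("need at least 2 genes to define a background")
        self.values = values
        self.n = int(len(values))
        self.mu = float(values.mean())
        self.sigma = float(values.std(ddof=1))
        if self.sigma <= 0:
            raise ValidationError("expression SD must be positive")

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self.values.index

    def __getitem__(self, gene_id: str) -> float:
        return float(self.values[gene_id])

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)
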