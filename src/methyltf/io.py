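"""Readers and writers for the standard input formats.

PWMs come as TRANSFAC-flat, JASPAR or minimal-MEME text; promoters either
directly as FASTA or extracted from a genome FASTA plus BED6 annotations;
methylation as bedGraph or WIG on the log2-ratio scale; expression as a
two-column TSV.  Biopython handles FASTA and the JASPAR/TRANSFAC motif
dialects; the minimal-MEME probability matrix is read directly so the
numbers in the file are preserved exactly.
"""

from __future__ import annotations

import io as _io
import logging
from pathlib import Path
from typing import Iterable, List, Optional, Sequence, TextIO, Tuple, Union

import numpy as np
import pandas as pd
from Bio import SeqIO, motifs as bio_motifs
from Bio.Seq import Seq

from .containers import (
    BASES,
    ExpressionVector,
    MethylationTrack,
    Promoter,
    PromoterSet,
    PWM,
    ValidationError,
)

logger = logging.getLogger(__name__)

Source = Union[str, Path, TextIO]

PWM_DIALECTS = ("transfac", "jaspar", "meme-minimal")


class ParseError(ValueError):
    """A source file is malformed; the message names the record/line."""


def _open(source: Source):
    """Return (handle, should_close)."""
    if isinstance(source, (str, Path)):
        return open(source, "rt"), True
    return source, False


# ---------------------------------------------------------------------------
# PWMs
# ---------------------------------------------------------------------------

def _pwms_from_biopython(records, dialect: str) -> List[PWM]:
    out = []
    for i, m in enumerate(records):
        if dialect == "transfac":
            tf_id = m.get("AC") or m.get("ID") or f"record{i + 1}"
            tf_name = m.get("ID") or tf_id
        else:  # jaspar
            tf_id = getattr(m, "matrix_id", None) or f"record{i + 1}"
            tf_name = m.name or tf_id
        weights = np.column_stack([np.asarray(m.counts[b], dtype=float) for b in BASES])
        out.append(PWM(tf_id, tf_name, weights))
    return out


def _read_meme_minimal(handle: TextIO) -> List[PWM]:
    pwms: List[PWM] = []
    lines = handle.read().splitlines()
    i = 0
    while i < len(lines):
        line = lines[i].strip()
        if line.startswith("MOTIF"):
            fields = line.split()
            if len(fields) < 2:
                raise ParseError(f"line {i + 1}: MOTIF line without an identifier")
            tf_id = fields[1]
            tf_name = fields[2] if len(fields) > 2 else tf_id
            # advance to the letter-probability header
            j = i + 1
            while j < len(lines) and not lines[j].strip().startswith(
                "letter-probability matrix"
            ):
                if lines[j].strip().startswith("MOTIF"):
                    raise ParseError(
                        f"motif {tf_id!r}: missing letter-probability matrix"
                    )
                j += 1
            if j >= len(lines):
                raise ParseError(f"motif {tf_id!r}: missing letter-probability matrix")
            rows = []
            j += 1
            while j < len(lines):
                s = lines[j].strip()
                if not s or s.startswith(("MOTIF", "URL")):
                    break
                try:
                    vals = [float(x) for x in s.split()]
                except ValueError as exc:
                    raise ParseError(f"motif {tf_id!r}, line {j + 1}: {exc}") from exc
                if len(vals) != 4:
                    raise ParseError(
                        f"motif {tf_id!r}, line {j + 1}: expected 4 columns, got {len(vals)}"
                    )
                rows.append(vals)
                j += 1
            if not rows:
                raise ParseError(f"motif {tf_id!r}: empty probability matrix")
            pwms.append(PWM(tf_id, tf_name, np.asarray(rows)))
            i = j
        else:
            i += 1
    return pwms


def read_pwms(source: Source, dialect: str) -> List[PWM]:
    """Read a PWM collection; column order is normalized to A, C, G, T.

    Weights are accepted as the file holds them (counts, frequencies or
    scores) but must be nonnegative.  An empty stream yields an empty list.
    """
    if dialect not in PWM_DIALECTS:
        raise ValueError(f"unknown PWM dialect {dialect!r}; expected one of {PWM_DIALECTS}")
    handle, close = _open(source)
    try:
        text = handle.read()
    finally:
        if close:
            handle.close()
    if not text.strip():
        return []
    if dialect == "meme-minimal":
        return _read_meme_minimal(_io.StringIO(text))
    fmt = {"transfac": "transfac", "jaspar": "jaspar"}[dialect]
    try:
        records = bio_motifs.parse(_io.StringIO(text), fmt)
    except Exception as exc:
        raise ParseError(f"malformed {dialect} stream: {exc}") from exc
    return _pwms_from_biopython(records, dialect)


def write_pwms(pwms: Sequence[PWM], dest: Source, dialect: str = "jaspar") -> None:
    """Write PWMs at full precision (JASPAR or minimal-MEME dialects)."""
    handle, close = _open_w(dest)
    try:
        if dialect == "jaspar":
            for p in pwms:
                handle.write(f">{p.tf_id} {p.tf_name}\n")
                for col, base in enumerate(BASES):
                    row = " ".join(repr(float(v)) for v in p.weights[:, col])
                    handle.write(f"{base} [ {row} ]\n")
        elif dialect == "meme-minimal":
            handle.write("MEME version 4\n\nALPHABET= ACGT\n\n")
            for p in pwms:
                handle.write(f"MOTIF {p.tf_id} {p.tf_name}\n")
                handle.write(
                    f"letter-probability matrix: alength= 4 w= {p.length}\n"
                )
                for row in p.weights:
                    handle.write(" " + " ".join(repr(float(v)) for v in row) + "\n")
                handle.write("\n")
        else:
            raise ValueError(f"unsupported write dialect {dialect!r}")
    finally:
        if close:
            handle.close()


def _open_w(dest: Source):
    if isinstance(dest, (str, Path)):
        return open(dest, "wt"), True
    return dest, False


# ---------------------------------------------------------------------------
# Promoters
# ---------------------------------------------------------------------------

def read_bed(source: Source) -> pd.DataFrame:
    """Read BED6 gene annotations into a DataFrame.

    TSS convention: ``start`` for + strand genes, ``end - 1`` for - strand.
    """
    handle, close = _open(source)
    try:
        lines = [
            ln
            for ln in handle.read().splitlines()
            if ln.strip() and not ln.startswith(("#", "track", "browser"))
        ]
    finally:
        if close:
            handle.close()
    rows = []
    for num, ln in enumerate(lines, start=1):
        fields = ln.rstrip("\n").split("\t")
        if len(fields) < 6:
            raise ParseError(f"BED line {num}: expected 6 columns, got {len(fields)}")
        chrom, start, end, name, score, strand = fields[:6]
        if strand not in "+-":
            raise ParseError(f"BED line {num}: bad strand {strand!r}")
        try:
            rows.append((chrom, int(start), int(end), name, score, strand))
        except ValueError as exc:
            raise ParseError(f"BED line {num}: {exc}") from exc
    return pd.DataFrame(
        rows, columns=["chrom", "start", "end", "name", "score", "strand"]
    )


def read_promoters_fasta(source: Source) -> PromoterSet:
    """Read promoter sequences directly from FASTA (no genomic provenance)."""
    handle, close = _open(source)
    try:
        proms = [
            Promoter(gene_id=rec.id, sequence=str(rec.seq))
            for rec in SeqIO.parse(handle, "fasta")
        ]
    finally:
        if close:
            handle.close()
    return PromoterSet(proms)


def _load_genome(genome) -> dict:
    if isinstance(genome, dict):
        return {k: str(v).upper() for k, v in genome.items()}
    handle, close = _open(genome)
    try:
        return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(handle, "fasta")}
    finally:
        if close:
            handle.close()


def extract_promoters(
    genome,
    annotations: Union[Source, pd.DataFrame],
    upstream_bp: int = 1200,
    downstream_bp: int = 300,
) -> PromoterSet:
    """Extract TSS-relative promoter windows from a genome.

    For + strand genes the window is ``[TSS - upstream, TSS + downstream)``;
    for - strand genes it is ``[TSS - downstream, TSS + upstream)`` and the
    sequence is reverse-complemented, so promoter index 0 is always the
    most-upstream base on the gene's sense strand.  Windows are clipped at
    chromosome bounds (recorded on the promoter); genes on missing
    chromosomes or with empty clipped windows are skipped and listed in
    the set's ``skip_report``.
    """
    if upstream_bp < 0 or downstream_bp < 0:
        raise ValueError("upstream_bp and downstream_bp must be >= 0")
    chroms = _load_genome(genome)
    if not isinstance(annotations, pd.DataFrame):
        annotations = read_bed(annotations)
    proms: List[Promoter] = []
    skipped: List[Tuple[str, str]] = []
    for row in annotations.itertuples(index=False):
        if row.chrom not in chroms:
            logger.warning("gene %s: chromosome %s not in genome", row.name, row.chrom)
            skipped.append((row.name, f"missing chromosome {row.chrom}"))
            continue
        seq = chroms[row.chrom]
        if row.strand == "+":
            tss = row.start
            lo, hi = tss - upstream_bp, tss + downstream_bp
        else:
            tss = row.end - 1
            lo, hi = tss - downstream_bp, tss + upstream_bp
        clo, chi = max(lo, 0), min(hi, len(seq))
        if chi <= clo:
            logger.warning("gene %s: window empty after clipping", row.name)
            skipped.append((row.name, "window empty after clipping"))
            continue
        window = seq[clo:chi]
        if row.strand == "-":
            window = str(Seq(window).reverse_complement())
        proms.append(
            Promoter(
                gene_id=row.name,
                sequence=window,
                strand=row.strand,
                chrom=row.chrom,
                start=clo,
                end=chi,
                clipped=(clo != lo or chi != hi),
            )
        )
    return PromoterSet(
        proms, upstream_bp=upstream_bp, downstream_bp=downstream_bp, skip_report=skipped
    )


def write_skip_report(promoters: PromoterSet, dest: Source) -> None:
    handle, close = _open_w(dest)
    try:
        handle.write("gene_id\treason\n")
        for gene_id, reason in promoters.skip_report:
            handle.write(f"{gene_id}\t{reason}\n")
    finally:
        if close:
            handle.close()


# ---------------------------------------------------------------------------
# Methylation tracks
# ---------------------------------------------------------------------------

def _parse_bedgraph(lines: Iterable[str]) -> List[Tuple[str, int, int, float]]:
    intervals = []
    for num, ln in enumerate(lines, start=1):
        s = ln.strip()
        if not s or s.startswith(("#", "track", "browser")):
            continue
        fields = s.split()
        if len(fields) < 4:
            raise ParseError(f"bedGraph line {num}: expected 4 columns")
        try:
            intervals.append((fields[0], int(fields[1]), int(fields[2]), float(fields[3])))
        except ValueError as exc:
            raise ParseError(f"bedGraph line {num}: {exc}") from exc
    return intervals


def _parse_wig(lines: Iterable[str]) -> List[Tuple[str, int, int, float]]:
    """Parse fixedStep/variableStep WIG; 1-based starts become 0-based."""
    intervals = []
    mode = None
    chrom = None
    pos = 0
    step = 1
    span = 1
    for num, ln in enumerate(lines, start=1):
        s = ln.strip()
        if not s or s.startswith(("#", "track", "browser")):
            continue
        if s.startswith(("fixedStep", "variableStep")):
            mode = "fixed" if s.startswith("fixedStep") else "variable"
            kv = dict(tok.split("=", 1) for tok in s.split()[1:])
            if "chrom" not in kv:
                raise ParseError(f"WIG line {num}: declaration missing chrom=")
            chrom = kv["chrom"]
            span = int(kv.get("span", 1))
            if mode == "fixed":
                if "start" not in kv:
                    raise ParseError(f"WIG line {num}: fixedStep missing start=")
                pos = int(kv["start"]) - 1
                step = int(kv.get("step", 1))
            continue
        if mode is None:
            raise ParseError(f"WIG line {num}: data before a step declaration")
        fields = s.split()
        try:
            if mode == "fixed":
                value = float(fields[0])
                intervals.append((chrom, pos, pos + span, value))
                pos += step
            else:
                start = int(fields[0]) - 1
                value = float(fields[1])
                intervals.append((chrom, start, start + span, value))
        except (ValueError, IndexError) as exc:
            raise ParseError(f"WIG line {num}: {exc}") from exc
    return intervals


def read_methylation(
    source: Source,
    promoters: PromoterSet,
    fmt: Optional[str] = None,
) -> MethylationTrack:
    """Project a genome-coordinate methylation track onto promoter coordinates.

    Per-base values are mapped strand-aware (matching the orientation used
    by :func:`extract_promoters`); positions without data stay NaN.
    Overlapping records are resolved last-record-wins with a warning.
    ``fmt`` is ``"bedgraph"`` or ``"wig"``; when None it is sniffed from the
    first data line.
    """
    handle, close = _open(source)
    try:
        lines = handle.read().splitlines()
    finally:
        if close:
            handle.close()
    if fmt is None:
        fmt = "bedgraph"
        for ln in lines:
            if ln.startswith(("fixedStep", "variableStep")):
                fmt = "wig"
                break
    intervals = _parse_bedgraph(lines) if fmt == "bedgraph" else _parse_wig(lines)

    for p in promoters:
        if not p.has_provenance:
            raise ValidationError(
                f"promoter {p.gene_id!r} lacks genomic coordinates; cannot project track"
            )

    # index promoters per chromosome for overlap queries
    by_chrom: dict = {}
    arrays = {p.gene_id: np.full(len(p), np.nan) for p in promoters}
    for p in promoters:
        by_chrom.setdefault(p.chrom, []).append(p)
    order_keys = {}
    for chrom, plist in by_chrom.items():
        plist.sort(key=lambda p: p.start)
        starts = np.array([p.start for p in plist])
        ends = np.array([p.end for p in plist])
        ends_sorted = bool(np.all(np.diff(ends) >= 0))
        order_keys[chrom] = (starts, ends, ends_sorted)

    overlap_warned = False
    for chrom, a, b, value in intervals:
        plist = by_chrom.get(chrom)
        if plist is None:
            continue
        starts, ends, ends_sorted = order_keys[chrom]
        # candidate promoters: start < b and end > a
        hi = int(np.searchsorted(starts, b, side="left"))
        lo_idx = int(np.searchsorted(ends, a, side="right")) if ends_sorted else 0
        for p in plist[lo_idx:hi]:
            if p.end <= a:
                continue
            lo, hi2 = max(a, p.start), min(b, p.end)
            if hi2 <= lo:
                continue
            gpos = np.arange(lo, hi2)
            local = gpos - p.start if p.strand == "+" else (p.end - 1) - gpos
            arr = arrays[p.gene_id]
            if not overlap_warned and np.any(~np.isnan(arr[local])):
                logger.warning("overlapping track records: last record wins")
                overlap_warned = True
            arr[local] = value
    return MethylationTrack(arrays, promoters)


# ---------------------------------------------------------------------------
# Expression
# ---------------------------------------------------------------------------

def read_expression(
    source: Source,
    log_transform: bool = False,
    low_expr_quantile: float = 0.10,
) -> ExpressionVector:
    """Read a two-column ``gene_id<TAB>value`` table.

    Optionally log2-transforms, then drops genes whose (transformed) value
    falls below the ``low_expr_quantile`` of the distribution — an explicit
    stand-in for the usual removal of very-low-expression genes.  The
    background mean and SD are computed on the surviving set.
    """
    handle, close = _open(source)
    try:
        df = pd.read_csv(handle, sep="\t")
    finally:
        if close:
            handle.close()
    if df.shape[1] < 2:
        raise ParseError("expression table needs columns gene_id and value")
    gene_col, val_col = df.columns[:2]
    if df[gene_col].duplicated().any():
        dup = df[gene_col][df[gene_col].duplicated()].iloc[0]
        raise ValidationError(f"duplicate gene_id {dup!r} in expression table")
    values = pd.Series(df[val_col].to_numpy(dtype=float), index=df[gene_col].astype(str))
    if log_transform:
        bad = values.index[values <= 0]
        if len(bad):
            raise ValidationError(
                f"gene {bad[0]!r}: nonpositive value under log transform"
            )
        values = np.log2(values)
    return filter_low_expression(values, low_expr_quantile)


def filter_low_expression(
    values: pd.Series, low_expr_quantile: float
) -> ExpressionVector:
    """Drop genes below the given quantile of the value distribution."""
    if not 0 <= low_expr_quantile < 1:
        raise ValueError("low_expr_quantile must be in [0, 1)")
    values = pd.Series(values, dtype=float)
    if low_expr_quantile > 0:
        cutoff = float(np.quantile(values.to_numpy(), low_expr_quantile))
        values = values[values >= cutoff]
    if len(values) < 2:
        raise ValidationError("fewer than 2 genes survive the low-expression filter")
    return ExpressionVector(values)
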