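"""Self-contained synthetic fixtures with a known planted generative model.

The generator emulates the screen's real inputs end to end: sharpened
random frequency PWMs, i.i.d. uniform promoters with exact consensus
motifs planted per (TF, target gene), block-wise MeDIP-style log2-ratio
methylation on roughly [-2, 2], and log expression built as

    g = baseline + beta * E_sense(M_site; planted_C, planted_S) + noise

for target genes of *active* TFs.  Decoy TFs get planted motif instances
but no expression term, so they estimate the screen's false-positive rate.
A per-gene truth table records the deterministic expression component; a
per-site table records every planted site and its methylation level.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Tuple

import numpy as np
import pandas as pd

from .containers import (
    ExpressionVector,
    MethylationTrack,
    Promoter,
    PromoterSet,
    PWM,
)
from .model import effect_sense

_BASES = np.array(list("ACGT"))
_SPACER = 100  # bp of methylation-free filler between gene blocks on the contig
_CONTIG = "chrSim"


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for one simulated cohort.

    The methylation mixture places a hypomethylated and a hypermethylated
    mode at -/+0.75 with SD 0.75 (clipped to the [-2, 2] log2-ratio
    support), giving appreciable density across the whole C search range.
    ``promoter_length`` matches the 1200 bp upstream + 300 bp downstream
    window used for real promoter arrays, and ``motif_length`` the ~10 bp
    binding-site size that site-level methylation is quantified over.
    """

    n_genes: int = 500
    promoter_length: int = 1500
    n_tfs: int = 10
    n_active_tfs: int = 1
    motif_length: int = 10
    planted_C: float = 0.25
    planted_S: float = 0.01
    effect_size: float = 2.0
    noise_sd: float = 0.5
    meth_low_mean: float = -0.75
    meth_high_mean: float = 0.75
    meth_mode_sd: float = 0.75
    meth_support: Tuple[float, float] = (-2.0, 2.0)
    meth_block_bp: int = 50
    target_fraction: float = 0.3
    expressed_fraction: float = 0.5
    baseline_expression: float = 8.0
    consensus_weight_range: Tuple[float, float] = (0.8, 0.95)
    sites_per_target: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_genes", "promoter_length", "n_tfs", "motif_length", "sites_per_target"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.n_active_tfs < 0 or self.n_active_tfs > self.n_tfs:
            raise ValueError("n_active_tfs must lie in [0, n_tfs]")
        if self.motif_length > self.promoter_length:
            raise ValueError("motif longer than promoter")
        if not self.noise_sd > 0:
            raise ValueError("noise_sd must be > 0")
        if not self.planted_S > 0:
            raise ValueError("planted_S must be > 0")
        if not 0 < self.target_fraction <= 1:
            raise ValueError("target_fraction must be in (0, 1]")
        if not 0 <= self.expressed_fraction <= 1:
            raise ValueError("expressed_fraction must be in [0, 1]")


@dataclass
class SimData:
    """One simulated cohort plus its ground truth."""

    config: SimConfig
    pwms: List[PWM]
    promoters: PromoterSet
    track: MethylationTrack
    expression: ExpressionVector
    truth: pd.DataFrame  # one row per gene
    sites: pd.DataFrame  # one row per planted site


def _draw_mixture(rng: np.random.Generator, n: int, cfg: SimConfig) -> np.ndarray:
    """Methylation values from the low/high two-mode mixture, clipped."""
    low = rng.random(n) < 0.5
    means = np.where(low, cfg.meth_low_mean, cfg.meth_high_mean)
    vals = rng.normal(means, cfg.meth_mode_sd)
    return np.clip(vals, *cfg.meth_support)


def _draw_mode(
    rng: np.random.Generator, n: int, cfg: SimConfig, low: bool
) -> np.ndarray:
    mean = cfg.meth_low_mean if low else cfg.meth_high_mean
    return np.clip(rng.normal(mean, cfg.meth_mode_sd, n), *cfg.meth_support)


def simulate(config: SimConfig) -> SimData:
    """Generate one cohort; the same config (seed included) is byte-reproducible."""
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    L, n_genes, n_p = cfg.motif_length, cfg.n_genes, cfg.promoter_length

    # --- PWMs: sharpened random frequency matrices, active TFs first
    pwms: List[PWM] = []
    for i in range(cfg.n_tfs):
        cons_idx = rng.integers(0, 4, L)
        p = rng.uniform(*cfg.consensus_weight_range, L)
        w = np.tile(((1 - p) / 3)[:, None], (1, 4))
        w[np.arange(L), cons_idx] = p
        role = "active" if i < cfg.n_active_tfs else "decoy"
        pwms.append(PWM(f"SIM{i:03d}", f"synTF{i:02d}_{role}", w))

    # --- promoters on a synthetic contig; strands alternate to exercise
    # the strand-aware extraction/projection path when written to disk
    gene_ids = [f"gene{g:04d}" for g in range(n_genes)]
    block = n_p + _SPACER
    seq_arrays = [rng.integers(0, 4, n_p) for _ in range(n_genes)]

    # --- plant one motif instance per (TF, target gene), no overlaps.
    # Site sequences are sampled from the TF's frequency matrix rather than
    # fixed at the consensus: heterogeneous site strengths are what real
    # binding sites look like, and they keep the attenuation center
    # identifiable — with all sites at the identical consensus score, the
    # downstream threshold sweep can absorb any over-large center C by
    # cutting inside the sigmoid transition, flattening the Z(C) curve.
    targets: Dict[int, np.ndarray] = {}
    n_targets = max(1, round(cfg.target_fraction * n_genes))
    occupied: List[List[Tuple[int, int]]] = [[] for _ in range(n_genes)]
    site_rows = []
    for i in range(cfg.n_tfs):
        targets[i] = rng.choice(n_genes, size=n_targets, replace=False)
        freqs = pwms[i].weights
        for g in targets[i]:
            for _ in range(cfg.sites_per_target):
                offset = None
                for _try in range(200):
                    cand = int(rng.integers(0, n_p - L + 1))
                    if all(
                        cand + L <= s or cand >= e for s, e in occupied[g]
                    ):
                        offset = cand
                        break
                if offset is None:
                    continue  # promoter saturated; extremely unlikely
                occupied[g].append((offset, offset + L))
                site_codes = np.array(
                    [rng.choice(4, p=freqs[l]) for l in range(L)], dtype=np.int64
                )
                seq_arrays[g][offset : offset + L] = site_codes
                site_rows.append(
                    {
                        "gene_id": gene_ids[g],
                        "tf_id": pwms[i].tf_id,
                        "tf_role": "active" if i < cfg.n_active_tfs else "decoy",
                        "site_offset": offset,
                        "strand": "sense",
                    }
                )
    sites = pd.DataFrame(
        site_rows,
        columns=["gene_id", "tf_id", "tf_role", "site_offset", "strand"],
    )

    # --- methylation: block-wise background from the mixture, then one
    # constant site-level value per planted site of an *active* TF, drawn
    # from the low mode for expressed targets and the high mode otherwise
    n_blocks = (n_p + cfg.meth_block_bp - 1) // cfg.meth_block_bp
    meth = {}
    for g in range(n_genes):
        blocks = _draw_mixture(rng, n_blocks, cfg)
        meth[gene_ids[g]] = np.repeat(blocks, cfg.meth_block_bp)[:n_p].copy()

    expressed_label = np.zeros(n_genes, dtype=bool)
    for i in range(cfg.n_active_tfs):
        tgt = targets[i]
        n_expr = round(cfg.expressed_fraction * len(tgt))
        is_expr = np.zeros(len(tgt), dtype=bool)
        is_expr[rng.permutation(len(tgt))[:n_expr]] = True
        site_m = np.where(
            is_expr,
            _draw_mode(rng, len(tgt), cfg, low=True),
            _draw_mode(rng, len(tgt), cfg, low=False),
        )
        for g, m_val, e_flag in zip(tgt, site_m, is_expr):
            expressed_label[g] |= e_flag
            mask = sites["gene_id"].eq(gene_ids[g]) & sites["tf_id"].eq(pwms[i].tf_id)
            for off in sites.loc[mask, "site_offset"]:
                meth[gene_ids[g]][off : off + L] = m_val

    # record each planted site's realized methylation (mean over the site)
    sites["site_methylation"] = [
        float(np.mean(meth[r.gene_id][r.site_offset : r.site_offset + L]))
        for r in sites.itertuples(index=False)
    ]

    # --- expression: baseline + attenuated binding effect + noise
    det = np.full(n_genes, cfg.baseline_expression)
    for i in range(cfg.n_active_tfs):
        for g in targets[i]:
            mask = sites["gene_id"].eq(gene_ids[g]) & sites["tf_id"].eq(pwms[i].tf_id)
            for m_val in sites.loc[mask, "site_methylation"]:
                det[g] += cfg.effect_size * float(
                    effect_sense(m_val, cfg.planted_C, cfg.planted_S)
                )
    noise = rng.normal(0.0, cfg.noise_sd, n_genes)
    values = det + noise

    truth = pd.DataFrame(
        {
            "gene_id": gene_ids,
            "expressed_target": expressed_label,
            "n_planted_sites": [len(o) for o in occupied],
            "deterministic_expression": det,
            "noise": noise,
            "expression": values,
            "seed": cfg.seed,
        }
    )

    # --- wrap into pipeline containers with contig provenance
    proms = []
    for g in range(n_genes):
        strand = "+" if g % 2 == 0 else "-"
        start = g * block
        proms.append(
            Promoter(
                gene_id=gene_ids[g],
                sequence="".join(_BASES[seq_arrays[g]]),
                strand=strand,
                chrom=_CONTIG,
                start=start,
                end=start + n_p,
            )
        )
    # TSS-relative split in the 4:1 upstream:downstream ratio of the
    # 1200/300 promoter-array window (exact at the default length 1500)
    up = (4 * n_p) // 5
    promoters = PromoterSet(proms, upstream_bp=up, downstream_bp=n_p - up)
    track = MethylationTrack(meth, promoters)
    expression = ExpressionVector(pd.Series(values, index=gene_ids))
    return SimData(cfg, pwms, promoters, track, expression, truth, sites)


# ---------------------------------------------------------------------------
# fixture files
# ---------------------------------------------------------------------------

def _revcomp(seq: str) -> str:
    return seq.translate(str.maketrans("ACGTN", "TGCAN"))[::-1]


def write_fixture(sim: SimData, directory) -> Dict[str, Path]:
    """Emit the cohort in exactly the formats the readers consume.

    Files: ``genome.fa`` (one synthetic contig), ``annotations.bed`` (BED6
    whose TSS conventions reproduce each promoter window under the default
    1200/300 extraction), ``promoters.fa``, ``pwms.jaspar``,
    ``methylation.bedGraph``, ``expression.tsv``, ``truth.tsv``,
    ``sites.tsv`` and a ``manifest.json`` echoing the config.
    """
    from . import io as mio

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    cfg = sim.config
    n_p = cfg.promoter_length
    block = n_p + _SPACER
    up = sim.promoters.upstream_bp
    down = sim.promoters.downstream_bp

    rng = np.random.default_rng(cfg.seed + 1)  # spacer filler only
    contig_parts: List[str] = []
    bed_rows = []
    bg_rows: List[Tuple[int, int, float]] = []
    for g, p in enumerate(sim.promoters):
        win = p.sequence if p.strand == "+" else _revcomp(p.sequence)
        contig_parts.append(win)
        contig_parts.append("".join(_BASES[rng.integers(0, 4, _SPACER)]))
        if p.strand == "+":
            tss = p.start + up  # extraction window [TSS - up, TSS + down)
            bed_rows.append((_CONTIG, tss, tss + 1, p.gene_id, 0, "+"))
        else:
            tss = p.end - up  # extraction window [TSS - down, TSS + up)
            bed_rows.append((_CONTIG, tss, tss + 1, p.gene_id, 0, "-"))
        vec = sim.track[p.gene_id]
        # local index -> genome position, then run-length encode
        if p.strand == "+":
            genome_vals = vec
        else:
            genome_vals = vec[::-1]
        base = p.start
        run_start = 0
        for i in range(1, n_p + 1):
            if i == n_p or genome_vals[i] != genome_vals[run_start]:
                bg_rows.append((base + run_start, base + i, float(genome_vals[run_start])))
                run_start = i

    paths: Dict[str, Path] = {}
    paths["genome"] = directory / "genome.fa"
    with open(paths["genome"], "wt") as fh:
        fh.write(f">{_CONTIG}\n")
        contig = "".join(contig_parts)
        for i in range(0, len(contig), 80):
            fh.write(contig[i : i + 80] + "\n")

    paths["annotations"] = directory / "annotations.bed"
    with open(paths["annotations"], "wt") as fh:
        for row in bed_rows:
            fh.write("\t".join(map(str, row)) + "\n")

    paths["promoters"] = directory / "promoters.fa"
    with open(paths["promoters"], "wt") as fh:
        for p in sim.promoters:
            fh.write(f">{p.gene_id}\n{p.sequence}\n")

    paths["pwms"] = directory / "pwms.jaspar"
    mio.write_pwms(sim.pwms, paths["pwms"], dialect="jaspar")

    paths["methylation"] = directory / "methylation.bedGraph"
    with open(paths["methylation"], "wt") as fh:
        for a, b, v in bg_rows:
            fh.write(f"{_CONTIG}\t{a}\t{b}\t{v!r}\n")

    paths["expression"] = directory / "expression.tsv"
    sim.expression.values.rename("value").rename_axis("gene_id").to_csv(
        paths["expression"], sep="\t"
    )

    paths["truth"] = directory / "truth.tsv"
    sim.truth.to_csv(paths["truth"], sep="\t", index=False)
    paths["sites"] = directory / "sites.tsv"
    sim.sites.to_csv(paths["sites"], sep="\t", index=False)

    paths["manifest"] = directory / "manifest.json"
    with open(paths["manifest"], "wt") as fh:
        json.dump(
            {"config": dataclasses.asdict(cfg), "n_genes": cfg.n_genes},
            fh,
            indent=2,
            default=str,
        )
        fh.write("\n")
    return paths
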