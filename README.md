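# methyltf

A screen for transcription factors (TFs) whose promoter binding is
modulated by DNA methylation and which are functionally active in gene
expression.  It is aimed at regulatory genomicists who have, for one cell
type, (i) a PWM collection, (ii) promoter sequences (or a genome plus gene
annotations), (iii) a promoter methylation track on the MeDIP log2-ratio
scale, and (iv) a log expression profile — and who want to know which TFs'
apparent regulatory activity is sharpened, rather than blurred, when
methylation is allowed to attenuate their binding sites.

## The model

For TF *i* with motif length *L*, every promoter window of gene *j* gets a
match value — the one-hot dot product with the PWM —

> A\_ijk = Σ\_l a\_jkl · w\_il,

and the sequence-only **match score** is S\_ij = max\_k A\_ijk.  Linking
scores to expression: for a score threshold *t*, the genes scoring above
*t* form a putative target set of size *k*, and

> Z = (mean(g\_targets) − μ) / (σ / √k)

measures how coherently those targets are over- or under-expressed against
the cohort background (μ, σ).  Sweeping every candidate threshold and
keeping the Z of largest magnitude (sign preserved) gives the TF's
**Z\_m** statistic; computed from match scores it is written **Z\_m-o**.

Methylation enters through a two-parameter logistic attenuation of each
site.  With site methylation *M* (mean log2 ratio over the ~10 bp site),
center *C* and steepness *S*:

> E\_sense = expit(−(M − C)/S)   (binding weakened by methylation)
> E\_anti  = expit(+(M − C)/S)   (the mirror; E\_sense + E\_anti = 1)

The **binding score** is B\_ij = max\_k A\_ijk · E\_ijk — the max is over
the *product*, so a methylated strong site can lose to an unmethylated
weaker one.  Re-running the threshold sweep on binding scores for every
(C, S) on a grid (C from −2 to 2 step 0.05; S ∈ {0.01, 0.05, 0.1}) yields
**Z\_m-p** (sense model, extreme over the grid) and **Z\_m-q** (antisense
model).  A TF is called **functionally active** when

1. |Z\_m-p| ≥ (1 + margin) · |Z\_m-o| (default margin 10%), and
2. no grid cell's |Z\_m-q| strictly exceeds |Z\_m-o| — the wrong-signed
   control must never beat the methylation-free baseline.

The sign of Z\_m-o labels the TF an activator (positive) or repressor
(negative).

## Worked example

The built-in generator creates a full synthetic cohort — PWMs, promoters
with planted binding sites, a block-wise methylation track, and expression
in which one TF's targets are expressed only where their site is
hypomethylated:

```python
import methyltf as mtf

sim = mtf.simulate(mtf.SimConfig(seed=1))          # 500 genes, 10 TFs, 1 active
expr = mtf.filter_low_expression(sim.expression.values, 0.10)
result = mtf.run_screen(sim.pwms, sim.promoters, sim.track, expr)
print(result.positive_table.to_string(index=False))
```

```
 rank  tf_id        tf_name    z_m_o     z_m_p   C   S
    1 SIM000 synTF00_active 6.370909 10.891119 0.5 0.1
```

The planted activator is the only TF called active: its sequence-only
statistic Z\_m-o = 6.37 rises to an extreme Z\_m-p = 10.89 (a 71% gain)
when binding sites are attenuated around the recovered center C\* = 0.50,
while every antisense cell stays at or below the baseline
(max |Z\_m-q| = 6.13).  The nine decoy TFs — planted motifs but no
expression link — are all rejected.

The same workflow is available from the shell:

```sh
methyltf simulate --seed 1 --out fixture/
methyltf screen --pwms fixture/pwms.jaspar --genome fixture/genome.fa \
    --annotations fixture/annotations.bed --methylation fixture/methylation.bedGraph \
    --expression fixture/expression.tsv --out run/
```

`run/` then holds the ranked positive/negative activity tables, all
per-TF (C → Z\_m) grid curves, a Wilcoxon comparison of the Z\_m-p vs
Z\_m-o distributions, and a manifest with a hash of the effective
configuration.

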