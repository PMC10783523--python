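# txturnover

Estimation of gain and loss rates of *de novo* transcripts from
multi-sample transcriptomes of a single species.

Most eukaryotic genomes produce many transcripts outside annotated genes.
Transcripts with no detectable homolog in outgroup species — *de novo*
transcripts — are candidate raw material for *de novo* gene birth, and they
turn over quickly: most are found in only one of several conspecific
samples.  `txturnover` quantifies that turnover.  Given per-sample
transcript catalogs (StringTie-style GTF), homology-search results (BLAST
tabular) and a reference annotation, it

1. filters each catalog down to *de novo* transcripts (expression
   threshold, staged homology exclusion with an E ≤ 10⁻² forward-direction
   cutoff) and merges splice variants into unspliced transcripts;
2. classifies every transcript into one of six genomic-position categories
   (exon longer, intergenic, antisense, pseudogenic, ncRNA, intronic);
3. clusters transcripts across samples into **orthogroups** under three
   definitions — (1) reciprocal sequence similarity (≥ 70% coverage,
   ≥ 75% identity), (2) similarity plus transcription start sites within a
   500 bp window, (3) start *and* end positions each within 500 bp, with no
   similarity requirement;
4. summarises orthogroups as a **transcript frequency spectrum**
   `D = (d_1, …, d_n)` — the number of orthogroups found in exactly `k` of
   `n` samples — and
5. fits an **infinitely-many-genes model** to the spectrum.

## The model

Each transcript is gained once (rate `u` per generation) and lost
independently per lineage (rate `v`).  On a Kingman coalescent genealogy
with coalescent-scale rates `θ = 2Nₑu`, `ρ = 2Nₑv`, the expected spectrum
is

    E[G_k] = (θ/k) · n(n−1)⋯(n−k+1) / [(n−1+ρ)(n−2+ρ)⋯(n−k+ρ)],   k < n,

with the `k = n` denominator extending down to `ρ` and an additional count
`C_fixed` of zero-loss transcripts present in every sample.  One or two
transcript classes (slow/fast turnover) are supported.  Parameters are
estimated by minimising the χ² distance `Σ (d_k − t_k)²/t_k` with SLSQP
under the constraint `Σᵢ θᵢ/ρᵢ + C_fixed = Σ_k k·d_k / n` and the bounds
`θ ∈ [0, 20000]`, `ρ ∈ (0, 1000]`.  Rates convert to calendar time via
`generations per year / (2Nₑ)` (defaults: `Nₑ = 900 000`, 26
generations/year, for European *D. melanogaster*).

A built-in coalescent simulator (exact gain events with exponential
lifetimes along each branch) generates presence/absence matrices for
validation, and a toy-data generator plants catalogs, annotations and
similarity tables with known orthogroup and category ground truth.

## Worked example

```python
from txturnover import (TurnoverParams, simulate_poisson_spectrum, fit_spectrum)

truth = TurnoverParams.single(9000, 3.4615, c_fixed=91)   # coalescent scale
spec = simulate_poisson_spectrum(truth, n=6, seed=42)
print("spectrum:", spec.d)
res = fit_spectrum(spec)
print(res.summary())
print("lifespan:", round(1 / res.per_year.classes[0].rho), "years")
```

prints

```
spectrum: (6449, 2195, 836, 379, 115, 118)
          Transcript Turnover Model (infinitely many genes)
======================================================================
No. samples (n): 6          No. orthogroups: 10092
Transcript classes: 1       chi2: 5.35087
Converged: True             constraint residual: 0
Mean transcripts/sample: 2691
----------------------------------------------------------------------
parameter         coalescent      per generation        per year
gain                 9213.55          0.00511864        0.133085
loss                 3.54019         1.96677e-06     5.11361e-05
C_fixed                   88
======================================================================
lifespan: 19556 years
```

The fitted per-year rates say that roughly 0.13 new transcripts arise per
year in a lineage and each is lost at about 5×10⁻⁵ per year — an expected
lifespan around 20 000 years — with ~90 transcripts effectively fixed
across the six samples.  Most orthogroups (here 64%) are specific to a
single sample, the signature of fast transient turnover.

A command-line interface mirrors the library
(`txturnover filter|classify|cluster|spectrum|fit|simulate|run`); see
`txturnover --help`.

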