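# Methods

## Model and assumptions

The package treats *de novo* transcript turnover as an
infinitely-many-genes process on the genealogy of conspecific samples.
Assumptions:

- **Unique origin.** Each transcript arises exactly once over the short
  evolutionary window studied, so a transcript shared by several samples
  was gained in a common ancestral lineage.  This is plausible within a
  species over thousands of years, not across deep phylogenies.
- **Neutrality.** Transcripts confer no fitness effect; gain and loss are
  Poisson processes with constant rates.
- **Panmixia.** The genealogy is a standard (unstructured) Kingman
  coalescent.  Weakly structured populations are tolerable; strongly
  structured samples (e.g. a distant outgroup) should be excluded from the
  spectrum, which `spectrum_from_orthogroups(…, sample_list)` and the
  pipeline's `outgroup_samples` option support.
- **Fixed class.** Transcripts present in all samples with zero loss rate
  are counted separately (`C_fixed`) rather than forcing `ρ → 0`.

On the coalescent time scale, gains arrive at rate `θ/2` per lineage and
each transcript is lost at rate `ρ/2` per lineage.  With this convention
the expected frequency spectrum has the closed form implemented in
`expected_spectrum` (falling-factorial ratio; the `k = n` denominator runs
down to `ρ`), the stationary per-lineage transcript count is `θ/ρ`, and
the exact-event simulator in `simulate.py` reproduces the expectation
without bias — the agreement test (3 Monte-Carlo SE over 20 000
genealogies) is therefore a genuine cross-check of two independent
implementations, closed form vs. event simulation.

## Parameters that matter

| parameter | units | default | why |
|---|---|---|---|
| `θ` (gain) | per `2Nₑ` generations | fitted, bounded `[0, 20000]` | upper bound keeps SLSQP in a sane region |
| `ρ` (loss) | per `2Nₑ` generations | fitted, bounded `[10⁻⁶, 1000]` | strictly positive lower bound keeps the `k = n` term finite |
| `C_fixed` | count | fitted, bounded `[0, d_n]` | cannot exceed the orthogroups observed in all samples |
| `Nₑ` | individuals | 900 000 | European *D. melanogaster* estimate |
| generations/year | 1/year | 26 | two-week generation time |
| TPM threshold | TPM | 0.5 (presets 1, 5) | transcripts at exactly the threshold are kept |
| E-value cutoff | — | 10⁻² | homology hits at or below, in forward orientation, exclude a transcript |
| coverage / identity | fraction / % | 0.70 / 75 | orthogroup definitions 1–2 (controls 0.30/0.90 available as arguments) |
| positional window | bp | 500 | definitions 2–3; window = max − min ≤ 500, inclusive |

## Estimation

The objective is the χ² distance between empirical and expected spectra.
The equality constraint pins the model's mean per-sample count
`Σθᵢ/ρᵢ + C_fixed` to the empirical `Σ k·d_k / n`; this removes one
effective degree of freedom and stabilises the multi-class fit.  Whether
`C_fixed` belongs inside the constraint is genuinely ambiguous; the package
includes it by default (`constrain_c_fixed=True`) because the model's
expected per-sample count includes fixed transcripts, and offers the
transient-only variant as a flag.

Initial values invert two spectrum moments: `A = Σ k·d_k/n = θ/ρ` and the
mean pairwise difference `D = Σ d_k·2k(n−k)/(n(n−1)) = 2θ/(1+ρ)` give
`ρ₀ = D/(2A−D)`, `θ₀ = A·ρ₀` (fallback `ρ₀ = 1, θ₀ = A` when the
inversion degenerates, e.g. everything shared).  The two-class start is the
one-class start with `θ` halved for the fast class and both fast values
divided by 100 for the slow class; `C_fixed` starts at 0, is optimised as
a continuous quantity and reported rounded.

SLSQP from a single start cannot guarantee the nested-model property
(two-class fit at least as good as one-class).  `fit()` therefore also
evaluates a second deterministic start for the two-class model — the
one-class solution embedded with the slow class switched off — and returns
the best feasible candidate, which enforces nesting without randomness.
Feasibility tolerance is `10⁻⁶` relative to the mean count; inside the
objective the expectation is floored at `10⁻¹²` so the boundary `θ = 0`
stays finite and smooth.

## Orthogroup construction

Pairwise criteria are converted to groups by connected components.
Components that are not cliques are flagged (`is_clique=False`) rather
than re-cut: at the 70% coverage threshold ambiguous components are rare,
but behaviour must be defined.  For the positional definitions, a
component whose group-wide start (and, for definition 3, end) span exceeds
the window is split greedily along ascending coordinate, opening a new
group as soon as the span would overflow.  Definition 3 requires matching
strands by default (configurable); definition 2 applies the 500 bp window
both per edge and to the final group span.  Coverage is computed against
each transcript's own spliced length and both sides must pass; identity of
a reciprocal pair is the more conservative of the two directions.  Ties
and orderings are fixed by sorting on `(chrom, start, sample, id)`, making
clustering invariant to input order.

The splice-variant merge takes the union span per precursor and the
maximum TPM over variants (the TPM of a transcription unit is at least the
TPM of its best-expressed variant); the merged transcript is single-exon
by construction, so the merge is idempotent.

When a transcript overlaps several annotation classes the classifier
applies the precedence intronic → pseudogenic → ncRNA → exon-longer →
antisense → intergenic.  "Intronic" requires full containment in a single
intron (any strand); "ncRNA" requires overlap plus extension beyond the
ncRNA; a transcript overlapping genes on both strands is classed
exon-longer (sense wins, logged).

## Synthetic data: what it emulates, what it does not

`simulate_coalescent_presence` realises the exact generative model
(genealogy + gain/loss), so estimator tests against it probe the fit
machinery, not model adequacy.  `simulate_poisson_spectrum` draws spectrum
entries as independent Poissons around the expectation; it reproduces the
marginal means but not the correlation induced by a shared genealogy, and
is used where many cheap replicates are needed.  The toy catalog generator
plants orthogroups at well-separated loci with configurable coordinate
jitter, sequence divergence (similarity records are derived analytically,
emulating a BLAST with no cross-locus hits), splice variants, and decoy
transcripts for the filter stages.  Real data differ in ways the toys do
not capture: overlapping loci, partial homology, assembly noise, unequal
per-sample catalog sizes, and population structure.  Passing tests
demonstrate the pipeline's correctness on its own terms, not the
robustness of the biological conclusions to those complications.

## Problem sizes and numerical choices

The simulator-vs-theory check uses 20 000 genealogies at
`(θ=50, ρ=2, C_fixed=10, n=6)` (3 SE band); module-level tests use
2 000–4 000 replicates at two parameter sets.  The recovery study uses 100
Poisson spectra at `(θ=9000, ρ=3.46, C_fixed=90, n=6)`.  The acceptance
script reports medians over 25 fitted replicates per parameter set, which
stabilises the reported rates to ~1% without hiding the stochasticity
(`recovery_median_gain_error_pct` reports it directly).  Per-region
coverage fractions are configuration inputs; only the intergenic (0.68)
and ncRNA (0.09) fractions ship as defaults, other regions require a
user-supplied fraction and otherwise omit the normalised gain with a
warning.

## Known limitations

- One or two transcript classes only; no model-selection statistic is
  computed for choosing between them (the χ² values are reported and the
  two-class fit is guaranteed nested).
- Point estimates only; no confidence intervals or bootstrap.
- Per-year rates inherit the full uncertainty of `Nₑ` and the generation
  time; published `Nₑ` estimates for the modelled population span more
  than an order of magnitude, and the per-year scale shifts linearly with
  that choice.
- The genealogy model ignores gene flow between samples and phylogenetic
  structure; spectra from strongly structured samples will bias the rates.
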