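# Methods

## Overview

`hcstopics` treats a multi-endpoint high-content-screening (HCS) study as a
text corpus. Each drug is profiled on 10 cellular endpoints at 4 time points
over a dose series; after summarizing each dose-response curve as a single
control-normalized AUC and discretizing, every drug-hour combination becomes
a "document" whose 10 endpoint "words" occur with integer frequencies. A
latent Dirichlet allocation (LDA) topic model fitted to this corpus yields
two conditional probability tables — p(topic | document) and
p(word | topic) — which are then used (i) to split the endpoints into
disjoint groups by argmax over p(endpoint | topic) and (ii) to score topics
against drug classes defined by in vivo necrosis histopathology, declaring
the highest-scoring topic the class's *diagnostic topic*.

## Preprocessing

1. **Control normalization.** Each treatment curve is divided pointwise by
   the vehicle (DMSO) control curve for the same endpoint and time point
   ("fold of control"). A `difference` mode (treatment minus control) is
   available behind the `normalization` switch; ratio is the default because
   fold-of-control is the prevailing HCS convention.
2. **AUC.** Doses form a 2-fold dilution series, so the natural integration
   axis is log2(dose), on which the grid is uniform. We integrate
   (value − baseline) by the trapezoidal rule, with baseline 1 for ratio
   normalization and 0 for difference. Consequences: a no-effect curve
   scores exactly 0, sub-control responses score negative, and the AUC is
   invariant to the unit the doses are expressed in.
3. **Discretization.** Each AUC-table column is split into `n_bins = 100`
   equal-width bins spanning [column min, column max]; an entry maps to its
   1-based bin index (column maximum → bin 100, constant column → all 1).
   1-based indexing guarantees every endpoint contributes at least one token
   to every document, keeping LDA's support identical across documents. An
   `equal_frequency` (rank-based) scheme is available for sensitivity
   analysis.
4. **Reorientation.** The drug × (endpoint, time) table is reshaped to a
   (drug, time) × endpoint count matrix: 122 drugs × 4 time points → 488
   documents over a 10-term vocabulary. Documents are ordered drug-major
   then time-ascending, terms in catalog order, so output files are
   byte-reproducible.

## Topic model

LDA with K = 3 topics (one per anticipated necrosis class), symmetric
Dirichlet priors α on the document-topic mixtures and β on the topic-word
distributions. Inference is **collapsed Gibbs sampling** over token-level
topic assignments — chosen over variational inference because the collapsed
sampler can be verified exactly against brute-force enumeration on tiny
corpora, and its CPT estimates agree in expectation. The full conditional is

    p(z_i = k | z_-i, w) ∝ (n_dk + α) · (n_kw + β) / (n_k + Vβ)

and the reported CPTs are posterior means over retained post-burn-in
samples of the Dirichlet-smoothed estimates
θ_dk = (n_dk + α)/(n_d + Kα), φ_kw = (n_kw + β)/(n_k + Vβ). Averaging over
samples rather than using a single final state reduces the variance of the
downstream diagnostic scores. The joint log probability
log p(w, z | α, β) is traced every sweep as a convergence monitor.

Defaults: α = 50/K, β = 0.1 (the common convention for topic models with
small vocabularies); 2,000 sweeps, 500 burn-in, sample lag 10. The test
suite and the acceptance script use 400 sweeps / 100 burn-in / lag 10 —
the 488 × 10 corpus with ~300–500 tokens per document mixes within tens of
sweeps, and the planted-recovery results are unchanged at the longer
schedule. Seeds are mandatory; the inner sampler loop is compiled with
numba, and all randomness (initial assignments and the sampler's stream)
derives from the config seed, so identical inputs give identical models.

Topic labels are exchangeable across runs, so all cross-run and
truth-vs-estimate comparisons are made after optimal (Hungarian) matching
of topic-word rows by cosine similarity. Ties anywhere resolve to the
lowest index.

## Diagnostic topics

For a class partition of drugs (a *setting*) and one HCS time point t,
μ_ck is the mean of p(topic k | document(drug, t)) over the drugs of class
c — each drug contributes exactly its single document at that time point,
since the per-time-point view is what exposes the temporal pattern (a
pooled-over-time mode, `time_h=None`, averages all of a drug's documents
instead). The significance score normalizes the class
means within each topic,

    S_ck = μ_ck / Σ_c' μ_c'k ,

so scores lie in [0, 1] and sum to 1 over classes for every topic; the
diagnostic topic of class c is k* = argmax_k S_ck. Exact ties are resolved
to the lowest topic index and flagged, because near-0.5 scores in a binary
setting are uninformative. The statistic is scale-invariant per topic
column and equivariant under topic relabeling.

Three standard binary settings are built from the 3-class label table
rather than hard-coded drug lists: necrosis at 6 h vs not, necrosis at 24 h
vs not, and necrosis at either time vs never.

## Synthetic data generator

No public equivalent of the assay data exists, so the generator emulates
the study design directly: 122 drugs × 10 endpoints × 4 time points
(1, 6, 24, 48 h) × a 10-point 2-fold titration up to 200 μM, one value per
dose level (the well-level aggregation of the original data is unknown; one
aggregated value per dose is assumed), plus one DMSO control curve per
(endpoint, time point).

Planted structure: endpoints belong to three event groups —
{Steatosis, DNA Fragmentation, Mitochondrial Potential, Lysosome Mass},
{DNA Damage, Apoptosis}, and {Cell Loss ×2, Nuclear Size ×2} — and drugs to
three classes with a documented activation schedule:

| class | active group | multiplier over time |
|---|---|---|
| early necrosis | 1 | 1.0 at all four time points |
| late necrosis | 2 | ramps 0.25 → 0.5 → 0.75 → 1.0 |
| non-necrotic | 3 | 0.4 at all time points |

An active endpoint follows a Hill-type sigmoid in log dose (slope 1.5,
per-drug EC50 drawn log-uniformly over the central doses) scaled so the
mean fold-of-control shift at the top dose equals
`effect_size × multiplier`; inactive endpoints sit at the control baseline.
Gaussian noise (`noise_sd`, default 0.05 in control units — i.e. 5% of the
vehicle signal, a typical well-level CV for imaging assays) is added to
every value. `effect_size` defaults to 1.0 (a doubling over control at the
top dose for a fully active endpoint).

Class counts use largest-remainder apportionment of the class fractions
(default 15:8:22 over 45, mirroring the study's necrosis-at-6-h /
late-only / never-necrotic composition; the real 6 h and 24 h necrosis sets
overlap, which three disjoint planted classes cannot express, so the 24 h
class here is "late-onset only"). Label-to-drug assignment is a seeded
permutation, making the whole dataset bit-reproducible per seed.

**What passing tests show — and don't.** The generator plants exactly the
kind of structure LDA represents: endpoint groups co-activated within drug
classes, with monotone dose response and independent Gaussian noise.
Recovery on these data demonstrates that the pipeline's machinery is
correct, not that real HCS data contain such clean structure. Real assays
have plate effects, correlated noise across endpoints on a plate,
non-monotone (e.g. bell-shaped) dose responses, partial class overlap and
mixed mechanisms per drug — none of which are simulated.

## Numerical choices and degenerate inputs

- Constant AUC columns discretize to bin 1 (no information, minimal token
  weight). Non-finite AUCs are rejected.
- Zero control values make ratio normalization undefined and raise an
  error naming the dose; mismatched dose grids raise alignment errors.
- An all-zero topic column in the score statistic (impossible with smoothed
  CPTs, possible with user-supplied means) raises rather than yielding 0/0.
- Empty documents are rejected before sampling; with 1-based binning they
  cannot arise from the pipeline itself.
- Per-stage seeds derive from the global seed by CRC-32 of
  `"<seed>:<stage>"`, so stages can be re-run in isolation and independent
  stages never share a random stream.

## Known limitations

- The numeric table entries of the original analysis are not reproducible:
  they depend on proprietary measurements, and the original
  hyperparameters and iteration counts are unrecorded. The package
  therefore validates structure, exact score arithmetic, sampler
  correctness at enumerable scale, and recovery of planted truth.
- The discretized "counts" are bin indices, not real occurrence counts;
  the multinomial document model is an approximation inherited from the
  method itself.
- K is fixed by design (one topic per class hypothesis); no model
  selection over K is provided.
- Held-out inference for unseen documents is not implemented.
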