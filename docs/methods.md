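# Methods

## Overview

`haplogen` generates synthetic phased human haplotypes in four stages:

1. **Segmentation** — phased biallelic variants are split into sections at
   recombination hotspots, so that strongly linked variants stay together.
2. **Compression** — each section is compressed ~100-fold by an autoencoder
   (a variational autoencoder with sigmoid activations in the production
   configuration), giving a per-haplotype latent code per section.
3. **Generation** — a Wasserstein GAN is trained on the concatenated latent
   codes of all sections and samples novel latent profiles, which are decoded
   section by section and binarized into synthetic haplotypes.
4. **Validation** — the synthetic population is audited for realism (allele
   frequencies, linkage disequilibrium), coherence across sections (shuffle
   control), and privacy (nearest-neighbour edit scores).

The package runs end to end on simulated populations from
`haplogen.synthetic_data`, so no external downloads are required.

## Data model

A haplotype population is a binary N×M matrix (`HaplotypeMatrix`): one row per
haplotype (two per phased donor, `<sample>_A` = left of `|`, `<sample>_B` =
right), one column per variant, 1 = alternate allele present.  Positions are
1-based; recombination-map intervals are stored 1-based with inclusive start
and exclusive end (BED-style half-open input is shifted on read; the reader
takes `coords={"bed","one-based"}`, default `bed`, since published maps use
both dialects).

## Segmentation

Hotspot filtering takes a recombination-rate map (cM/Mb) and

1. removes intervals with rate ≤ 5 cM/Mb (threshold configurable; "at or
   below" is removed),
2. reduces survivors to their centre base ⌊(start+end)/2⌋,
3. scans loci by descending intensity and discards any locus within 5 kb of an
   already-retained stronger locus — diffuse shoulders of one hotspot rather
   than separate events.  Equal intensities retain the smaller position, which
   makes the result order-independent.

Section building scans variants left to right.  Crossing a hotspot closes the
accumulated run as a section if it holds ≥ `min_mutations` (default 500)
variants; otherwise the run is appended to the previously closed section and
the hotspot is counted as *ignored*.  A run reaching `max_mutations` (default
5000) closes immediately at an *artificial hotspot* placed midway between the
last included and the next variant.  The final run closes at the chromosome
end, merging backward if below the minimum.  Conventions chosen where the
procedure is underdetermined:

- a hotspot exactly on a variant position falls *after* that variant;
- a section closes when it holds exactly `max_mutations` variants, so no
  section exceeds the maximum at closing time;
- consecutive ignored hotspots extend the same predecessor section, so a
  section's final length can exceed `max_mutations` by roughly the number of
  consecutive ignored hotspots times (`min_mutations` − 1) in pathological
  hotspot-dense regions;
- the sub-minimum run merges *backward* (the literal reading); the scan
  restarts empty after the ignored hotspot.  The alternative reading — the run
  stays open and keeps accumulating across the ignored hotspot — is available
  as ``merge_mode="forward"`` (CLI ``--merge-mode``), since both readings are
  defensible.

A naive equal-size binning mode (`segment_naive`) exists for comparison, and
`flag_split_bins` marks bins with a hotspot strictly inside their span — used
with a one-sided Mann–Whitney U test to show hotspot-split bins reconstruct
worse than intact bins.

## Autoencoders

Architecture per section of D variants: encoder with three hidden layers on a
5-point geometric progression from D down to the bottleneck ⌈D/100⌉, decoder
mirrored.  Hidden activation is one of relu / sigmoid / tanh / leaky-relu
(slope 0.01); the output layer is ReLU capped at 1 (`clip(z, 0, 1)`); dropout
between consecutive hidden layers is 0.2 (AE) or 0.4 (VAE).  The VAE
bottleneck has linear mean and log-variance heads with reparameterized
sampling.

Losses: the AE minimises mean binary cross-entropy between input and
reconstruction.  The VAE minimises the standard evidence lower bound: BCE
summed over variants plus the KL divergence to a standard normal summed over
latent dimensions, both averaged over the batch, with KL weight 1 and no
annealing.

Training uses Adam (lr 1e-3) on a seeded 80/20 row split, early stopping on
validation loss with patience 10 (30 for sigmoid/tanh, which converge more
slowly), and restores the best weights.  The reported metric is validation
reconstruction accuracy: the fraction of matrix entries reproduced after
binarizing the deterministic (mean-decoded) reconstruction at 0.5.

Numerical/initialisation choices (all exposed or documented here because the
small capped-relu/sigmoid networks are otherwise fragile):

- *Log-variance head bias starts at −5.*  With unit-variance sampling noise
  from the first step, the decoder learns to ignore the latent code and the
  posterior collapses to the prior; starting near-deterministic (σ ≈ 0.08)
  lets reconstruction organise the latent space before the KL term inflates
  variances where affordable.
- *Sigmoid/tanh weight gain ×4 over Glorot.*  Glorot scaling targets the
  linear regime of tanh; for the logistic sigmoid the equivalent gain is 4,
  without which signal attenuates ~4× per layer and deep funnels train
  extremely slowly.
- *Output bias starts at the training-column means* (clipped to [0.05,
  0.95]).  The capped relu has zero gradient outside (0, 1); with zero bias
  roughly half the output units are born in the clipped region and their
  variants can never be reconstructed — the "disappearing mutation" failure
  mode in its most extreme form.  Starting at the base rate keeps every output
  in the gradient-active band.
- Binarization threshold 0.5 everywhere.

The WGAN is trained on latent *means* (the deterministic projection of each
haplotype); decoding generated profiles uses the decoder directly
(`mode="mean"`), and sampling around encoded means uses each row's own
log-variance (`mode="sample"`).

## WGAN

The generator maps `noise_dim` = 1000 i.i.d. N(0,1) draws through three relu
hidden layers of sizes T/10, T/5, T/2 (T = total latent dimension) to a
T-dimensional output with the same activation as the latent space (linear for
VAE means).  The critic mirrors this with hidden sizes T/10, T/50, T/100 and a
single linear output.  Hidden sizes use floor division, floored at 1 with a
warning when T < 100.  At sub-paper scale the resulting one- and two-unit
funnels are vulnerable to dying relu paths, so hidden biases start at 0.01 and
layers with ≤ 2 units get non-negative initial weights; a single unlucky sign
would otherwise sever the network permanently.

Both networks train with RMSProp at lr 5e-5.  One epoch = five critic updates
(fresh real batch, fresh generated batch, weights clipped to ±`clip_value`
after each step) followed by one generator update; the critic loss is
mean(fake scores) − mean(real scores) and the generator loss is −mean(fake
scores).  Checkpoints (both networks' weights) are stored every
`checkpoint_every` epochs (default 10 000 of 30 000) and scored afterwards by
the evaluation module (within-section LD-pattern correlation minus mean
frequency drift of decoded samples); the best checkpoint is used for
generation.

Weight clipping enforces the Lipschitz constraint.  The classic bound 0.01
assumes wide hidden layers; with uniform clipping at c a relu critic's maximum
slope is ∏(c · fan_in) over its layers, which at desk scale (T ≈ 20, unit-width
layers) is ~10⁻⁷ — the Wasserstein signal vanishes entirely.
`suggested_clip_value(T)` solves ∏(c · fan_in) = 1 for c; at T ≈ 1000 it
reproduces ≈ 0.015, essentially the classic recipe, and at T ≈ 20 gives ≈ 0.4.
Desk-scale runs use this value; `WGANConfig.clip_value` defaults to the
classic 0.01.

## Evaluation

- **Frequency drift**: per-variant |f_ref − f_syn| (column means);
  `n_disappeared` counts variants present in the reference and absent after
  decoding+binarization.
- **LD**: signed Pearson r between allele indicator columns across haplotypes
  (chosen because both positive and negative LD are informative; r² would fold
  them); signed D′ is available via ``statistic="dprime"``.  Monomorphic
  columns give 0 by convention.
- **Edit score**: Hamming distance to each reference haplotype divided by
  sequence length; the k = 3 smallest are the 1st–3rd nearest-neighbour
  scores.  A synthetic sample with 1st-NN ≈ 0 and a sharp jump to the 2nd-NN
  is a near-copy of a training haplotype; the jump ratio
  (2nd−1st)/(3rd−2nd) quantifies this (values ≳ 3 are suspicious; steadily
  increasing scores indicate genuine interpolation).
- **Coherence**: cross-section LD blocks of adjacent section pairs are
  correlated (vectorised Pearson) between reference and synthetic data, and
  between reference and a *shuffled* control in which row order is permuted
  independently within each section — destroying cross-section structure while
  preserving every marginal frequency and every within-section LD pattern.  A
  coherent generator must beat its own shuffled control.  PCA projections
  (fitted on the reference only) of reference/synthetic/shuffled data are
  returned for plotting.
- **Ancestry metaprofiles**: given per-sample ancestry label sequences from an
  external chromosome-painting tool, the switch profile at position i is the
  fraction of samples whose label changes between i−1 and i; reference and
  synthetic profiles are compared by Pearson correlation.  The alternative
  reading (population-level changes) is not implemented.

## Synthetic populations

`simulate_population` draws founder allele frequencies from Beta(0.5, 0.5)
truncated to [0.05, 0.95] — U-shaped like a real site-frequency spectrum but
bounded away from 0 so fixture variants survive the ≥3-carrier filter at desk
sample sizes — then builds each haplotype by copying one founder left to right
and switching to a uniformly chosen founder at each hotspot with probability
`crossover_prob` (default 0.5), finally applying per-site flip noise (default
0.01).  The emitted recombination map has rate 10 cM/Mb intervals centred
exactly on the hotspot positions and rate 0 elsewhere, so hotspot filtering at
the default threshold recovers the simulated hotspots exactly (when they are
farther apart than the 5 kb proximity radius).  A truth record stores the
founder assignment of every block of every haplotype.

What the simulator does *not* emulate: realistic site-frequency spectra
dominated by rare variants, LD decay within blocks, mutation/recombination
coalescent history, population structure, or genotyping error correlation.
Passing tests on these fixtures therefore demonstrates that the pipeline
recovers planted block/founder structure, not that it reproduces every
property of real cohort data.

## Problem sizes in the bundled runs

Tests and the acceptance script run at desk scale, chosen so the full
pipeline (simulation, VAE training, WGAN training, generation, validation)
completes on one CPU: compression fixtures of 500 haplotypes × 600 variants
with 20 founders; end-to-end runs on 3 sections (~700 variants each, total
latent dimension ≈ 22) compressed by the architecture that wins validation on
this fixture (the relu AE — with no rare variants to lose, it beats the
mode-searching sigmoid VAE here, the mirror image of the selection on real
rare-variant-dominated data); WGAN batches of 64 for 20 000–30 000 epochs with
checkpoint selection; 100 generated haplotypes.  Autoencoders train for a
fixed budget of 800–1500 epochs keeping the best validation weights: at this
data size an epoch is only ~13 parameter updates, so the patience defaults
(calibrated to cohort-scale epochs) would fire inside the optimizer's initial
transient.

## Known limitations

- At bounded minor-allele frequencies (no rare variants), heavy dropout (the
  0.4 VAE rate) limits achievable reconstruction accuracy on founder-mixture
  fixtures: the sigmoid VAE "mode searches", collapsing its reconstructions to
  a handful of founder archetypes.  On real cohort data, where rare variants
  dominate and per-variant baselines are high, the same architecture is the
  preferred compressor; on these fixtures the relu AE is.
- Below T ≈ 100 total latent dimensions the WGAN sizing rules yield one- and
  two-unit hidden layers; the resulting generator manifold and near-linear
  critic reproduce global moments of the latent distribution but not its
  cluster structure, which limits LD preservation and cross-section coherence
  of generated data at desk scale.  The rules were designed for
  cohort-scale latent spaces (hundreds to thousands of dimensions).
- Phased input is required; no phasing, imputation, or multiallelic
  decomposition is performed.
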