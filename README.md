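# graphot

Optimal-transport models of letter-shape (graphetic) similarity, and the
EEG representational similarity analysis (RSA) that tests them.

Visual word recognition begins with the perception of letter shapes, yet
models of reading usually treat letters as irreducible symbols.  This
package implements a computationally explicit alternative: the
dissimilarity between two letters is quantified by the **Wasserstein-1
distance** (earth mover's distance) between their rendered glyphs —
the minimal cost of transporting one letter's pixel "ink" onto the
other's — and compared against the classical overlap-based **Jaccard
distance**.  Brain–model alignment is then estimated by correlating these
model geometries with dissimilarities between letter-evoked EEG patterns.
It is intended for cognitive/computational neuroscientists studying
orthographic processing, and more generally for anyone who wants exact
discrete optimal transport between raster shapes with a tested RSA stack
on top.

## What it computes

For glyphs rendered as intensity images `a`, `b` (values in [0, 1],
masses rescaled to sum to 1):

- **Jaccard distance** (fuzzy form):
  `d_J = 1 − Σᵢ min(aᵢ, bᵢ) / Σᵢ max(aᵢ, bᵢ)`
- **Wasserstein-1 distance**: `d_W = min_T Σᵢⱼ Tᵢⱼ ‖xᵢ − yⱼ‖₂` over
  couplings `T` with marginals `a`, `b` — solved exactly as the
  transportation linear program, after overlap-aligning the pair at the
  peak of their 2-D cross-correlation.
- **Gromov-Wasserstein distance** (square loss) between the glyphs'
  internal distance structures — invariant to translation, rotation and
  reflection.
- **Transformation-invariant variants**: the minimum of `d_J` / `d_W`
  over translation, scale (log-bounded in [log ½, log 2]) and rotation of
  one glyph, via multi-start Nelder–Mead (5 equidistant starts per
  optimised dimension; translation for Jaccard is resolved by the
  cross-correlation peak).

All unordered pairs of the 30 lower-case German letters (a–z, ä, ö, ü, ß)
form a 30 × 30 representational dissimilarity matrix (RDM) with 435
informative pairs.  Neural RDMs are `1 − Pearson r` between per-letter
ERP pattern vectors (a posterior 30-channel region of interest, 150–225 ms
window, samples concatenated end-to-end), rank-transformed.  Alignment is
estimated with a Bayesian model of the Spearman correlation structure:
stacked standardised rank vectors are modelled as multivariate normal
with a shared correlation matrix under a uniform (LKJ η = 1) prior, so
directional Bayes factors equal posterior odds
(`BF = #{θ > 0} / #{θ < 0}` over posterior samples).  Partial
correlations, 50%/89% highest-density intervals, and a leave-one-out
noise ceiling complete the analysis.  A synthetic-data generator with a
known ground-truth mixture of model RDMs makes the entire pipeline
testable without EEG recordings; a trial-schedule generator reproduces
the alphabetic decision task's pseudorandomisation constraints.

## Worked example

```python
from graphot import (
    render_letter_set, build_model_rdm, rank_transform_rdm,
    SynthConfig, synth_epochs, all_participant_rank_rdms,
    run_planned_analysis, MCMCConfig, spearman_rdm,
)

letters = tuple("abcdefghijkl")
images = render_letter_set(letters, max_height_px=28)
rdm_w = build_model_rdm(images, metric="wasserstein")
rdm_j = build_model_rdm(images, metric="jaccard")
rank_w, rank_j = rank_transform_rdm(rdm_w), rank_transform_rdm(rdm_j)
print(f"Jaccard-Wasserstein Spearman = {spearman_rdm(rank_j, rank_w):.2f}")

cfg = SynthConfig(n_participants=14, trials_per_letter=8, n_channels=10,
                  sfreq=250.0, epoch_span_ms=(-100.0, 400.0),
                  weights=(0.6, 0.2), snr=2.0, seed=7)
epochs = synth_epochs(cfg, [rdm_w, rdm_j])
neural = all_participant_rank_rdms(epochs, roi=epochs.channel_names,
                                   window_ms=(150.0, 225.0))
result = run_planned_analysis({"wasserstein": rank_w, "jaccard": rank_j},
                              neural, MCMCConfig(seed=7))
```

This prints, and the result object reports:

```
Jaccard-Wasserstein Spearman = 0.70
rho(wasserstein) median = 0.936, 89% HDI = [0.931, 0.941]
rho(jaccard)     median = 0.745, 89% HDI = [0.726, 0.763]
H1: BF > 80000        # P(rho_W > 0) vs P(rho_W < 0)
H2a: BF > 80000       # rho_W > rho_J
H2b: BF > 80000       # same ordering for partial correlations
noise ceiling = [0.941, 0.949]
```

The synthetic ground truth weighted the Wasserstein RDM (0.6) above the
Jaccard RDM (0.2), so the analysis recovers a higher Wasserstein
correlation, every posterior sample orders the two models correctly
(hence the capped "BF > draws" reports), and the Wasserstein correlation
approaches the noise ceiling — the best any model could do given
between-participant variability.  H2a and H2b agree because converting a
correlation matrix to partial correlations preserves the ordering of its
entries.

A thin CLI mirrors the library:

```bash
graphot design --seed 1 --out schedule.tsv
graphot model-rdm --metric wasserstein --height 32 --out rdm_w.csv
graphot run-all --seed 1 --out results/
```

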