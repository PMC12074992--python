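# Methods

## The problem

Most tandem mass spectra in bottom-up proteomics are chimeric: the isolation
window of an MS2 scan transmits more than one peptide precursor, so the
recorded fragment intensities are a superposition of several peptides'
fragmentation patterns.  Classic spectrum identification assigns one peptide
per spectrum (or strips explained peaks and searches again), which either
wastes shared fragment intensity or double-counts it.  specdecon instead
models each MS2 spectrum explicitly as a non-negative linear combination of
predicted pure spectra and reads the mixing coefficients off as both
identification evidence and quantitative signal.

## Model

For one spectrum, let `I_m_exp` (m = 1..M) be the experimental intensities
over *mass channels* and `I_{p,m}` (p = 1..P) the normalized predicted
intensity of candidate p in channel m.  Channels are defined by the
experimental peaks matched by at least one predicted fragment — two
fragments from different candidates hitting the same peak share a channel,
which is the whole mechanism for distributing shared fragment ions — plus
one zero-intensity channel per cluster of unmatched predicted fragments
(clustered at the match tolerance; keeping one channel per fragment instead
would only enlarge M with duplicate zeros).  Every predicted spectrum is
normalized to total sum 1 before channel assignment, so each design row sums
to 1 and a coefficient has the units of summed fragment intensity: the
interference-corrected total ion current (TIC) of that precursor in that
scan.

The coefficients minimize

    sum_m (I_m_exp - I_m^T beta)^2 + lambda * ||beta||_1,   beta >= 0

exactly as written — no 1/2 factor, no column standardization — by cyclic
coordinate descent with the non-negative soft-threshold update
`beta_p <- max(0, c_p - lambda/2) / ||col_p||^2`, converged at
`max |dbeta| <= 1e-8 * max(1, max beta)` or 1,000 sweeps.

### Choosing lambda

A geometric path of 30 values from `lambda_max = max_p 2 col_p . y` (the
smallest lambda with an all-zero solution) down to `1e-3 * lambda_max`, plus
`lambda = 0`, is evaluated with warm starts.  Each lambda contributes the
*support* of its LASSO solution; the model actually scored is the
non-negative least-squares refit on that support, and the score is the
corrected Akaike information criterion

    AICc = M ln(RSS/M) + 2k + 2k(k+1)/(M-k-1),   k = (#nonzero) + 1

(the +1 counts the noise variance; models with `M - k - 1 <= 0` are
disqualified; ties — exact, or within the configurable `aicc_tie_window`,
default 0 — resolve toward the larger lambda, i.e. the most regularized of
the equally good models).  Scoring the refit rather than the shrunk
coordinate-descent solution matters: AICc applied to shrunk solutions
compares shrinkage levels rather than candidate sets and under-regularizes
(in our signal-plus-noise benchmark it kept the spurious candidate ~3x more
often); after refitting, the selection agrees with exhaustive best-subset
least squares + AICc on 100/100 benchmark instances, and the winning
coefficients are unbiased TIC estimates.  One visible consequence: when a
single candidate fits perfectly, the reported lambda is the largest lambda
whose support already contains it, not 0 — the selected model (and its
coefficients) are identical to the lambda = 0 fit.

Coefficients below `1e-8 * max(beta)` are treated as zero when emitting
PSMs: coordinate descent at lambda = 0 leaves numerical residue at that
scale on candidates the selected model did not use.

### Shadow-spectrum rescoring

After the fit, each candidate with a positive coefficient is rescored
against its *shadow spectrum*: the experimental channel intensities minus
the fitted contributions of all other candidates, clamped at zero.  The
score vector (matched-fragment count, matched intensity fraction, normalized
spectral contrast angle `1 - 2 arccos(cos)/pi`, explained-TIC fraction, RT
delta, precursor ppm error, length/charge/missed-cleavage covariates) is
recomputed on the shadow intensities and the spurious-match pre-filter is
re-applied: at least three matched fragments, the predicted base peak
matched, and at least one more of the three most intense predicted peaks
matched.  Only survivors are reported — several per spectrum when the
spectrum is chimeric.

## Search workflow

Candidates come from an in-silico tryptic digest (after K/R not before P;
length 7-30; <= 2 missed cleavages; charges 2-4 — simulation studies use
2-3, matching the simulator's charge assignment) with per-peptide shuffled
decoys that preserve length, composition and the C-terminal residue
(Fisher-Yates on the non-C-terminal residues, per-peptide seed, 20 retries
against I/L-collapsed target collisions, reversal fallback, unshufflable
flag).  I/L isomers are collapsed to one scored representative
(lexicographically smallest) and expanded back afterwards with identical
scores and an `ambiguous` flag.

A sorted-array fragment ion index returns, in O(log F + hits), all
candidates owning a fragment near a peak; candidates additionally need at
least one precursor isotope (Poisson envelope, `lambda = 0.000594 * mass`,
5 isotopes, renormalized) inside the isolation window +- 10 ppm.  Pass 1
scores the top candidates of every spectrum without a retention-time filter;
target-decoy competition on the best PSM per spectrum defines a confident
set (1% FDR) that drives three calibrations for pass 2:

* **RT window** — least squares from predicted RT fraction to observed
  minutes; halfwidth = max |residual| x 2.5, floored at 0.5 min (the floor
  prevents zero-width windows in noiseless simulations); fewer than 10 pairs
  or a degenerate predictor falls back to the full gradient.
* **Mass recalibration** — subtract the median fragment ppm error; shrink
  the tolerance to 1.5x the 95th percentile of recalibrated |errors|
  (floor 5 ppm, default tolerance 20 ppm).
* **Class pruning** — search-space classes keyed by (length, missed
  cleavages, modification multiset) without confident pass-1 identifications
  are dropped; skipped entirely when fewer than 50 confident PSMs exist,
  because a tiny census would prune blindly.

Pass 2 repeats retrieval under the RT filter (disabled for direct-infusion
data, which has no RT axis), resolves isobaric candidate groups (precursor
m/z within tolerance and >= 90% shared matched-peak positions; best
spectral angle wins, ties lexicographic) and deconvolves every spectrum.

## FDR control

q-values use classic target-decoy competition,
`FDR(t) = (#decoys >= t + 1)/max(1, #targets >= t)` with the running
minimum over looser thresholds; ties share a q; decoys receive the q of
their position.  All PSMs of a spectrum enter the competition — the output
is multi-PSM-per-spectrum by design.  The combined score comes from
semi-supervised rescoring: 3 cross-validation folds split by spectrum,
initialization with the single best feature, up to 10 iterations of a linear
discriminant trained on (targets at <= 1% training FDR) versus all decoys,
a 400,000-row training cap, and per-fold scores rank-normalized against the
fold's decoy distribution.  A linear discriminant stands in for the usual
SVM deliberately: it is deterministic, dependency-light, and the learner is
a component, not the contribution; the interface accepts any scorer with
`fit`/`decision_function`.  Rollups re-run the competition on best member
scores per entity — PSM/precursor/peptide-group level, run-specific or
global context; peptide groups pool I/L variants and modification state.

Entrapment validation searches an augmented database of known-absent
peptides (per-segment shuffles of target proteins that keep K/R/P positions
fixed, so the digest fragment-length spectrum is preserved; entrapment
peptides colliding with targets on the I/L-collapsed key are removed).
Entrapment entries compete as targets with their own shuffled decoys.  At a
self-reported q cutoff accepting N (original + entrapment) targets of which
E are entrapment, the package reports both `efdr_lower = E/N` and
`efdr_combined = E(1 + 1/r)/N`, labelled explicitly rather than guessing
any further variant; r is the entrapment:target database size ratio.

## Quantification

For DIA/PRM, the coefficients of a precursor across consecutive scans of
one isolation window form a pseudo-XIC.  The apex is the coefficient-
weighted mean of relative retention times over PSMs at <= 1% run-specific
PSM FDR, transferred from other runs when the run itself has none.  Per-run
maximum integration borders are the 99% quantile (linear-interpolation
definition) of peak widths at base — operationalized as the span of the
contiguous coefficient run around the apex under the gap rule, since "at
base" has no further numeric definition — from precursors with >= 3
qualifying PSMs, falling back to 1 min below 20 such precursors.  Walking
outward from the scan nearest the apex, one missing cycle is bridged (gap
scan); a second consecutive missing cycle inserts a zero and closes the
border; borders are clipped symmetrically to apex +- width/2 (the symmetric
choice is ours; an asymmetric clip would be equally defensible).  Quantity
is either the maximum coefficient inside the borders (apex mode, the
default) or the trapezoidal integral (area mode).  DDA rows carry
identification only; direct infusion sums coefficients over scans sharing
the window.  Precursors confidently identified globally (q <= 0.01 in >= 1
run) are quantified in every run with an assemblable XIC, and both global
and run-specific q are reported so users can filter either way.
Peptide-group quantity is the sum over member precursors.

## Synthetic data

The simulator implements the forward model the engine inverts: each scan's
peaks are `sum_p contribution_p x predicted_p` with
`contribution_p(t) = abundance_p * exp(-(t - apex_p)^2 / 2 sigma_p^2)`,
coincident peaks centroid-merged at 5 ppm.  It shares the hash-based toy
predictor with the searcher (uniform variates from a 64-bit hash of the ion
descriptor, squared for dynamic range, normalized to sum 1; RT an affine
clip of mean Kyte-Doolittle hydropathy), so noiseless simulations are a
perfect-prediction regime with exact per-scan ground truth.  Schemes: DIA
(contiguous windows), DDA (top-10 on simulated MS1 with 20 s dynamic
exclusion), PRM (inclusion windows), DI (no RT axis).  Elution sigma is
log-normal around `0.05 x gradient/60` min; abundances log-normal over ~2
orders of magnitude around 1e5 counts.  Noise is the minimal set needed to
stress the pre-filters, model selection and FDR calibration: per-peak
log-normal jitter, uniform-m/z noise peaks, pure-noise spectra, and an
intensity-floor dropout.  Not emulated: isotope interference within MS2,
co-eluting modified forms, detector saturation, instrument-specific noise
physics — so passing tests demonstrate correctness of the inference
machinery under its stated model, not performance on real instrument data.

## Study problem sizes

The FDR-calibration study uses a synthetic proteome of 110 proteins
(~1,800-2,400 digest peptides, all of which double as the ~2,000 true
peptides), an equally sized entrapment set (r = 1), shuffled decoys for
both, a 30-min DDA gradient at 3 s cycle time, per-peak log-normal noise
(sigma 0.35), 20 noise peaks and 2 pure-noise spectra per cycle, at
isolation widths 1.4, 8 and 20.4 Th across 5 seeds.  The quantification
study uses ~260 precursors in 420-820 m/z, 20-Th DIA windows over an 8-min
gradient at 2 s cycle time, one replicate per condition and species log2
ratios (-2, 0, +1).  These sizes are the package's own choice of a
desk-scale experiment; every number the tests assert is recomputed from
them at run time.

## Known limitations

* The toy predictor is deliberately unphysical (hash intensities); library
  mode accepts any external TSV library but ships no trained model.
* Posterior error probabilities are not estimated (column reserved).
* Protein inference, protein-level FDR and MS1 feature quantification are
  out of scope.
* mzML reading supports centroided spectra with 32/64-bit float arrays and
  optional zlib compression; profile spectra and vendor formats are not
  supported.
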