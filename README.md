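# seqreg

Information regularity in temporally extended event sequences: a tested,
reusable pipeline for sliding-window randomness measures over constrained
visuomotor trial sequences, and for the parametric-modulator fMRI GLM that
relates those measures to regional BOLD — exercised end to end on
synthetic sessions and simulated ROI time series with known ground truth.

## Who this is for

Researchers studying how the brain tracks statistical regularities of
stimuli and of self-generated actions at multiple timescales.  The package
provides (1) a generator of task sessions with the design constraints of a
choice/specified finger-tapping paradigm, (2) the information-theoretic
trial-level measures, (3) the behavioral group statistics over those
measures, and (4) the first- and second-level GLM machinery, with a BOLD
simulator so that every stage can be validated by parameter recovery
rather than by eye.

## The measures

A session is a sequence of task stimuli `C_i ∈ {a,…,h}` (four *chosen*
stimuli offering three permitted responses, four *specified* stimuli
instructing one) and actions `A_i ∈ {1,…,4}`.  For a sliding window of the
`n` most recent task trials `[i − n + 1, i]`, three measures are assigned
to trial `i` (defined for `i ≥ n`):

- **Trial entropy** `TE_i = −Σ_k P(C_j = k) log P(C_j = k)` — Shannon
  entropy of the eight stimuli in the window; randomness of the recent
  stimulus sequence.
- **Selection entropy**
  `SE_i = −Σ_k Σ_m P(A_j = m, C_j = k) log P(A_j = m | C_j = k)` over the
  chosen trials in the window — conditional entropy of voluntary selection
  given the stimulus.
- **Surprise** `SUP_i = −log P(C_j = k)` for the current stimulus `k` —
  the self-information of the current event under the window's empirical
  distribution.

Probabilities are empirical window frequencies; logs default to base 2.
The measures are computed on a grid of window lengths (25–50 trials, step
5) to probe different timescales, and enter a first-level GLM as
mean-centred, serially orthogonalized parametric modulators (order: onset,
condition contrast, TE, SUP, SE) convolved with a canonical double-gamma
HRF, with a 400 s discrete-cosine high-pass and removal of the volumes
before the first full window.  Per-subject modulator betas across window
lengths are then tested with a repeated-measures ANOVA (subjects blocking;
df = (k−1, (n−1)(k−1))), Benjamini–Hochberg FDR, and post-hoc paired t
tests.

## Worked example

```python
import seqreg

# a full 1008-trial session: 50% chosen / 25% specified / 25% null,
# runs of at most four same-condition trials, repeat availability
# balanced within each condition
session = seqreg.generate_session(seed=1)

# randomness series at a 25-trial window (values in bits)
table = seqreg.randomness_table(session, 25)
print(table.loc[table.valid, ["trial_index", "TE", "SE", "SUP"]].head(3))
```

```
 trial_index       TE       SE      SUP
          38 2.599080 0.960787 2.058894
          39 2.675085 0.892159 3.643856
          40 2.739471 0.892159 3.643856
```

The first valid value appears at the 25th task trial (session trial 38
here, because null trials do not advance the window).  TE near its 3-bit
ceiling says the recent stimulus mix was close to uniform; SUP = 3.64 bits
means the current stimulus occurred in only 2 of the 25 window trials.

Recovery of injected couplings through the whole chain (session → series →
design → simulated BOLD → GLM), with negative entropy couplings and a
positive surprise coupling of magnitude 0.5 at contrast-to-noise 0.5:

```python
bundles = seqreg.simulate_group(
    n_subjects=4, config=seqreg.ExperimentConfig(n_trials=300),
    windows=(25, 50), truth=seqreg.preset_signs(gen_window=25),
    target_cnr=0.5, n_volumes=380, seed=1,
)
effects = seqreg.group_effects(bundles)
print(effects[effects.window == 25].groupby(["roi", "measure"])["beta"].mean())
```

```
roi      measure
roi_se   SE        -0.495
         SUP        0.005
         TE         0.000
roi_sup  SE         0.090
         SUP        0.436
         TE         0.002
roi_te   SE         0.013
         SUP       -0.013
         TE        -0.456
```

Each ROI recovers its own injected coupling (−0.5, −0.5, +0.5) with the
correct sign and near-zero cross-talk.

A full synthetic experiment with all artifacts and a reproducibility
manifest:

```
seqreg run --config config.yaml --out results/
```

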