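# lexepi

Epidemiological estimation of the basic reproductive ratio of words.

Lexical innovations — new words spreading through a speaker population —
behave like endemic pathogens: non-users acquire a word from users, keep
using it for the rest of their lives, and are eventually replaced by
fresh non-users through population turnover.  `lexepi` treats the
lexicon with the standard susceptible–infectious–susceptible (SIS)
machinery and estimates, per word, the **basic reproductive ratio**
R₀ — the expected number of people who pick up the word from a single
user over that user's whole "prolific" period.  A word spreads iff
R₀ > 1.

It is aimed at quantitative linguists and cultural-evolution
researchers who have (or can emulate) three standard data types:
age-of-acquisition norms, survey prevalence, and diachronic corpus
frequency trajectories.

## The model and the three estimators

With user fraction *U*, propagation rate β, abandonment rate γ and
mortality rate μ (all per year), the dynamics are

    dU/dt = β U (1 − U) − (γ + μ) U,     R₀ = β / (γ + μ).

For R₀ > 1 the user fraction follows a logistic curve with intrinsic
growth rate r = β − γ − μ toward the endemic equilibrium
U\* = 1 − 1/R₀.  Three closed-form identities then give three
independent estimators per word:

| method | identity | data needed |
|---|---|---|
| `aoa` | R₀ = LE / AoA | mean age of acquisition, life expectancy LE |
| `prevalence` | R₀ = 1 / (1 − p_U) | survey prevalence p_U |
| `growth` | R₀ = 1 + r·(LE − AoA) | logistic growth rate r of the reconstructed prevalence trajectory U(t) = p_U · f(t)/max f(t) |

Each estimate carries a 95% margin of error: first-order (delta-method)
propagation of the LE, AoA and prevalence margins, and a parametric
bootstrap (binomial resampling of the trajectory at the survey sample
size) for the growth rate.  Derived quantities include the
herd-immunity/stability threshold H = 1 − 1/R₀ and the contact-network
variant R₀ = T(⟨k²⟩ − ⟨k⟩)/⟨k⟩.

The pipeline applies the standard filters: core-lexicon words
(p_U ≥ 0.95) are excluded; the growth estimator is restricted to words
whose reconstructed prevalence increased significantly (Spearman trend
test) and whose fitted ratio is nonnegative; the stability coefficient
S = 1 − |ρ| (Spearman ρ of value vs. time over 1950–2000) records how
close each word rests to its equilibrium.

## Worked example

Real norm and corpus datasets are large and external, so the package
ships a generator that emulates them with known ground truth:

```python
from lexepi import (GeneratorConfig, generate_lexicon, RunConfig,
                    run_pipeline, herd_immunity_threshold, contact_share)

lex = generate_lexicon(GeneratorConfig(n_items=100, seed=42))
report = run_pipeline(lex.norms, lex.trajectories, RunConfig(n_boot=50, seed=42))
print(report.summaries.to_string(index=False))
```

prints

```
    method   n   median       q1       q3  median_moe
       aoa 100 6.004605 4.608571 8.017190    0.439512
prevalence 100 5.607966 4.152397 7.796258    1.362296
    growth  51 6.060207 4.397129 7.907412    0.633533
```

All three methods agree on a median R₀ of about 6 (the generator drew
true ratios from a log-normal law with median 6): an average spreading
word is passed on to roughly six other people per user.  The growth
method covers only the 51 words whose trajectories increased
significantly — the other 49 sit at equilibrium, where no growth rate
is identifiable.  The `median_moe` column shows the typical 95% margin
per method; prevalence-based margins are widest because 1/(1 − p) is
steep near high prevalence.  Downstream thresholds follow directly:

```python
r0 = report.summaries.set_index("method").loc["prevalence", "median"]
print(f"stability threshold H:  {herd_immunity_threshold(r0):.3f}")
print(f"contact share (600):    {contact_share(r0, 600):.4f}")
```

```
stability threshold H:  0.822
contact share (600):    0.0093
```

i.e. about 82% of potential adopters would have to be blocked for such
a word to die out, and a single user passes the word to under 1% of a
600-person lifetime contact network.

The same pipeline runs from the shell on CSV inputs:

```sh
lexepi simulate --n-items 100 --seed 42 --out data/
lexepi validate --norms data/norms.csv --trajectories data/trajectories.csv
lexepi estimate --norms data/norms.csv --trajectories data/trajectories.csv \
    --n-boot 300 --out run/
```

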