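# peerdiffusion

Agent-based simulation of physical-activity diffusion in classroom social
networks, for researchers designing **social network interventions**: health
programmes that educate a few influential pupils ("peer influencers") and rely
on peer influence to spread more active behavior through the class.

The package compares two ways of measuring the social network such an
intervention is designed on:

* a **web-based communication network** — directed edges from one-to-one
  messages exchanged on a class messaging platform, weighted by
  `w_ij = m_ij / max_c(m)` (pair message count over the class maximum), and
* a **peer-nomination network** — directed edges from the sociometric question
  *"who do you hang out or have contact with?"*, weighted by the fraction of
  four sociometric questions in which the ego named the alter
  (`w ∈ {¼, ½, ¾, 1}`).

On either network it selects the per-class top 15% of pupils by in-degree,
betweenness or closeness centrality, and simulates a health-education boost to
their physical activity with a threshold diffusion model.

## The model

Each agent *i* has a physical activity level `PAL_i` (mean daily steps /
10,000) and a family-affluence score `FAS_i` (0–12). Once per simulated day,
synchronously:

```
S_i = Σ_j W_ij · PAL_j              weighted mean of i's influencers
E_i = clip( PAL̄₀ · FAS_i / FAS̄₀ )   socioeconomic target
C_i = (1 − λ) · S_i + λ · E_i       combined influence   (λ = 0.2)

if |C_i − PAL_i| > T_PAL:  PAL_i ← clip( PAL_i · (1 ± I_PAL) )
```

`W` is the row-normalized influence matrix derived from the class network,
`T_PAL` the change threshold and `I_PAL` the change magnitude. The two free
parameters are calibrated by grid search: every `(T_PAL, I_PAL)` lattice point
is simulated to steady state from wave-1-resampled initial PALs and scored by
the sum of squared errors against per-class observed mean PALs at three year
points; the 100 best-fitting combinations form the parameter-uncertainty
ensemble. An intervention multiplies the selected influencers' PAL once by
`1 + boost` (reference boost 17%; sensitivity 5/10/20%) and runs 200 further
days; its **relative impact** is the percentage change in mean PAL between the
pre-boost baseline and day 200, summarized by the median and IQR over the
ensemble.

Because the cohort study the design is modelled on is not publicly deposited,
the package ships a synthetic-data generator (`peerdiffusion.synthetic_data`)
that emulates its structure: 21 classes of 15–27 pupils, right-skewed per-pair
message counts with class totals in 143–5301, at least one nomination per
pupil per question, daily steps averaging ~9,200 with invalid wear days, FAS
sums averaging 9.1, and a tunable (~0.69) Jaccard overlap between the two
network representations.

## Worked example

The numbered scripts under `analysis/` run the full study on the default
synthetic cohort and write tables under `results/`:

```sh
python analysis/01_generate_cohort.py
python analysis/02_build_networks.py
python analysis/03_compare_networks.py
python analysis/04_calibrate.py            # ~1 minute
python analysis/05_simulate_interventions.py
python analysis/06_boost_sensitivity.py
```

Output (seed 1):

```
cohort: 442 pupils in 21 classes
messages: 28817 total; class totals 164-3868
wave-5 mean PAL: 0.907 (range 0.19-1.65)
web: density 0.381 (SD 0.049), mean weight 0.154, 3461 edges
nomination: density 0.341 (SD 0.026), mean weight 0.443, 3145 edges
network similarity (Jaccard): 0.66 (SD 0.07)
closeness: 35/66 influential peers shared (53%)
web: best fit T_PAL=0.18, I_PAL=0.046 (SSE 0.2056)
web/closeness: median impact 2.38% (IQR 2.24-2.49) ≈ 215 steps/day
boost 5%: median impact 0.75% (69% lower than reference)
boost 10%: median impact 1.45% (39% lower than reference)
```

Reading: the two network representations share about two-thirds of their
edges but only about half of the influential peers they nominate, yet the
simulated 17% health-education boost raises cohort mean PAL similarly
(~2.4%, ≈215 extra steps per pupil per day) in both. Halving or thirding the
boost shrinks the impact near-proportionally — the lever that matters most is
the effectiveness of the health education itself, not the centrality measure.

The same pipeline is scriptable end to end (`peerdiffusion run --config
cohort.yaml --out DIR --seed N`, or `peerdiffusion generate` for the cohort
alone) via the `PipelineConfig` YAML schema in `peerdiffusion.pipeline`.

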