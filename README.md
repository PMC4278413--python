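# cbf3select

Model selection for circadian clock control of *CBF3* transcription in
*Arabidopsis thaliana*.

The C-REPEAT BINDING FACTOR genes (*CBF1–3*) trigger cold acclimation and
freezing tolerance, and their expression is clock-controlled: *CBF3* mRNA
peaks sharply 8 h after dawn (ZT8), with a phase that is robust to
photoperiod and persists in constant light. Which clock components drive
that waveform directly — morning activation by LHY/CCA1, evening
repression by TOC1, repression by the Evening Complex (EC), or the
day-phased PRRs — is a question this package addresses by statistical
comparison of dynamical models, for researchers working on circadian
output pathways and gene-network inference from time-series data.

## The model ensemble

*CBF3* mRNA is a pure clock output with Hill-function transcription and
first-order decay,

    dC/dt = v · ∏_A A^n/(A^n + K_A^n) · ∏_R K_R^n/(K_R^n + R^n) − d·C,

where the products run over candidate activators A and repressors R taken
from six clock regulator proteins (LHY/CCA1, PRR9, PRR7, NI, TOC1, EC)
whose waveforms are supplied by a configurable clock driver (built-in
phenomenological waveforms by default; optionally an SBML clock model).
A 13-member ensemble of candidate architectures is fitted to expression
time series in four light regimes (8L/16D, 12L/12D, 16L/8D, constant
light) by seeded multi-start least squares, scored with the corrected
Akaike Information Criterion computed from the pooled residual sum of
squares (`AICc = n·ln(RSS/n) + 2k + 2k(k+1)/(n−k−1)`), and ranked by
Akaike weight. Fitted models are then interrogated in silico: clock-mutant
simulations (*lhy cca1*, *ni prr7 prr9*, *toc1*, *lux*) and circadian
gating of cold induction, where a five-fold cold stimulus is routed either
through the clock (a transient LHY/CCA1 rise) or directly to the *CBF3*
transcript, every 4 h across the subjective day.

See `docs/methods.md` for model assumptions, parameter defaults, numerical
choices and known limitations.

## Worked example

```python
from cbf3select.pipeline import RunConfig, run_selection, run_experiments

config = RunConfig(master_seed=1, outdir="results/run1")
table, fits = run_selection(config)   # data -> clocks -> 13 fits -> AICc table
print(table.to_text())
```

```
Rank Model                             AICc score  AICc weight  Features
1    EC↓:TOC1↓:LHY/CCA1↑                  -251.10         0.56
2    EC↓:TOC1↓                            -250.64         0.44
3    EC↓:LHY/CCA1↑                        -203.65         0.00
4    EC↓                                   -89.45         0.00
5    LHY/CCA1↑:TOC1↓                       -77.98         0.00
...
13   EC↑                                   -48.48         0.00
```

The three-connection model — LHY/CCA1 activation with TOC1 and EC
repression — ranks first: the EC term is needed for the sharp rise after
its repression releases in the afternoon, and the LHY and TOC1 terms
shape the peak and shut transcription down toward dusk. Architectures
without EC repression (ranks 5–13) cannot reproduce the waveform's
sharpness and are heavily penalised; the runner-up, EC↓:TOC1↓, differs
only in lacking the LHY link, and on synthetic data whose regimes share
one waveform it remains competitive (weight 0.44).

```python
run_experiments(config, table.best.fit)  # writes mutants.csv, gating_*.csv
```

For the top model this prints simulated knockout effects — *lhy cca1*
abolishes expression (fold 0.00, the activator is gone), *toc1* raises
peak mRNA 1.5-fold (de-repression partially buffered by the EC), *lux*
raises it 6.1-fold — and the gating profiles: a direct five-fold transcript
induction is maximal at ZT8 (induction 1.00, next largest 0.13), simply
tracking the ambient waveform, whereas routing the cold signal through
LHY/CCA1 produces a broader response shifted toward the morning (0.58 at
ZT4 vs 0.13 for direct). Only the clock-routed signal can move the gate
away from the expression peak.

The same analysis is available from a shell:

    cbf3select all --seed 1 --outdir results/run1

with subcommands `simulate-data`, `fit`, `select`, `mutants`, `gating`,
and a YAML/JSON config file for every setting (`--config`). Each run
writes a manifest with the config hash, derived stage seeds, and SHA-256
checksums of all outputs; re-running the same configuration is
bit-identical.

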