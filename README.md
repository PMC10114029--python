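# culturesim

An agent-based simulator of **cultural tool repertoires** in connected
populations, for researchers studying why a population's census size does —
or does not — predict the size of its cultural repertoire.

Human groups accumulate discrete cultural traits ("tools"). A long-standing
hypothesis holds that larger populations sustain larger tool repertoires,
yet empirical studies disagree. This package implements a minimal model in
which even *rare* cultural migration between groups decouples repertoire
size from census size: a population of 200 in contact with a larger
neighbour can carry the repertoire of a population several times its size,
while still keeping many tools that are unique to it.

## The model

Time is discrete. Each population holds a set of established tools
(presence/absence; within-population frequencies are abstracted away). Per
time step:

- **Innovation.** Each of the *N* individuals invents a new tool with
  probability *P*<sub>inv</sub>. The tool draws a selection coefficient
  *s* ~ Exp(*β*) (so E(*s*) = *β*, clamped to 1) and establishes with
  probability *s* — the classic approximation that an adaptive variant
  fixes with probability *s*.
- **Migration.** Each individual migrates with probability
  *P*<sub>mig</sub>, copying a fraction *f* of its population's repertoire
  (or a fixed number of tools) into the other population; each carried
  tool establishes there with its original *s*. Census sizes never change.
- **Loss.** Each established tool is forgotten with probability
  *P*<sub>loss</sub>/*N* (default), or *p*<sub>ind</sub><sup>*N*</sup>
  under the alternative independent-individuals loss model.

Balancing innovation and loss, an isolated population plateaus at

&nbsp;&nbsp;&nbsp;&nbsp;*x* = *P*<sub>inv</sub> · *β* · *N*² / *P*<sub>loss</sub>,

from the balance condition *P*<sub>inv</sub>·*β*·*N* =
*P*<sub>loss</sub>·*x*/*N*. Inverting it defines the **effective cultural
population size** *N*<sub>eff</sub> = √(*x* · *P*<sub>loss</sub> /
(*P*<sub>inv</sub> · *β*)): the census size whose isolated equilibrium
matches an observed repertoire. Defaults are *P*<sub>inv</sub> = 0.001,
*β* = 0.1, *P*<sub>loss</sub> = 0.1, *f* = 1, 200 000 steps with
equilibrium statistics averaged over steps 100 000–200 000 and unique-tool
counts sampled every 100 steps.

At very high connectivity the model exhibits **cultural rescue**: a tool
leaves a tightly coupled pair of populations only when both lose it almost
simultaneously — probability (*P*<sub>loss</sub>/*N*)², far below the
merged-population loss *P*<sub>loss</sub>/2*N* — so the pooled effective
size can exceed the sum of the census sizes.

## Worked example

Closed-form layer (no simulation):

```console
$ culturesim analytic --n 200
equilibrium repertoire (N=200): 40
$ culturesim analytic --x 135
effective population size (x=135): 367.423
$ culturesim analytic --n 200 --rescue
equilibrium repertoire (N=200): 40
merged 2N loss prob: 0.00025; simultaneous loss prob: 2.5e-07; ratio: 1000
```

An isolated population of 200 holds ~40 tools at equilibrium; a population
holding 135 tools has the repertoire of an isolated population of ~367;
and for N = 200 a merged population of 2N loses a tool 1000× more readily
than two coupled populations of N lose it simultaneously.

The highlighted two-population scenario (focal 200, neighbour 400,
per-individual migration 5×10⁻⁶) from the library:

```python
from culturesim import SimParams
from culturesim.experiments import run_unique_tools_experiment

out = run_unique_tools_experiment(params=SimParams(), replicates=10, base_seed=2025)
print(out["mean_repertoire"], out["mean_unique"])
```

At the full protocol this prints a focal mean repertoire of ≈ 134 tools
(up from the isolated 40), of which ≈ 55 are unique to the focal
population at any sampled instant — contact with a larger neighbour more
than triples the repertoire *and* increases cultural distinctiveness.

Other experiments are available as `culturesim sweep` (neighbour-size ×
migration-rate heat map), `rescue`, `curve` (sigmoid-like
connectivity–repertoire relationship), `timeline`, and `run` with a YAML
config (`--help` lists flags; `--reduced-scale` runs a 40 000-step
variant for quick exploration).

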