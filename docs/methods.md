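# Methods

## Model definition

The simulator tracks a metapopulation of discrete populations with fixed
census sizes. A population's culture is the *set* of tool identifiers
currently established in it; a tool is a record `(id, s, origin
population, invention step)` whose selection coefficient `s` is drawn once
at invention and never changes, including when the tool is later carried
elsewhere. Identifiers are globally unique and never reused, so shared and
unique tools remain countable across populations and through loss.

Each discrete time step applies, in fixed order:

1. **Innovation**, for every population in index order. The number of
   invention attempts is drawn `Binomial(N, P_inv)` — distributionally
   identical to a Bernoulli trial per individual, and O(1) per step. Each
   attempt draws `s = min(Exp(beta), 1)` and establishes the tool with
   probability `s`; failed inventions are discarded and never registered
   (the model gives unestablished tools no later role). Establishment
   stands in for within-population transmission: the fixation probability
   of an adaptive variant is approximately `s`, and an established tool is
   simply *present* thereafter, with no frequency dynamics.
2. **Migration.** Every population emits `Binomial(N, P_mig)` migrants;
   in the two-population case each migrant targets the other population
   (a pairwise matrix is supported for larger networks). A migrant copies
   a payload out of its source repertoire — each tool independently with
   probability `f` (so `f = 1`, the default, carries everything), or a
   uniform random subset of `payload_k` tools in the fixed-count variant —
   and each payload tool absent from the target establishes there with
   its stored `s`. Migration copies culture and never moves or removes
   it, and census sizes are constant.
3. **Loss**, for every population in index order. Each established tool
   is forgotten independently with probability `P_loss / N` (default
   `scaled` model) or `p_ind ** N` (`independent_individuals` model).
   Implemented as a binomial count followed by a uniform subset, which is
   exactly equivalent to per-tool Bernoulli trials by exchangeability;
   the test suite checks this against a naive per-individual, per-tool
   Bernoulli reference implementation.

The within-step ordering (innovate → migrate → lose) is not dictated by
the model's description; at the default rates ordering effects are far
below Monte-Carlo noise, but a fixed order is required for
reproducibility. A consequence worth noting: a tool invented in a step can
be carried, or lost, in that same step. Likewise, multiple migration
events in one step are processed sequentially in draw order with payloads
snapshotted at processing time; simultaneous events are vanishingly rare
at the studied rates.

All randomness flows through a single `numpy.random.Generator` owned by
the run and is consumed in the order above, so a run is bit-reproducible
from `(configuration, seed)`. Where a draw's outcome depends on set
iteration order (loss subsets, partial payloads), the candidate ids are
sorted first, removing any dependence on hash-table internals.

## Parameters

| Parameter | Default | Meaning |
| --- | --- | --- |
| `p_inv` | 0.001 | per-individual per-step innovation probability |
| `beta` | 0.1 | mean of the Exp selection-coefficient distribution |
| `p_loss` | 0.1 | loss constant; per-tool loss is `p_loss / N` |
| `p_mig` | 0 | per-individual per-step migration probability |
| `f` | 1 | fraction of the source repertoire per migrant |
| `payload_k` | – | payload size in the fixed-count variant |
| `p_ind` | – | per-individual retention failure (independent loss model) |
| `t_max` | 200 000 | simulated steps |
| window | [100 000, 200 000) | averaging window (inclusive start, exclusive end) |
| `unique_sample_every` | 100 | cadence of unique/overlap sampling in the window |

The rate defaults yield moderate repertoires at moderate census sizes
(equilibrium `1e-4 · N²` tools) and are of no empirical significance in
themselves; the qualitative behaviour is robust over a wide range.
Migration probabilities of 1e-6 to 1e-5 correspond to 0.0002–0.02
migration events per step for the population sizes studied — rare enough
that a tool's fate between contacts is governed by within-population
dynamics.

Clamping `s` at 1 matters only in the eighth decimal place of the mean
(`E[min(s,1)] = beta (1 - e^(-1/beta))`, within 5e-6 of `beta` at the
default), but it is required for `s` to be a probability; the clamp
probability `e^(-10) ≈ 4.5e-5` is verified in the tests.

## Analytics

`equilibrium_repertoire(N)` solves the innovation–loss balance
`P_inv·beta·N = P_loss·x/N`, and `effective_population_size(x)` is its
exact inverse `sqrt(x·P_loss/(P_inv·beta))`; their round trip is tested as
an identity over N = 1…5000. Under the independent-individuals loss model
the balance becomes `x = P_inv·beta·N / p_ind^N`, whose inverse has no
closed form and is obtained by bracketing plus Brent's method.

`summarize` averages per-step repertoire sizes over the window and the
sparser overlap samples (unique counts, pairwise shared counts, union
size, Jaccard) over the same window, then maps mean sizes to effective
sizes under the run's loss model. "Unique" means present in that
population and absent from every other at the sampling instant. The
pooled (metapopulation) effective size is computed from the mean *union*
repertoire — the natural metapopulation analogue when comparing against
the sum of census sizes. Degenerate case: the Jaccard index of two empty
repertoires is defined as 1 (identical sets); it arises only in zero-rate
configurations.

## The rescue comparison and the alternative loss model

Under scaled loss, a merged population of `2N` loses a tool with
probability `P_loss/2N` per step, while a tightly coupled pair of `N`-size
populations loses it only on near-simultaneous loss, probability
`(P_loss/N)²` — smaller by the factor `N/(2·P_loss)` (1000 at the
defaults). High migration therefore drives the pooled effective size
*above* the census sum ("cultural rescue"). The alternative model, in
which a tool is lost only when all `N` individuals independently fail to
retain it, makes population-level loss `p_ind^N`; a merged `2N` population
then loses at `p_ind^(2N) = (p_ind^N)²`, exactly the simultaneous-loss
probability of two independent `N` populations, so rescue vanishes and
the pooled effective size approaches the census sum from below.

For the head-to-head experiment `p_ind` defaults to
`(P_loss/n)^(1/n)` (0.9627 for n = 200), calibrated so a *single*
population of size `n` has identical per-tool loss under both models.
The two arms then share identical within-population dynamics and differ
only in the size→loss mapping used for effective-size accounting — which
is precisely the mechanism under test.

## The connectivity curve

Against `log10(P_mig)` the focal repertoire is sigmoid-like, with three
regimes the shape classifier detects:

* **flat low** — mean within 3 SE (or 5%) of the isolation equilibrium.
  This is the isolation-recovery condition: the expected waiting time
  between migration events, `1/(N·P_mig)`, far exceeds the repertoire's
  relaxation time `N/P_loss`, so the repertoire decays back to its
  isolated equilibrium between contacts.
* **rising** — some adjacent-grid-point gain exceeds 4 combined SE.
* **flat high** — *saturated sharing*: the focal population holds > 90%
  of the union repertoire and the per-decade relative gain has fallen
  below half its maximum.

The high end deserves a precise statement. Under the fraction payload the
absolute focal mean has no strict ceiling: the migration rate at which
sharing saturates coincides, after the algebra cancels, with the rate at
which cultural rescue begins inflating the union itself, so at the top of
the grid the repertoire keeps drifting upward even though nearly every
tool is already shared and each additional migrant contributes almost
nothing new. Saturation is therefore detected on the relative scale
(collapsing per-decade multiplicative gain plus near-complete sharing)
rather than as an absolute plateau — that is the model's actual
behaviour, and it is consistent with the rescue analysis above. The
default curve uses focal 200 / neighbour 400 over
`P_mig ∈ [1e-9, 1e-3]` (six decades), five replicates per point.

## Experiment protocols and problem sizes

All equilibrium statistics follow the full protocol: 200 000 steps,
window [100 000, 200 000), unique sampling every 100 steps. The headline
scenarios (isolated N = 200; focal 200 / neighbour 400 at
`P_mig = 5e-6`) use 10 replicate seeds and are run at this full scale in
both the test suite and `scripts/acceptance.py`.

The qualitative property experiments (heat-map monotonicity on a 3×3
grid, payload-variant comparison, f/P_mig interchangeability, rescue
sign test, connectivity curve) run at a reduced horizon — 40 000 steps
with window [20 000, 40 000) — which the package exposes as
`SimParams.reduced()`. The reduced window sits many relaxation times
(`N/P_loss`) past the start for every census size used, and the reduced
runs reproduce the full-scale equilibria within Monte-Carlo error for
isolated populations; for the strongly coupled high-migration cells the
union repertoire is still growing at 40 000 steps, so reduced-scale
values there are conservative (smaller) — the sign and ordering
properties tested are unaffected.

Replicate seeds derive from `SeedSequence([base_seed, cell, replicate])`,
so any single cell of any sweep can be re-run in isolation; Monte-Carlo
comparisons use replicate means at 3 standard errors with ≥ 10 replicates
unless a test documents otherwise.

For the payload-variant comparison the constant payload is 100 tools,
the order of the mid-range equilibrium repertoires spanned by the
neighbour grid (40–1000 tools). A much smaller payload suppresses the
neighbour-size channel by construction — migrants carry the same few
tools however much their source knows — which depresses the rank
correlation between the two surfaces without changing either surface's
monotonicity.

## What the simulations do and do not show

The generator *is* the study system: there is no external data, and every
reported number is a property of the model at the stated parameters. The
model abstracts away within-population transmission (establishment ≈
fixation with probability `s`), assumes tools are independent (no
combination, interdependence, or functional categories), treats loss as
purely stochastic (no environmental coupling between connected
populations, which would dampen cultural rescue), and holds census sizes
constant. Conclusions about real populations inherit those assumptions;
in particular the rescue effect depends qualitatively on the loss
mechanism, which is why both loss models are implemented and compared.

## Known limitations

* `n > 2` populations are supported structurally (migration matrix), but
  all shipped experiments and calibrations are two-population.
* With thinned recording (`record_every > 1`) the windowed mean
  repertoire averages only the recorded steps; overlap samples are taken
  independently of the thinning and are unaffected.
* The independent-individuals loss model has no principled default
  `p_ind`; it must be chosen per analysis (the rescue experiment's
  calibration is one defensible choice, not a universal one).
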