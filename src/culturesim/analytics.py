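"""Closed-form companion layer and trajectory summaries.

The simulator's stochastic equilibrium has a simple deterministic skeleton.
An isolated population of size ``N`` gains established tools at rate
``P_inv * beta * N`` per step (``N * P_inv`` inventions, each establishing
with expected probability ``E(s) = beta``) and loses each of its ``x``
tools with probability ``P_loss / N``, so the balance condition

    P_inv * beta * N = P_loss * x / N

gives the equilibrium repertoire ``x = P_inv * beta * N**2 / P_loss``.
Inverting that relation defines the *effective cultural population size*:
the census size at which an isolated population would be expected to hold
an observed repertoire.  Connectivity typically pushes a population's
effective size far above its census size, which is the model's central
phenomenon.

The same layer houses the cultural-rescue arithmetic (merged-population
loss ``P_loss / 2N`` versus simultaneous loss ``(P_loss / N)**2`` in two
separate populations) and the per-step migration-event expectation
``N * P_mig``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
from scipy.optimize import brentq

from .model_core import (
    LOSS_INDEPENDENT,
    ConfigurationError,
    SimParams,
    Trajectory,
)

__all__ = [
    "SummaryStats",
    "RescueComparison",
    "equilibrium_repertoire",
    "effective_population_size",
    "independent_loss_equilibrium",
    "independent_loss_effective_size",
    "expected_migration_events",
    "rescue_loss_comparison",
    "alternative_loss_prob",
    "summarize",
]


def equilibrium_repertoire(n: float, params: SimParams) -> float:
    """Expected equilibrium repertoire of an isolated population of size ``n``.

    Solves the innovation-loss balance ``P_inv * beta * N = P_loss * x / N``
    for ``x``; with the defaults (``P_inv = 0.001``, ``beta = 0.1``,
    ``P_loss = 0.1``) a population of 200 plateaus at 40 tools.
    """
    if n < 0:
        raise ConfigurationError(f"population size must be >= 0, got {n!r}")
    if params.p_loss <= 0:
        raise ConfigurationError(
            "no finite equilibrium repertoire when p_loss = 0"
        )
    return params.p_inv * params.beta * n * n / params.p_loss


def effective_population_size(x: float, params: SimParams) -> float:
    """Census size whose isolated equilibrium repertoire equals ``x``.

    Exact inverse of :func:`equilibrium_repertoire`:
    ``N_eff = sqrt(x * P_loss / (P_inv * beta))``.
    """
    if x < 0:
        raise ConfigurationError(f"repertoire size must be >= 0, got {x!r}")
    if params.p_inv <= 0:
        raise ConfigurationError("effective size undefined when p_inv = 0")
    return math.sqrt(x * params.p_loss / (params.p_inv * params.beta))


def independent_loss_equilibrium(n: float, params: SimParams) -> float:
    """Isolated equilibrium under the independent-individuals loss model.

    With per-tool loss probability ``p_ind ** N`` the balance condition
    becomes ``P_inv * beta * N = p_ind**N * x``, so
    ``x = P_inv * beta * N / p_ind**N`` — rising nearly exponentially in
    ``N`` because loss collapses once many individuals must all forget.
    """
    if params.p_ind is None:
        raise ConfigurationError("independent loss model requires p_ind")
    if params.p_ind <= 0:
        raise ConfigurationError("no finite equilibrium when p_ind = 0")
    return params.p_inv * params.beta * n / params.p_ind**n


def independent_loss_effective_size(x: float, params: SimParams) -> float:
    """Numeric inverse of :func:`independent_loss_equilibrium`.

    The map ``N -> P_inv * beta * N / p_ind**N`` is strictly increasing for
    ``p_ind < 1``, so the inverse is found by bracketing and Brent's
    method.
    """
    if x < 0:
        raise ConfigurationError(f"repertoire size must be >= 0, got {x!r}")
    if x == 0:
        return 0.0
    if params.p_ind is None:
        raise ConfigurationError("independent loss model requires p_ind")
    if params.p_ind >= 1.0:
        # Degenerate: loss prob 1 for every n; equilibrium x = P_inv*beta*n.
        return x / (params.p_inv * params.beta)

    def g(n: float) -> float:
        return independent_loss_equilibrium(n, params) - x

    hi = 1.0
    while g(hi) < 0:
        hi *= 2.0
        if hi > 1e12:  # pragma: no cover - unreachable for sane inputs
            raise ConfigurationError("failed to bracket effective size")
    return float(brentq(g, 0.0, hi, xtol=1e-9, rtol=1e-12))


def expected_migration_events(n: float, p_mig: float) -> float:
    """Expected migration events per step emitted by a population: ``N * P_mig``.

    At the experiment scales this spans 0.0002 (``N = 200``,
    ``P_mig = 1e-6``) to 0.02 (``N = 2000``, ``P_mig = 1e-5``) events per
    step — rare enough that the populations stay culturally distinct.
    """
    if n < 0:
        raise ConfigurationError(f"population size must be >= 0, got {n!r}")
    _ = SimParams(p_mig=p_mig)  # range check
    return n * p_mig


class RescueComparison(NamedTuple):
    """Loss probabilities behind the cultural-rescue effect."""

    merged_loss_prob: float
    simultaneous_loss_prob: float
    ratio: float


def rescue_loss_comparison(n: int, p_loss: float) -> RescueComparison:
    """Compare tool loss in one merged ``2N`` population with simultaneous
    loss in two separate ``N`` populations.

    Under the scaled loss model a merged population of ``2N`` loses a tool
    with probability ``P_loss / 2N`` per step, whereas two connected
    populations of ``N`` each only lose it from the pair when both lose it
    at once, probability ``(P_loss / N)**2``.  Whenever ``N >= 2 * P_loss``
    the merged probability is the larger one (ratio ``N / (2 * P_loss)``),
    which is why tightly coupled populations can exceed the pooled census
    size in effective cultural population size ("cultural rescue").
    """
    if n < 1:
        raise ConfigurationError(f"population size must be >= 1, got {n!r}")
    if not 0 < p_loss <= 1:
        raise ConfigurationError(f"p_loss must be in (0, 1], got {p_loss!r}")
    merged = p_loss / (2 * n)
    simultaneous = (p_loss / n) ** 2
    ratio = n / (2 * p_loss)
    assert (merged >= simultaneous) == (n >= 2 * p_loss)
    return RescueComparison(merged, simultaneous, ratio)


def alternative_loss_prob(n: int, p_ind: float) -> float:
    """Per-tool per-step loss probability when every individual must forget.

    If each of ``n`` individuals independently fails to retain a tool with
    probability ``p_ind``, the population loses it with probability
    ``p_ind ** n`` — exponentially decreasing in ``n``, unlike the default
    hyperbolic ``P_loss / n``.  Under this model highly connected
    populations approach, but do not exceed, the sum of their census sizes
    in effective cultural population size.
    """
    if n < 1:
        raise ConfigurationError(f"population size must be >= 1, got {n!r}")
    if not 0 <= p_ind <= 1:
        raise ConfigurationError(f"p_ind must be in [0, 1], got {p_ind!r}")
    return p_ind**n


@dataclass
class SummaryStats:
    """Windowed summary of a trajectory.

    Per-population arrays (index = population index):

    * ``mean_repertoire`` — time-averaged repertoire size over the window.
    * ``mean_sampled_repertoire`` — same average restricted to the sparser
      overlap-sampling instants (used for unique/overlap consistency).
    * ``mean_unique`` — time-averaged count of tools present in this
      population and absent from every other at the sampling instant.
    * ``n_eff`` — effective cultural population size implied by
      ``mean_repertoire`` under the run's loss model.

    Pair/metapopulation quantities:

    * ``jaccard`` — mean Jaccard index per population pair.
    * ``mean_shared`` — mean shared-tool count per pair.
    * ``mean_union`` / ``pooled_n_eff`` — mean size of the union repertoire
      and the effective size it implies for the metapopulation as a whole.
    """

    mean_repertoire: np.ndarray
    mean_sampled_repertoire: np.ndarray
    mean_unique: np.ndarray
    n_eff: np.ndarray
    pair_indices: list[tuple[int, int]]
    mean_shared: np.ndarray
    jaccard: np.ndarray
    mean_union: float
    pooled_n_eff: float


def _n_eff(x: float, params: SimParams) -> float:
    if params.loss_model == LOSS_INDEPENDENT:
        return independent_loss_effective_size(x, params)
    return effective_population_size(x, params)


def summarize(trajectory: Trajectory, params: SimParams | None = None) -> SummaryStats:
    """Compute windowed summary statistics for a finished run.

    ``mean_repertoire`` averages the per-step size record over
    ``[window_start, window_end)``; unique-tool and overlap statistics
    average the sparser samples taken every ``unique_sample_every`` steps
    inside the same window, matching the protocol used for all reported
    equilibrium numbers.
    """
    if params is None:
        params = trajectory.params
    w0, w1 = params.window_start, params.window_end
    times = trajectory.recorded_times
    mask = (times >= w0) & (times < w1)
    if not mask.any():
        raise ConfigurationError(
            f"trajectory has no recorded steps in window [{w0}, {w1})"
        )
    mean_rep = trajectory.sizes[mask].mean(axis=0)

    if trajectory.sample_times.size:
        mean_sampled = trajectory.sampled_sizes.mean(axis=0)
        mean_unique = trajectory.unique_counts.mean(axis=0)
        mean_shared = (
            trajectory.shared_counts.mean(axis=0)
            if trajectory.shared_counts.size
            else np.zeros(len(trajectory.pair_indices))
        )
        mean_union = float(trajectory.union_sizes.mean())
        jaccard = np.zeros(len(trajectory.pair_indices))
        for k, (i, j) in enumerate(trajectory.pair_indices):
            pair_union = (
                trajectory.sampled_sizes[:, i]
                + trajectory.sampled_sizes[:, j]
                - trajectory.shared_counts[:, k]
            ).astype(float)
            ratio = np.divide(
                trajectory.shared_counts[:, k],
                pair_union,
                out=np.ones_like(pair_union),  # two empty repertoires: J = 1
                where=pair_union > 0,
            )
            jaccard[k] = float(ratio.mean())
    else:
        npop = trajectory.n_populations
        mean_sampled = np.full(npop, np.nan)
        mean_unique = np.full(npop, np.nan)
        mean_shared = np.full(len(trajectory.pair_indices), np.nan)
        jaccard = np.full(len(trajectory.pair_indices), np.nan)
        mean_union = float("nan")

    n_eff = np.array([_n_eff(float(x), params) for x in mean_rep])
    pooled = (
        _n_eff(mean_union, params) if not math.isnan(mean_union) else float("nan")
    )
    return SummaryStats(
        mean_repertoire=mean_rep,
        mean_sampled_repertoire=mean_sampled,
        mean_unique=mean_unique,
        n_eff=n_eff,
        pair_indices=list(trajectory.pair_indices),
        mean_shared=mean_shared,
        jaccard=jaccard,
        mean_union=mean_union,
        pooled_n_eff=pooled,
    )
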