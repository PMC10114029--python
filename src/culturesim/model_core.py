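"""Within-population dynamics of cultural tool accumulation and loss.

The model tracks, for each population, the *set* of distinct tools currently
established in it.  Three stochastic processes act each discrete time step:

* **Innovation** — each of the ``N`` individuals invents a new tool with
  probability ``P_inv``.  Every invention is a brand-new tool carrying a
  selection coefficient ``s`` drawn from an exponential distribution with
  mean ``beta`` (clamped to 1, since ``s`` doubles as a probability).  The
  tool establishes in the population with probability ``s`` — a stand-in
  for the fixation probability of an adaptive variant — and is otherwise
  discarded.  Within-population transmission is abstracted away: an
  established tool is simply *present*.

* **Migration** — handled by :mod:`culturesim.migration`; migrants copy
  tools between populations without changing census sizes.

* **Loss** — each established tool is forgotten independently with
  per-step probability ``P_loss / N`` under the default (``scaled``) loss
  model, so larger populations retain tools longer.  An alternative
  ``independent_individuals`` model uses ``p_ind ** N`` instead (every
  individual must fail to retain the tool independently), which decreases
  exponentially rather than hyperbolically in ``N``.

Balancing innovation against loss, an isolated population plateaus at the
equilibrium repertoire size ``x = P_inv * beta * N**2 / P_loss`` (see
:mod:`culturesim.analytics`).

All randomness flows through a single :class:`numpy.random.Generator` owned
by the run; draws are consumed in a fixed, documented order (innovation for
each population in index order, then migration, then loss in index order),
so a run is bit-reproducible from ``(configuration, seed)``.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from typing import TYPE_CHECKING

import numpy as np

if TYPE_CHECKING:  # pragma: no cover - import cycle guard, typing only
    from .migration import MetaPopulation

__all__ = [
    "ConfigurationError",
    "LOSS_SCALED",
    "LOSS_INDEPENDENT",
    "PAYLOAD_FRACTION",
    "PAYLOAD_FIXED_COUNT",
    "Tool",
    "SimParams",
    "PopulationState",
    "ToolRegistry",
    "Trajectory",
    "draw_selection_coefficient",
    "innovate",
    "apply_loss",
    "step",
    "run",
]

logger = logging.getLogger(__name__)

LOSS_SCALED = "scaled"
LOSS_INDEPENDENT = "independent_individuals"
PAYLOAD_FRACTION = "fraction"
PAYLOAD_FIXED_COUNT = "fixed_count"


class ConfigurationError(ValueError):
    """Raised when simulation parameters are inconsistent or out of range."""


@dataclass(frozen=True)
class Tool:
    """A cultural trait with a fixed identity and selection coefficient.

    The selection coefficient ``s`` is drawn once, at invention, and is
    reused as the establishment probability wherever the tool arrives —
    including populations it reaches later by migration.  Identifiers are
    never reused, even after the tool is lost everywhere, so shared and
    unique tools remain recognisable across populations.
    """

    id: int
    s: float
    origin_pop: int
    t_invented: int


def _check_prob(name: str, value: float) -> None:
    if not 0.0 <= value <= 1.0:
        raise ConfigurationError(f"{name} must be in [0, 1], got {value!r}")


@dataclass(frozen=True)
class SimParams:
    """All model rates and protocol settings.

    Parameters
    ----------
    p_inv
        Per-individual per-step innovation probability.
    beta
        Mean of the exponential selection-coefficient distribution,
        ``E(s) = beta``.
    p_loss
        Loss-rate constant; the per-tool per-step loss probability is
        ``p_loss / N`` under the default ``scaled`` loss model.
    p_mig
        Per-individual per-step migration probability (used when the
        metapopulation does not carry its own migration matrix).
    f
        Fraction of the source repertoire a migrant carries (``fraction``
        payload mode).  ``f = 1`` copies the entire repertoire.
    payload_mode
        ``"fraction"`` (each tool included independently with probability
        ``f``) or ``"fixed_count"`` (a uniform random subset of
        ``payload_k`` tools).
    payload_k
        Payload size for ``fixed_count`` mode; truncated to the repertoire
        size when the source holds fewer tools.
    loss_model
        ``"scaled"`` (per-tool loss ``p_loss / N``) or
        ``"independent_individuals"`` (per-tool loss ``p_ind ** N``).
    p_ind
        Per-individual retention-failure probability; required by the
        ``independent_individuals`` loss model, ignored otherwise.
    t_max
        Number of time steps to simulate.
    window_start, window_end
        Averaging window for equilibrium statistics, interpreted as the
        half-open step range ``[window_start, window_end)``.
    unique_sample_every
        Cadence (in steps) at which unique-tool and overlap counts are
        sampled inside the averaging window.
    record_every
        Thinning of the per-step repertoire-size record (1 = every step).
    seed
        Seed for the run's random generator.
    """

    p_inv: float = 0.001
    beta: float = 0.1
    p_loss: float = 0.1
    p_mig: float = 0.0
    f: float = 1.0
    payload_mode: str = PAYLOAD_FRACTION
    payload_k: int = 0
    loss_model: str = LOSS_SCALED
    p_ind: float | None = None
    t_max: int = 200_000
    window_start: int = 100_000
    window_end: int = 200_000
    unique_sample_every: int = 100
    record_every: int = 1
    seed: int | None = None

    def __post_init__(self) -> None:
        _check_prob("p_inv", self.p_inv)
        _check_prob("p_loss", self.p_loss)
        _check_prob("p_mig", self.p_mig)
        _check_prob("f", self.f)
        if self.beta <= 0:
            raise ConfigurationError(f"beta must be > 0, got {self.beta!r}")
        if self.payload_mode not in (PAYLOAD_FRACTION, PAYLOAD_FIXED_COUNT):
            raise ConfigurationError(f"unknown payload_mode {self.payload_mode!r}")
        if self.payload_k < 0:
            raise ConfigurationError(f"payload_k must be >= 0, got {self.payload_k!r}")
        if self.loss_model not in (LOSS_SCALED, LOSS_INDEPENDENT):
            raise ConfigurationError(f"unknown loss_model {self.loss_model!r}")
        if self.loss_model == LOSS_INDEPENDENT:
            if self.p_ind is None:
                raise ConfigurationError(
                    "loss_model 'independent_individuals' requires p_ind"
                )
            _check_prob("p_ind", self.p_ind)
        if self.t_max < 0:
            raise ConfigurationError(f"t_max must be >= 0, got {self.t_max!r}")
        if self.t_max > 0 and not (
            0 <= self.window_start < self.window_end <= self.t_max
        ):
            raise ConfigurationError(
                "averaging window must satisfy "
                f"0 <= window_start < window_end <= t_max, got "
                f"[{self.window_start}, {self.window_end}) with t_max={self.t_max}"
            )
        if self.unique_sample_every < 1:
            raise ConfigurationError("unique_sample_every must be >= 1")
        if self.record_every < 1:
            raise ConfigurationError("record_every must be >= 1")

    def replace(self, **changes) -> "SimParams":
        """Return a copy with the given fields replaced (re-validated)."""
        return dataclasses.replace(self, **changes)

    def reduced(self, t_max: int = 40_000) -> "SimParams":
        """Return a reduced-horizon copy with the window in the second half.

        Used for quick exploratory runs; the default full horizon keeps
        ``t_max = 200_000`` with the window ``[100_000, 200_000)``.
        """
        return self.replace(
            t_max=t_max, window_start=t_max // 2, window_end=t_max
        )

    def per_tool_loss_prob(self, n: int) -> float:
        """Per-tool per-step loss probability in a population of size ``n``."""
        if self.loss_model == LOSS_SCALED:
            p = self.p_loss / n
            if p > 1.0:
                raise ConfigurationError(
                    f"p_loss / n = {p!r} exceeds 1 for n={n}"
                )
            return p
        assert self.p_ind is not None
        return self.p_ind**n


@dataclass
class PopulationState:
    """Census size and current repertoire of one population.

    The census size ``n`` is constant through time: migration copies
    culture, not people.  The repertoire is a set of tool ids — presence or
    absence only, with no within-population frequencies.
    """

    index: int
    n: int
    repertoire: set[int] = field(default_factory=set)

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ConfigurationError(f"population size must be >= 1, got {self.n!r}")

    @property
    def repertoire_size(self) -> int:
        return len(self.repertoire)


class ToolRegistry:
    """Append-only store of every tool ever established anywhere.

    Ids are consecutive integers assigned at registration and never reused,
    so a tool lost from every population and later re-encountered (e.g. in
    a recorded migration payload) is still resolvable.  Selection
    coefficients are kept in a flat array for vectorised lookup during
    migration.
    """

    def __init__(self, capacity: int = 1024) -> None:
        self._s = np.empty(capacity, dtype=np.float64)
        self._origin = np.empty(capacity, dtype=np.int64)
        self._t = np.empty(capacity, dtype=np.int64)
        self._count = 0

    def __len__(self) -> int:
        return self._count

    def __contains__(self, tool_id: int) -> bool:
        return 0 <= tool_id < self._count

    def _grow(self) -> None:
        new_cap = max(2 * self._s.size, 1024)
        for name in ("_s", "_origin", "_t"):
            arr = getattr(self, name)
            bigger = np.empty(new_cap, dtype=arr.dtype)
            bigger[: self._count] = arr[: self._count]
            setattr(self, name, bigger)

    def register(self, s: float, origin_pop: int, t_invented: int) -> int:
        """Record a newly established tool; returns its fresh id."""
        if self._count == self._s.size:
            self._grow()
        tool_id = self._count
        self._s[tool_id] = s
        self._origin[tool_id] = origin_pop
        self._t[tool_id] = t_invented
        self._count += 1
        return tool_id

    def get(self, tool_id: int) -> Tool:
        if tool_id not in self:
            raise KeyError(f"unknown tool id {tool_id!r}")
        return Tool(
            id=tool_id,
            s=float(self._s[tool_id]),
            origin_pop=int(self._origin[tool_id]),
            t_invented=int(self._t[tool_id]),
        )

    def s_of(self, ids: np.ndarray) -> np.ndarray:
        """Vectorised selection-coefficient lookup for an id array."""
        ids = np.asarray(ids, dtype=np.int64)
        if ids.size and (ids.min() < 0 or ids.max() >= self._count):
            raise KeyError("payload references unknown tool ids")
        return self._s[ids]


def draw_selection_coefficient(params: SimParams, rng: np.random.Generator) -> float:
    """Draw a tool's selection coefficient: ``min(Exp(beta), 1)``.

    The raw draw has mean ``beta``; because ``s`` is reused as an
    establishment probability it is clamped to at most 1.  With the default
    ``beta = 0.1`` the clamp fires with probability ``exp(-10)``, so the
    mean of the clamped draw, ``beta * (1 - exp(-1/beta))``, is within
    5e-6 of ``beta``.
    """
    return min(float(rng.exponential(params.beta)), 1.0)


def innovate(
    pop: PopulationState,
    params: SimParams,
    registry: ToolRegistry,
    t: int,
    rng: np.random.Generator,
) -> list[int]:
    """One step of invention in ``pop``; returns ids of newly established tools.

    The number of invention attempts is drawn ``Binomial(n, p_inv)`` —
    distributionally identical to a per-individual Bernoulli loop.  Each
    attempt creates a fresh tool that establishes with probability equal to
    its selection coefficient; failed inventions are discarded and never
    registered (the model gives them no later role).
    """
    if params.p_inv == 0.0:
        return []
    attempts = int(rng.binomial(pop.n, params.p_inv))
    established: list[int] = []
    for _ in range(attempts):
        s = draw_selection_coefficient(params, rng)
        if rng.random() < s:
            tool_id = registry.register(s, pop.index, t)
            pop.repertoire.add(tool_id)
            established.append(tool_id)
    return established


def apply_loss(
    pop: PopulationState, params: SimParams, rng: np.random.Generator
) -> list[int]:
    """One step of stochastic loss in ``pop``; returns the removed tool ids.

    Each tool currently in the repertoire is removed independently with the
    per-tool probability given by the loss model (``p_loss / n`` by
    default).  Implemented as a binomial draw of the number of losses
    followed by a uniform subset — exactly equivalent to independent
    per-tool Bernoulli trials, by exchangeability.  Loss in one population
    never touches another population's repertoire.
    """
    x = len(pop.repertoire)
    if x == 0:
        return []
    p = params.per_tool_loss_prob(pop.n)
    if p == 0.0:
        return []
    k = int(rng.binomial(x, p))
    if k == 0:
        return []
    # Sort for platform-independent draw order; set iteration order is an
    # implementation detail we do not rely on.
    pool = sorted(pop.repertoire)
    idx = rng.choice(x, size=k, replace=False)
    removed = [pool[i] for i in idx]
    pop.repertoire.difference_update(removed)
    return removed


def step(
    meta: "MetaPopulation",
    params: SimParams,
    registry: ToolRegistry,
    t: int,
    rng: np.random.Generator,
) -> "MetaPopulation":
    """Advance the metapopulation by one time step, in place.

    Fixed sub-step order: innovation in every population (index order),
    then migration events, then loss in every population (index order).
    At the model's default rates the ordering is far below Monte-Carlo
    noise, but fixing it makes runs reproducible.  Note the order permits a
    tool invented this step to be carried or lost in the same step.
    """
    for pop in meta.populations:
        innovate(pop, params, registry, t, rng)
    _migration.perform_migration(meta, params, registry, rng)
    for pop in meta.populations:
        apply_loss(pop, params, rng)
    return meta


@dataclass
class Trajectory:
    """Recorded output of a run: sizes per step plus windowed overlap samples.

    ``sizes[r, i]`` is the repertoire size of population ``i`` after
    completing step ``recorded_times[r]``.  Inside the averaging window,
    every ``unique_sample_every`` steps the per-population unique-tool
    counts, pairwise shared counts, and the size of the union repertoire
    are sampled (``sample_times`` gives the step of each sample).
    """

    params: SimParams
    pop_sizes: list[int]
    recorded_times: np.ndarray
    sizes: np.ndarray
    sample_times: np.ndarray
    sampled_sizes: np.ndarray
    unique_counts: np.ndarray
    pair_indices: list[tuple[int, int]]
    shared_counts: np.ndarray
    union_sizes: np.ndarray
    registry: ToolRegistry
    final_repertoires: list[set[int]]

    @property
    def n_populations(self) -> int:
        return len(self.pop_sizes)


def _overlap_sample(populations: list[PopulationState]):
    reps = [pop.repertoire for pop in populations]
    npop = len(reps)
    union: set[int] = set().union(*reps) if reps else set()
    uniques = []
    for i, rep in enumerate(reps):
        others: set[int] = set()
        for j, other in enumerate(reps):
            if j != i:
                others |= other
        uniques.append(len(rep - others))
    shared = [len(reps[i] & reps[j]) for i in range(npop) for j in range(i + 1, npop)]
    return uniques, shared, len(union)


def run(
    meta: "MetaPopulation",
    params: SimParams,
    registry: ToolRegistry | None = None,
    rng: np.random.Generator | None = None,
) -> Trajectory:
    """Simulate ``params.t_max`` steps and return the recorded trajectory.

    A fresh registry and a generator seeded with ``params.seed`` are created
    unless supplied, so two calls with identical ``(meta sizes, params)``
    produce bit-identical trajectories.
    """
    if rng is None:
        rng = np.random.default_rng(params.seed)
    if registry is None:
        registry = ToolRegistry()

    populations = meta.populations
    npop = len(populations)
    pop_sizes = [pop.n for pop in populations]
    pair_indices = [(i, j) for i in range(npop) for j in range(i + 1, npop)]

    recorded_times = np.arange(0, params.t_max, params.record_every, dtype=np.int64)
    sizes = np.zeros((recorded_times.size, npop), dtype=np.int64)

    sample_times_list: list[int] = []
    sampled_sizes_list: list[list[int]] = []
    uniques_list: list[list[int]] = []
    shared_list: list[list[int]] = []
    union_list: list[int] = []

    progress = logger.isEnabledFor(logging.INFO)
    record_every = params.record_every
    every = params.unique_sample_every
    w0, w1 = params.window_start, params.window_end
    rec_row = 0
    for t in range(params.t_max):
        step(meta, params, registry, t, rng)
        if t % record_every == 0:
            for i, pop in enumerate(populations):
                sizes[rec_row, i] = len(pop.repertoire)
            rec_row += 1
        if w0 <= t < w1 and t % every == 0:
            uniques, shared, union = _overlap_sample(populations)
            sample_times_list.append(t)
            sampled_sizes_list.append([len(p.repertoire) for p in populations])
            uniques_list.append(uniques)
            shared_list.append(shared)
            union_list.append(union)
        if progress and t > 0 and t % 10_000 == 0:
            logger.info(
                "step %d/%d sizes=%s tools=%d",
                t,
                params.t_max,
                [len(p.repertoire) for p in populations],
                len(registry),
            )

    sample_times = np.asarray(sample_times_list, dtype=np.int64)
    sampled_sizes = np.asarray(sampled_sizes_list, dtype=np.int64).reshape(-1, npop)

    return Trajectory(
        params=params,
        pop_sizes=pop_sizes,
        recorded_times=recorded_times,
        sizes=sizes,
        sample_times=sample_times,
        sampled_sizes=sampled_sizes,
        unique_counts=np.asarray(uniques_list, dtype=np.int64).reshape(
            (sample_times.size, npop)
        ),
        pair_indices=pair_indices,
        shared_counts=np.asarray(shared_list, dtype=np.int64).reshape(
            (sample_times.size, len(pair_indices))
        ),
        union_sizes=np.asarray(union_list, dtype=np.int64),
        registry=registry,
        final_repertoires=[set(pop.repertoire) for pop in populations],
    )


# Imported at module bottom to break the type-level cycle with .migration,
# which needs the domain classes above at its own import time.
from . import migration as _migration  # noqa: E402
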