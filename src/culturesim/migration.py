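"""Inter-population cultural migration.

Migration is cultural, not demographic: a migrating individual *copies*
tools from its native population into the target population, and census
sizes never change.  Each step, every population emits
``Binomial(N, P_mig)`` migrants.  A migrant carries a payload — by default
an independent fraction ``f`` of the source repertoire (``f = 1`` carries
everything), or alternatively a uniform random subset of fixed size — and
each payload tool not already present in the target establishes there with
the same selection coefficient ``s`` that was drawn when the tool was
invented.  Tool identity is preserved across populations, so shared and
unique tools remain countable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model_core import (
    PAYLOAD_FRACTION,
    ConfigurationError,
    PopulationState,
    SimParams,
    ToolRegistry,
)

__all__ = [
    "MetaPopulation",
    "MigrationEvent",
    "draw_migration_events",
    "select_payload",
    "transfer",
    "perform_migration",
]


@dataclass
class MetaPopulation:
    """An ordered collection of populations and their connectivity.

    ``migration_prob`` may be ``None`` (fall back to the scalar
    ``SimParams.p_mig``, applied symmetrically), a scalar (per-individual
    emigration probability; the target is the other population in the
    two-population case, uniform among the others for larger networks), or
    a full pairwise matrix whose entry ``[i, j]`` is the per-individual
    probability of migrating from population ``i`` to ``j``.
    """

    populations: list[PopulationState]
    migration_prob: float | np.ndarray | None = None

    def __post_init__(self) -> None:
        indices = [pop.index for pop in self.populations]
        if indices != list(range(len(self.populations))):
            raise ConfigurationError(
                "population indices must be 0..n-1 in list order"
            )
        if isinstance(self.migration_prob, np.ndarray):
            m = self.migration_prob
            n = len(self.populations)
            if m.shape != (n, n):
                raise ConfigurationError(
                    f"migration matrix must be {n}x{n}, got {m.shape}"
                )
            if (m < 0).any() or (m > 1).any():
                raise ConfigurationError("migration matrix entries must be in [0, 1]")
            if np.diag(m).any():
                raise ConfigurationError("self-migration (diagonal) must be zero")
        elif self.migration_prob is not None and not (
            0.0 <= float(self.migration_prob) <= 1.0
        ):
            raise ConfigurationError("migration_prob must be in [0, 1]")

    @classmethod
    def isolated(cls, n: int) -> "MetaPopulation":
        """A single population with no neighbours."""
        return cls(populations=[PopulationState(index=0, n=n)])

    @classmethod
    def two_populations(
        cls,
        n_focal: int,
        n_neighbour: int,
        migration_prob: float | None = None,
    ) -> "MetaPopulation":
        """The focal/neighbour pair used throughout the experiments."""
        return cls(
            populations=[
                PopulationState(index=0, n=n_focal),
                PopulationState(index=1, n=n_neighbour),
            ],
            migration_prob=migration_prob,
        )

    @classmethod
    def from_sizes(
        cls, sizes: list[int], migration_prob: float | np.ndarray | None = None
    ) -> "MetaPopulation":
        return cls(
            populations=[
                PopulationState(index=i, n=n) for i, n in enumerate(sizes)
            ],
            migration_prob=migration_prob,
        )


@dataclass(frozen=True)
class MigrationEvent:
    """One migrant's crossing: what was carried and what took hold."""

    source: int
    target: int
    payload: frozenset[int]
    established: frozenset[int]


def draw_migration_events(
    meta: MetaPopulation, params: SimParams, rng: np.random.Generator
) -> list[tuple[int, int]]:
    """Draw this step's migration events as ``(source, target)`` pairs.

    Each population's emigrant count is ``Binomial(N, P_mig)``; emigrant
    counts of different populations are independent.  With a migration
    matrix, the emigrant count uses the row total and each emigrant's
    target is drawn from the row-normalised probabilities.
    """
    npop = len(meta.populations)
    if npop < 2:
        return []
    events: list[tuple[int, int]] = []
    prob = meta.migration_prob
    if prob is None:
        prob = params.p_mig
    if isinstance(prob, np.ndarray):
        for i, pop in enumerate(meta.populations):
            row = prob[i]
            total = float(row.sum())
            if total == 0.0:
                continue
            m = int(rng.binomial(pop.n, total))
            if m == 0:
                continue
            targets = rng.choice(npop, size=m, p=row / total)
            events.extend((i, int(j)) for j in targets)
    else:
        p = float(prob)
        if p == 0.0:
            return []
        others = {i: [j for j in range(npop) if j != i] for i in range(npop)}
        for i, pop in enumerate(meta.populations):
            m = int(rng.binomial(pop.n, p))
            cand = others[i]
            for _ in range(m):
                tgt = cand[0] if len(cand) == 1 else cand[int(rng.integers(len(cand)))]
                events.append((i, tgt))
    return events


def select_payload(
    source: PopulationState, params: SimParams, rng: np.random.Generator
) -> set[int]:
    """Choose the tool ids one migrant carries out of ``source``.

    Fraction mode includes each tool independently with probability ``f``
    (``f = 1`` deterministically carries the whole repertoire, the default
    setting); fixed-count mode draws a uniform subset of ``payload_k``
    tools without replacement, truncated to the repertoire size.
    """
    x = len(source.repertoire)
    if x == 0:
        return set()
    if params.payload_mode == PAYLOAD_FRACTION:
        if params.f >= 1.0:
            return set(source.repertoire)
        if params.f <= 0.0:
            return set()
        pool = sorted(source.repertoire)
        mask = rng.random(x) < params.f
        return {pool[i] for i in np.nonzero(mask)[0]}
    # fixed_count
    k = min(params.payload_k, x)
    if k == 0:
        return set()
    if k == x:
        return set(source.repertoire)
    pool = sorted(source.repertoire)
    idx = rng.choice(x, size=k, replace=False)
    return {pool[i] for i in idx}


def transfer(
    payload: set[int],
    target: PopulationState,
    registry: ToolRegistry,
    rng: np.random.Generator,
) -> set[int]:
    """Attempt establishment of payload tools in ``target``; returns new ids.

    Tools already present in the target are no-ops.  Every other payload
    tool gets one Bernoulli trial with success probability equal to its
    stored selection coefficient — the very same ``s`` drawn at invention.
    The source repertoire is never modified: migration copies, it does not
    move.
    """
    new = payload - target.repertoire
    if not new:
        return set()
    ids = np.fromiter(new, dtype=np.int64, count=len(new))
    ids.sort()  # fixed draw order regardless of set iteration order
    s = registry.s_of(ids)
    established = ids[rng.random(ids.size) < s]
    out = {int(i) for i in established}
    target.repertoire |= out
    return out


def perform_migration(
    meta: MetaPopulation,
    params: SimParams,
    registry: ToolRegistry,
    rng: np.random.Generator,
) -> list[MigrationEvent]:
    """Draw and execute all of this step's migration events, in draw order.

    Payloads are snapshots of the source repertoire at processing time, so
    an earlier event in the same step can enlarge a later event's payload.
    At the model's default rates simultaneous events are vanishingly rare;
    the sequential order exists for reproducibility, not realism.
    """
    events = draw_migration_events(meta, params, rng)
    records: list[MigrationEvent] = []
    for src, dst in events:
        payload = select_payload(meta.populations[src], params, rng)
        established = transfer(payload, meta.populations[dst], registry, rng)
        records.append(
            MigrationEvent(
                source=src,
                target=dst,
                payload=frozenset(payload),
                established=frozenset(established),
            )
        )
    return records
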