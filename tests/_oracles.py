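"""Shared independent reference implementations for cross-checking tests."""

import math

import numpy as np
from scipy import stats as sps

from culturesim import MetaPopulation, SimParams, run


def naive_isolated_run(n: int, params: SimParams, t_max: int, seed: int):
    """Reference dynamics: explicit Bernoulli loop over every individual
    (invention) and every tool (loss), one draw each, no binomial
    shortcuts."""
    rng = np.random.default_rng(seed)
    repertoire: dict[int, float] = {}
    next_id = 0
    p_tool_loss = params.p_loss / n
    sizes = []
    for _ in range(t_max):
        for _ in range(n):
            if rng.random() < params.p_inv:
                s = min(rng.exponential(params.beta), 1.0)
                if rng.random() < s:
                    repertoire[next_id] = s
                next_id += 1
        for tool_id in list(repertoire):
            if rng.random() < p_tool_loss:
                del repertoire[tool_id]
        sizes.append(len(repertoire))
    return sizes


def check_naive_oracle_agreement(reps: int = 3000) -> None:
    """Final-repertoire-size distributions of the production simulator and
    the naive loop agree for N = 5 over 50 steps.

    Rates are elevated (P_inv = 0.05, beta = 0.3, P_loss = 0.5) so the
    50-step distribution has real mass away from zero; agreement is a
    two-sample chi-squared test on the size counts plus a 3-SE mean
    comparison.
    """
    n, t_max = 5, 50
    params = SimParams(p_inv=0.05, beta=0.3, p_loss=0.5, t_max=0)
    naive_final = np.array(
        [naive_isolated_run(n, params, t_max, seed=10_000 + r)[-1] for r in range(reps)]
    )
    run_params = params.replace(
        t_max=t_max, window_start=0, window_end=t_max, unique_sample_every=t_max
    )
    production_final = np.array(
        [
            run(MetaPopulation.isolated(n), run_params.replace(seed=20_000 + r)).sizes[
                -1, 0
            ]
            for r in range(reps)
        ]
    )

    hi = int(max(naive_final.max(), production_final.max()))
    bins = np.arange(hi + 2)
    counts = np.vstack(
        [np.histogram(x, bins=bins)[0] for x in (naive_final, production_final)]
    )
    keep = counts.sum(axis=0) >= 10  # merge the sparse tail for a valid chi2
    columns = [counts[:, keep]]
    if (~keep).any():
        columns.append(counts[:, ~keep].sum(axis=1)[:, None])
    table = np.hstack(columns)
    _, p_value, _, _ = sps.chi2_contingency(table)
    assert p_value > 1e-3

    se = math.sqrt(
        naive_final.var(ddof=1) / reps + production_final.var(ddof=1) / reps
    )
    assert abs(naive_final.mean() - production_final.mean()) < 3 * se
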