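"""Metropolis–Hastings sampling from the two-layer ERGM.

The chain proposes a uniformly random tie variable — one of the 2n(n-1)
ordered (layer, i, j) slots — and toggles it with probability
min(1, exp(θ·Δz)), which leaves P(X=x) ∝ exp(θ·z(x)) stationary. Statistics
are maintained incrementally from change statistics; the compiled kernels in
:mod:`dissonet._kernels` do the per-proposal work.

All randomness flows through explicit integer seeds; no global RNG state is
used. Long segments of the chain are seeded from a `numpy` SeedSequence
spawned off the caller's seed, so runs are reproducible end to end.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

from . import _kernels
from .effects import ModelSpec, change_statistics, statistics
from .network import ActorTable, TwoLayerDigraph, n_tie_variables

__all__ = ["SamplerSettings", "SampleBatch", "mh_step", "simulate", "DegeneracyWarning"]

logger = logging.getLogger(__name__)

DENSITY_DEGENERACY_THRESHOLD = 0.95
ACCEPTANCE_DEGENERACY_THRESHOLD = 1e-3


class DegeneracyWarning(UserWarning):
    """The chain drifted to a near-complete graph or near-frozen state."""


@dataclass(frozen=True)
class SamplerSettings:
    """Chain schedule. Defaults scale with the number of tie variables:
    burn-in 50·2n(n-1) proposals, thinning 2n(n-1) proposals per retained
    sample."""

    burn_in: int | None = None
    thinning: int | None = None
    n_samples: int = 100
    seed: int = 0
    initial_state: str | TwoLayerDigraph = "empty"
    return_graphs: bool = False

    def __post_init__(self):
        if self.burn_in is not None and self.burn_in < 0:
            raise ValueError("burn_in must be >= 0")
        if self.thinning is not None and self.thinning < 1:
            raise ValueError("thinning must be >= 1")
        if self.n_samples < 1:
            raise ValueError("n_samples must be >= 1")

    def resolved(self, n: int) -> tuple[int, int]:
        nt = n_tie_variables(n)
        burn = self.burn_in if self.burn_in is not None else 50 * nt
        thin = self.thinning if self.thinning is not None else nt
        return burn, thin


@dataclass(frozen=True)
class SampleBatch:
    """Retained statistic vectors (rows) and chain diagnostics."""

    statistics: np.ndarray
    acceptance_rate: float
    labels: tuple[str, ...]
    graphs: tuple[TwoLayerDigraph, ...] | None = None
    final_state: TwoLayerDigraph | None = None

    @property
    def n_samples(self) -> int:
        return self.statistics.shape[0]

    def mean(self) -> np.ndarray:
        return self.statistics.mean(axis=0)

    def sd(self) -> np.ndarray:
        return self.statistics.std(axis=0, ddof=1)

    def cov(self) -> np.ndarray:
        return np.cov(self.statistics, rowvar=False, ddof=1).reshape(
            self.statistics.shape[1], self.statistics.shape[1]
        )

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(self.statistics, columns=list(self.labels))


def _check_theta(theta: np.ndarray, spec: ModelSpec) -> np.ndarray:
    theta = np.asarray(theta, dtype=float)
    if theta.shape != (len(spec),):
        raise ValueError(f"theta has {theta.shape} entries; model has {len(spec)} effects")
    if not np.isfinite(theta).all():
        raise ValueError("theta must be finite")
    return theta


def mh_step(
    state: TwoLayerDigraph,
    theta: np.ndarray,
    spec: ModelSpec,
    attrs: ActorTable | None,
    rng: np.random.Generator,
) -> TwoLayerDigraph:
    """One Metropolis proposal, mutating the state's adjacency in place.

    Exposed for inspection and teaching; bulk simulation goes through
    :func:`simulate`, which runs the same proposal in compiled code.
    """
    theta = _check_theta(theta, spec)
    n = state.n
    layer = "F" if rng.integers(2) == 0 else "D"
    i = int(rng.integers(n))
    j = int(rng.integers(n - 1))
    if j >= i:
        j += 1
    delta = change_statistics(state, attrs, spec, i, j, layer)
    X = state.layer(layer)
    present = X[i, j] == 1
    log_ratio = float(theta @ delta)
    if present:
        log_ratio = -log_ratio
    if log_ratio >= 0 or rng.random() < np.exp(log_ratio):
        X[i, j] = 0 if present else 1
    return state


def _initial_graph(settings: SamplerSettings, n_actors: int) -> TwoLayerDigraph:
    init = settings.initial_state
    if isinstance(init, TwoLayerDigraph):
        if init.n != n_actors:
            raise ValueError("initial graph size does not match n_actors")
        return TwoLayerDigraph(F=init.F.copy(), D=init.D.copy(), actor_ids=init.actor_ids)
    if init == "empty":
        z = np.zeros((n_actors, n_actors), dtype=np.uint8)
        return TwoLayerDigraph(F=z, D=z.copy())
    raise ValueError(f"initial_state must be 'empty' or a graph, got {init!r}")


def simulate(
    theta: np.ndarray,
    spec: ModelSpec,
    attrs: ActorTable | None,
    n_actors: int,
    settings: SamplerSettings,
) -> SampleBatch:
    """Draw a batch of graphs (their statistic vectors) from the model at θ.

    Reproducible for a fixed seed; statistics are maintained incrementally
    and never recomputed from scratch after initialisation.
    """
    if n_actors < 2:
        raise ValueError("n_actors must be >= 2")
    theta = _check_theta(theta, spec)
    burn, thin = settings.resolved(n_actors)
    state = _initial_graph(settings, n_actors)
    F = state.F.astype(np.float64)
    D = state.D.astype(np.float64)
    kinds, layers, attr_idx, lams, A = spec.encode(attrs, n_actors)
    z = statistics(state, attrs, spec)
    seeds = np.random.SeedSequence(settings.seed).generate_state(
        settings.n_samples + 1, dtype=np.uint32
    ) % np.uint32(2**31)

    total = 0
    accepted = 0
    if burn > 0:
        accepted += _kernels.advance_chain(
            F, D, A, kinds, layers, attr_idx, lams, theta, z, burn, int(seeds[0])
        )
        total += burn
    out = np.empty((settings.n_samples, len(spec)), dtype=float)
    graphs: list[TwoLayerDigraph] | None = [] if settings.return_graphs else None
    for s in range(settings.n_samples):
        accepted += _kernels.advance_chain(
            F, D, A, kinds, layers, attr_idx, lams, theta, z, thin, int(seeds[s + 1])
        )
        total += thin
        out[s] = z
        if graphs is not None:
            graphs.append(
                TwoLayerDigraph(
                    F=F.astype(np.uint8), D=D.astype(np.uint8), actor_ids=state.actor_ids
                )
            )
    rate = accepted / total if total else 1.0
    final = TwoLayerDigraph(
        F=F.astype(np.uint8), D=D.astype(np.uint8), actor_ids=state.actor_ids
    )
    _degeneracy_guard(final, rate)
    return SampleBatch(
        statistics=out,
        acceptance_rate=rate,
        labels=tuple(spec.labels),
        graphs=tuple(graphs) if graphs is not None else None,
        final_state=final,
    )


def _degeneracy_guard(state: TwoLayerDigraph, acceptance_rate: float) -> None:
    n = state.n
    for name in ("F", "D"):
        dens = state.layer(name).sum() / (n * (n - 1))
        if dens > DENSITY_DEGENERACY_THRESHOLD:
            msg = f"near-degenerate chain: layer {name} density {dens:.3f}"
            logger.warning(msg)
            warnings.warn(msg, DegeneracyWarning, stacklevel=3)
    if acceptance_rate < ACCEPTANCE_DEGENERACY_THRESHOLD:
        msg = f"near-frozen chain: acceptance rate {acceptance_rate:.2e}"
        logger.warning(msg)
        warnings.warn(msg, DegeneracyWarning, stacklevel=3)
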