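"""Method-of-moments MCMC maximum-likelihood estimation (Robbins–Monro).

For an exponential-family network model the MLE solves the moment equation
E_θ[z(X)] = z(x_obs). The estimator approximates this root stochastically in
three phases, the standard stochastic-approximation scheme of the
PNet/SIENA software family:

phase 1
    A short simulation at θ₀ estimates the derivative matrix D ≈ cov(z)
    (the score–information identity for exponential families), used as a
    preconditioner.
phase 2
    Subphases of Robbins–Monro iterations θ ← θ − a·D⁻¹(z(X_t) − z_obs)
    against a persistently evolving chain, with the gain a halved between
    subphases; the estimate is the average of θ over the final subphase.
phase 3
    A long simulation at the final θ̂ yields convergence t-ratios
    t_A = (mean_sim z_A − z_obs,A)/sd_sim z_A, the simulated-statistic
    covariance Σ̂, and standard errors sqrt(diag(Σ̂⁻¹)).

A fit whose largest |t-ratio| is below 0.1 is declared converged — the
conventional threshold for this estimator family. Non-convergence triggers
phase-2 restarts from the current estimate up to ``max_retries`` and is then
reported with a failure flag, never silently.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .effects import ATTRIBUTE_KINDS, EffectSpec, ModelSpec, statistics
from .network import ActorTable, TwoLayerDigraph, n_tie_variables
from .sampler import SamplerSettings, simulate
from . import _kernels

__all__ = [
    "EstimationSettings",
    "EstimationResult",
    "GofReport",
    "fit",
    "convergence_check",
    "gof",
    "CONVERGENCE_THRESHOLD",
]

logger = logging.getLogger(__name__)

CONVERGENCE_THRESHOLD = 0.1
RIDGE = 1e-6


@dataclass(frozen=True)
class EstimationSettings:
    phase1_samples: int = 100
    subphase_iterations: tuple[int, ...] = (100, 200, 400, 800)
    initial_gain: float = 0.1
    phase3_samples: int = 1000
    seed: int = 0
    max_retries: int = 3
    burn_in: int | None = None
    thinning: int | None = None
    steps_per_iteration: int | None = None
    max_update: float = 0.5  # elementwise truncation of one RM update

    def __post_init__(self):
        if self.phase1_samples < 1 or self.phase3_samples < 1:
            raise ValueError("sample sizes must be >= 1")
        if any(it < 1 for it in self.subphase_iterations):
            raise ValueError("subphase iteration counts must be >= 1")
        if not self.initial_gain > 0:
            raise ValueError("gain must be > 0")


@dataclass(frozen=True)
class EstimationResult:
    spec: ModelSpec
    theta: np.ndarray
    se: np.ndarray
    t_ratios: np.ndarray
    covariance: np.ndarray
    observed: np.ndarray
    sim_mean: np.ndarray
    sim_sd: np.ndarray
    converged: bool
    n_retries: int
    seed: int

    @property
    def labels(self) -> list[str]:
        return self.spec.labels

    @property
    def significant(self) -> np.ndarray:
        """Effects whose |estimate| reaches twice its standard error."""
        return np.abs(self.theta) >= 2.0 * self.se

    def to_frame(self) -> pd.DataFrame:
        """Table of estimates in the conventional report layout:
        effect, estimate, SE, significance star, convergence t-ratio."""
        rows = []
        for k, e in enumerate(self.spec):
            rows.append(
                {
                    "kind": e.kind,
                    "layer": e.layer,
                    "attribute": e.attribute if e.attribute is not None else "",
                    "lambda": e.lam,
                    "estimate": self.theta[k],
                    "se": self.se[k],
                    "significant": "*" if self.significant[k] else "",
                    "t_ratio": self.t_ratios[k],
                }
            )
        return pd.DataFrame(rows)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, seed: int = 0) -> "EstimationResult":
        """Rebuild estimates/SEs/t-ratios from a serialised table.

        The simulated covariance and moment vectors are not serialised; the
        reconstructed result carries NaN there and is suitable for
        reporting-side use (log-odds tables, significance checks).
        """
        effects = tuple(
            EffectSpec(
                kind=r["kind"],
                layer=r["layer"],
                attribute=(r["attribute"] if isinstance(r["attribute"], str) and r["attribute"] else None),
                lam=float(r["lambda"]),
            )
            for r in df.to_dict("records")
        )
        p = len(effects)
        theta = df["estimate"].to_numpy(float)
        se = df["se"].to_numpy(float)
        t = df["t_ratio"].to_numpy(float)
        nan = np.full(p, np.nan)
        return cls(
            spec=ModelSpec(effects=effects),
            theta=theta,
            se=se,
            t_ratios=t,
            covariance=np.full((p, p), np.nan),
            observed=nan.copy(),
            sim_mean=nan.copy(),
            sim_sd=nan.copy(),
            converged=bool(np.nanmax(np.abs(t)) < CONVERGENCE_THRESHOLD) if p else False,
            n_retries=0,
            seed=seed,
        )

    @classmethod
    def from_csv(cls, path, seed: int = 0) -> "EstimationResult":
        return cls.from_frame(pd.read_csv(path, keep_default_na=False, na_values=[""]))


@dataclass(frozen=True)
class GofReport:
    """Simulation-based goodness of fit at the fitted parameters.

    ``table`` has one row per statistic: observed value, simulated mean/SD
    and t = (observed − simulated mean)/simulated SD, with a flag separating
    the fitted effects from auxiliary (not-fitted) statistics. An SD of zero
    leaves t as NaN (undefined)."""

    table: pd.DataFrame

    @property
    def max_abs_t_fitted(self) -> float:
        fitted = self.table[self.table["fitted"]]
        return float(np.nanmax(np.abs(fitted["t"].to_numpy(float))))


def _validate_spec_on_data(attrs: ActorTable | None, spec: ModelSpec) -> None:
    for e in spec:
        if e.kind in ATTRIBUTE_KINDS:
            a = np.asarray(attrs.attribute(e.attribute), dtype=float)
            if np.ptp(a) == 0:
                raise ValueError(
                    f"degenerate effect {e.label}: attribute {e.attribute!r} is constant"
                )


def _initial_theta(g: TwoLayerDigraph, spec: ModelSpec) -> np.ndarray:
    """Zeros, except arc effects start at the log-odds of the layer density
    (with a half-tie continuity correction so empty/complete layers stay
    finite)."""
    theta = np.zeros(len(spec))
    npairs = g.n * (g.n - 1)
    for k, e in enumerate(spec):
        if e.kind == "arc":
            ties = float(g.layer(e.layer).sum())
            d = (ties + 0.5) / (npairs + 1.0)
            theta[k] = np.log(d / (1.0 - d))
    return theta


class _Chain:
    """A persistently evolving chain whose θ can change between segments."""

    def __init__(self, g: TwoLayerDigraph, attrs, spec: ModelSpec, seed: int):
        self.F = g.F.astype(np.float64)
        self.D = g.D.astype(np.float64)
        (self.kinds, self.layers, self.attr_idx, self.lams, self.A) = spec.encode(
            attrs, g.n
        )
        self.z = statistics(g, attrs, spec)
        self._seeds = iter(
            np.random.SeedSequence(seed).generate_state(2_000_000, dtype=np.uint32)
            % np.uint32(2**31)
        )

    def advance(self, theta: np.ndarray, n_steps: int) -> np.ndarray:
        _kernels.advance_chain(
            self.F,
            self.D,
            self.A,
            self.kinds,
            self.layers,
            self.attr_idx,
            self.lams,
            theta,
            self.z,
            n_steps,
            int(next(self._seeds)),
        )
        return self.z


def _phase2(
    chain: _Chain,
    theta: np.ndarray,
    z_obs: np.ndarray,
    d_inv: np.ndarray,
    settings: EstimationSettings,
    steps: int,
) -> np.ndarray:
    gain = settings.initial_gain
    for sub, n_iter in enumerate(settings.subphase_iterations):
        is_last = sub == len(settings.subphase_iterations) - 1
        acc = np.zeros_like(theta)
        for _ in range(n_iter):
            z = chain.advance(theta, steps)
            update = gain * (d_inv @ (z - z_obs))
            np.clip(update, -settings.max_update, settings.max_update, out=update)
            theta = theta - update
            if is_last:
                acc += theta
        if is_last:
            theta = acc / n_iter  # Polyak-style averaging over the last subphase
        gain *= 0.5
    return theta


def fit(
    g: TwoLayerDigraph,
    attrs: ActorTable | None,
    spec: ModelSpec,
    settings: EstimationSettings | None = None,
) -> EstimationResult:
    """Fit θ̂ by stochastic approximation of the moment equation.

    Returns a complete :class:`EstimationResult`; a fit that fails the
    |t-ratio| < 0.1 criterion after all retries comes back with
    ``converged=False`` and the diagnostics intact.
    """
    settings = settings or EstimationSettings()
    _validate_spec_on_data(attrs, spec)
    z_obs = statistics(g, attrs, spec)
    if not np.isfinite(z_obs).all():
        raise ValueError("observed statistics are not finite")

    root = np.random.SeedSequence(settings.seed)
    s_phase1, s_phase2, s_phase3 = (int(s) for s in root.generate_state(3) % 2**31)

    nt = n_tie_variables(g.n)
    burn = settings.burn_in if settings.burn_in is not None else 50 * nt
    thin = settings.thinning if settings.thinning is not None else nt
    steps = (
        settings.steps_per_iteration
        if settings.steps_per_iteration is not None
        else max(nt // 2, 1)
    )

    theta = _initial_theta(g, spec)

    # phase 1: preconditioner from the statistic covariance at theta0
    batch1 = simulate(
        theta,
        spec,
        attrs,
        g.n,
        SamplerSettings(
            burn_in=burn,
            thinning=thin,
            n_samples=settings.phase1_samples,
            seed=s_phase1,
            initial_state=g,
        ),
    )
    d_hat = batch1.cov() + RIDGE * np.eye(len(spec))
    d_inv = np.linalg.inv(d_hat)

    chain = _Chain(g, attrs, spec, s_phase2)
    chain.advance(theta, burn)

    retries = 0
    while True:
        theta = _phase2(chain, theta, z_obs, d_inv, settings, steps)

        batch3 = simulate(
            theta,
            spec,
            attrs,
            g.n,
            SamplerSettings(
                burn_in=burn,
                thinning=thin,
                n_samples=settings.phase3_samples,
                seed=s_phase3 + retries,
                initial_state=g,
            ),
        )
        sim_mean = batch3.mean()
        sim_sd = batch3.sd()
        cov = batch3.cov() + RIDGE * np.eye(len(spec))
        with np.errstate(divide="ignore", invalid="ignore"):
            t_ratios = (sim_mean - z_obs) / sim_sd
        converged = bool(np.nanmax(np.abs(t_ratios)) < CONVERGENCE_THRESHOLD)
        if converged or retries >= settings.max_retries:
            break
        retries += 1
        logger.info(
            "fit not converged (max |t| = %.3f); phase-2 restart %d",
            float(np.nanmax(np.abs(t_ratios))),
            retries,
        )

    se = np.sqrt(np.diag(np.linalg.inv(cov)))
    if not converged:
        logger.warning(
            "estimation failed the |t| < %.2f criterion after %d retries (max |t| = %.3f)",
            CONVERGENCE_THRESHOLD,
            retries,
            float(np.nanmax(np.abs(t_ratios))),
        )
    return EstimationResult(
        spec=spec,
        theta=theta,
        se=se,
        t_ratios=t_ratios,
        covariance=cov,
        observed=z_obs,
        sim_mean=sim_mean,
        sim_sd=sim_sd,
        converged=converged,
        n_retries=retries,
        seed=settings.seed,
    )


def convergence_check(r: EstimationResult) -> tuple[bool, dict[str, float]]:
    """Apply the |t-ratio| < 0.1 convergence criterion per fitted effect."""
    ratios = {lab: float(t) for lab, t in zip(r.labels, r.t_ratios)}
    passed = all(abs(t) < CONVERGENCE_THRESHOLD for t in ratios.values())
    if not passed:
        failing = [lab for lab, t in ratios.items() if abs(t) >= CONVERGENCE_THRESHOLD]
        logger.warning("convergence check failed for: %s", ", ".join(failing))
    return passed, ratios


def gof(
    g: TwoLayerDigraph,
    attrs: ActorTable | None,
    r: EstimationResult,
    auxiliary_spec: ModelSpec | None = None,
    n_samples: int = 500,
    seed: int | None = None,
    burn_in: int | None = None,
    thinning: int | None = None,
) -> GofReport:
    """Simulation goodness of fit at θ̂ for fitted and auxiliary statistics.

    Auxiliary statistics are ones the model was NOT fitted to; a model that
    reproduces them as well (|t| small) fits features it never targeted.
    """
    aux_effects = tuple(auxiliary_spec.effects) if auxiliary_spec is not None else ()
    fitted_keys = {e.key for e in r.spec}
    combined = ModelSpec(
        effects=tuple(r.spec.effects)
        + tuple(e for e in aux_effects if e.key not in fitted_keys)
    )
    theta_full = np.concatenate([r.theta, np.zeros(len(combined) - len(r.spec))])
    # simulate under the fitted model only: zero-padding theta over the
    # auxiliary effects leaves the distribution unchanged while the chain
    # tracks the auxiliary statistics alongside
    batch = simulate(
        theta_full,
        combined,
        attrs,
        g.n,
        SamplerSettings(
            burn_in=burn_in,
            thinning=thinning,
            n_samples=n_samples,
            seed=r.seed + 7919 if seed is None else seed,
            initial_state=g,
        ),
    )
    observed = statistics(g, attrs, combined)
    sim_mean = batch.mean()
    sim_sd = batch.sd()
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(sim_sd > 0, (observed - sim_mean) / sim_sd, np.nan)
    table = pd.DataFrame(
        {
            "statistic": combined.labels,
            "observed": observed,
            "sim_mean": sim_mean,
            "sim_sd": sim_sd,
            "t": t,
            "fitted": [e.key in fitted_keys for e in combined],
        }
    )
    return GofReport(table=table)
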