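"""Synthetic roster cohorts with the structure the analysis assumes.

The school survey data behind the published cohort analyses was never
deposited, so every pipeline stage here is exercised on generated data. The
generator emulates two same-gender Year-8 cohorts: ~59 boys and ~61 girls,
friendship density around 0.07-0.09, dislike density around 0.02, clear
friendship reciprocity, triadic clustering, a handful of dissonant dyads,
and attribute distributions matching the cohorts' published means and SDs
(wellbeing near 61/58 with SD ~12; right-skewed depressed-mood scores with
mean 4-6 and SD ~5; 63% tertiary-educated parents).

Networks are drawn from the ERGM itself: profile "strengths" set the
reciprocity, closure and dissonance parameters, and the two arc parameters
are tuned by stochastic root-finding until realised densities hit the
profile targets.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import stats as sstats

from .effects import EffectSpec, ModelSpec
from .network import (
    PWB_RANGE,
    SMF_RANGE,
    ActorTable,
    TwoLayerDigraph,
    n_tie_variables,
)
from .sampler import SamplerSettings, simulate

__all__ = [
    "CohortProfile",
    "BOYS_PROFILE",
    "GIRLS_PROFILE",
    "generate_attributes",
    "generate_cohort",
    "default_generator_spec",
    "fixture",
    "FIXTURE_NAMES",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class CohortProfile:
    """Target structure of one same-gender cohort."""

    n_actors: int = 59
    friendship_density: float = 0.071
    dislike_density: float = 0.019
    reciprocity_strength: float = 1.5
    closure_strength: float = 0.3
    dissonance_strength: float = 1.0
    dissonance_attr_weight: float = 0.0  # mutual-sum-exchange weight on PWB
    pwb_mean: float = 61.1
    pwb_sd: float = 11.6
    smf_mean: float = 4.0
    smf_sd: float = 5.0
    ses_prevalence: float = 0.63
    gender: str = "boy"
    seed: int = 0

    def __post_init__(self):
        if not (0 < self.friendship_density < 1 and 0 < self.dislike_density < 1):
            raise ValueError("target densities must lie in (0, 1)")
        if self.n_actors < 10:
            raise ValueError("model-based generation needs at least 10 actors")
        if not 0 <= self.ses_prevalence <= 1:
            raise ValueError("ses_prevalence must lie in [0, 1]")


BOYS_PROFILE = CohortProfile()
GIRLS_PROFILE = CohortProfile(
    n_actors=61,
    friendship_density=0.090,
    dislike_density=0.0246,
    pwb_mean=58.2,
    pwb_sd=12.6,
    smf_mean=6.0,
    smf_sd=5.1,
    gender="girl",
)


def _smf_distribution(mean: float, sd: float):
    """Right-skewed integer depressed-mood scores: negative binomial when the
    target is overdispersed (variance > mean, the empirical case), Poisson
    otherwise."""
    var = sd * sd
    if var > mean > 0:
        p = mean / var
        r = mean * mean / (var - mean)
        return sstats.nbinom(r, p)
    return sstats.poisson(max(mean, 1e-9))


def _matched_normal_params(mean: float, sd: float, lo: float, hi: float) -> tuple[float, float]:
    """Pre-clip normal parameters whose rounded-and-clipped draw has the
    target mean and SD (fixed-point iteration over the discretised law)."""
    ks = np.arange(lo, hi + 1)
    m, s = mean, sd
    for _ in range(20):
        upper = np.where(ks == hi, np.inf, ks + 0.5)
        lower = np.where(ks == lo, -np.inf, ks - 0.5)
        pk = sstats.norm.cdf(upper, m, s) - sstats.norm.cdf(lower, m, s)
        mu = float(pk @ ks)
        sig = float(np.sqrt(pk @ (ks - mu) ** 2))
        m += mean - mu
        s *= sd / max(sig, 1e-9)
    return m, s


def generate_attributes(p: CohortProfile, seed: int | None = None) -> ActorTable:
    """Draw one cohort's attribute table from the profile distributions.

    Wellbeing is normal, rounded and clipped to its 14-84 instrument range;
    the pre-clip mean/SD are adjusted so the clipped scores keep the profile
    moments. Depressed mood is a right-skewed count clipped to 0-26; SES is
    Bernoulli at the stated prevalence. Reproducible by seed.
    """
    rng = np.random.default_rng(p.seed if seed is None else seed)
    n = p.n_actors
    m, s = _matched_normal_params(p.pwb_mean, p.pwb_sd, *PWB_RANGE)
    pwb = np.clip(np.rint(rng.normal(m, s, size=n)), *PWB_RANGE)
    smf = np.clip(_smf_distribution(p.smf_mean, p.smf_sd).rvs(size=n, random_state=rng), *SMF_RANGE)
    ses = (rng.random(n) < p.ses_prevalence).astype(float)
    ids = tuple(f"{p.gender}{k + 1:03d}" for k in range(n))
    return ActorTable(
        pwb=pwb,
        smf=smf.astype(float),
        ses=ses,
        gender=np.full(n, p.gender, dtype=object),
        actor_ids=ids,
    )


def default_generator_spec(p: CohortProfile) -> tuple[ModelSpec, np.ndarray]:
    """The generating model implied by a profile, with its fixed θ entries.

    Arc parameters (first two entries) are placeholders tuned by
    :func:`generate_cohort`; reciprocity, closure and dissonance strengths
    map onto the corresponding effect weights.
    """
    effects = [
        EffectSpec("arc", "F"),
        EffectSpec("arc", "D"),
        EffectSpec("reciprocity", "F"),
        EffectSpec("alt_transitive_triangle", "F"),
        EffectSpec("exchange", "cross"),
    ]
    theta = [
        _logit(p.friendship_density),
        _logit(p.dislike_density),
        p.reciprocity_strength,
        p.closure_strength,
        p.dissonance_strength,
    ]
    if p.dissonance_attr_weight != 0.0:
        effects.append(EffectSpec("mutual_sum_exchange", "cross", "pwb"))
        theta.append(p.dissonance_attr_weight)
    return ModelSpec(effects=tuple(effects)), np.array(theta, dtype=float)


def _logit(x: float) -> float:
    return float(np.log(x / (1.0 - x)))


def generate_cohort(
    p: CohortProfile,
    spec: ModelSpec | None = None,
    theta: np.ndarray | None = None,
    density_band: float = 0.30,
    max_tuning_steps: int = 25,
) -> tuple[TwoLayerDigraph, ActorTable]:
    """Generate attributes and a model-based two-layer network for a cohort.

    The arc parameters of both layers are tuned by damped stochastic
    root-finding on the logit scale (5 probe simulations per step from a
    persistent chain) until realised densities fall within ``density_band``
    (relative) of the profile targets; the final network is then drawn from
    a fresh chain at the tuned parameters.
    """
    attrs = generate_attributes(p)
    if spec is None:
        spec, theta = default_generator_spec(p)
    elif theta is None:
        raise ValueError("theta must be given alongside a custom spec")
    theta = np.asarray(theta, dtype=float).copy()
    try:
        kf = spec.index_of("arc", "F")
        kd = spec.index_of("arc", "D")
    except KeyError:
        raise ValueError("generator spec must include arc effects for both layers") from None

    n = p.n_actors
    npairs = n * (n - 1)
    targets = np.array([p.friendship_density, p.dislike_density])
    rng = np.random.default_rng(np.random.SeedSequence([p.seed, 211]))
    # probe burn-in matches the final draw so slow-mixing chains are judged
    # at the same point of their trajectory
    probe = SamplerSettings(
        burn_in=30 * n_tie_variables(n),
        thinning=n_tie_variables(n) // 2,
        n_samples=5,
    )
    tuned = False
    for step in range(max_tuning_steps):
        batch = simulate(
            theta, spec, attrs, n,
            replace(probe, seed=int(rng.integers(2**31))),
        )
        dens = np.array(
            [batch.statistics[:, kf].mean(), batch.statistics[:, kd].mean()]
        ) / npairs
        rel_err = np.abs(dens - targets) / targets
        # sparse layers on small cohorts expect only a handful of ties, so a
        # two-tie absolute slack accompanies the relative band
        tie_err = np.abs(dens - targets) * npairs
        logger.debug("tuning step %d: densities %s (rel err %s)", step, dens, rel_err)
        if ((rel_err < 0.5 * density_band) | (tie_err < 2.0)).all():
            tuned = True
            break
        dens = np.clip(dens, 0.5 / npairs, 1 - 0.5 / npairs)
        correction = np.array([_logit(t) for t in targets]) - np.array(
            [_logit(d) for d in dens]
        )
        # the density response is steeper than logistic once the positive
        # structural effects kick in, so the logit correction is damped hard
        theta[kf] += 0.35 * float(np.clip(correction[0], -1.0, 1.0))
        theta[kd] += 0.35 * float(np.clip(correction[1], -1.0, 1.0))
    if not tuned:
        raise RuntimeError(
            f"density tuning failed after {max_tuning_steps} steps: "
            f"last realised densities {dens}, targets {targets}"
        )

    # final draw: accept the first realisation inside the (wider) band
    for attempt in range(8):
        batch = simulate(
            theta, spec, attrs, n,
            SamplerSettings(
                burn_in=30 * n_tie_variables(n),
                thinning=1,
                n_samples=1,
                seed=int(rng.integers(2**31)),
                return_graphs=True,
            ),
        )
        g = batch.graphs[0]
        dens = np.array([g.F.sum(), g.D.sum()]) / npairs
        err = np.abs(dens - targets)
        if ((err / targets < density_band) | (err * npairs < 2.0)).all():
            break
    else:
        raise RuntimeError(
            f"no realisation within the density band after 8 draws: last {dens}, "
            f"targets {targets}"
        )
    g = TwoLayerDigraph(F=g.F, D=g.D, actor_ids=attrs.actor_ids)
    return g, attrs


# ---------------------------------------------------------------------------
# Deterministic hand-built fixtures
# ---------------------------------------------------------------------------

FIXTURE_NAMES = ("triangle", "dissonant-pair", "empty-5", "mixed-gender-6")


def fixture(name: str) -> tuple[TwoLayerDigraph, ActorTable]:
    """Small deterministic graphs with documented exact statistic values.

    triangle
        3 actors; friendship ties 0->1, 1->2, 0->2; no dislike. Exactly one
        directed two-path (0->1->2), closed by the tie 0->2, so the
        two-path count is 1 and the alternating transitive-triangle
        statistic at lambda=2 is 2*(1-(1/2)^1) = 1.
    dissonant-pair
        3 actors; friendship 0->1, dislike 1->0 and nothing else: exactly
        one exchange pair.
    empty-5
        5 actors, no ties: every statistic is zero.
    mixed-gender-6
        6 actors alternating boy/girl with both within- and cross-gender
        ties in both layers; used for subsetting and mixing tests.
    """
    if name == "triangle":
        F = _edges(3, [(0, 1), (1, 2), (0, 2)])
        D = np.zeros((3, 3), dtype=np.uint8)
        attrs = _attrs(["boy"] * 3, pwb=[20, 50, 79], smf=[0, 5, 22], ses=[0, 1, 1])
    elif name == "dissonant-pair":
        F = _edges(3, [(0, 1)])
        D = _edges(3, [(1, 0)])
        attrs = _attrs(["boy"] * 3, pwb=[30, 60, 45], smf=[3, 5, 8], ses=[1, 0, 1])
    elif name == "empty-5":
        F = np.zeros((5, 5), dtype=np.uint8)
        D = F.copy()
        attrs = _attrs(
            ["girl"] * 5, pwb=[20, 35, 50, 65, 80], smf=[0, 2, 6, 12, 22], ses=[0, 1, 0, 1, 1]
        )
    elif name == "mixed-gender-6":
        # actors 0,2,4 boys; 1,3,5 girls
        F = _edges(6, [(0, 2), (2, 0), (2, 4), (1, 3), (3, 5), (5, 1), (0, 1), (3, 2)])
        D = _edges(6, [(4, 0), (1, 5), (2, 3), (5, 3)])
        attrs = _attrs(
            ["boy", "girl", "boy", "girl", "boy", "girl"],
            pwb=[25, 40, 55, 60, 70, 79],
            smf=[1, 4, 2, 9, 0, 22],
            ses=[0, 1, 1, 0, 1, 1],
        )
    else:
        raise KeyError(f"unknown fixture {name!r}; known: {FIXTURE_NAMES}")
    ids = attrs.actor_ids
    return TwoLayerDigraph(F=F, D=D, actor_ids=ids), attrs


def _edges(n: int, pairs) -> np.ndarray:
    m = np.zeros((n, n), dtype=np.uint8)
    for i, j in pairs:
        m[i, j] = 1
    return m


def _attrs(gender, pwb, smf, ses) -> ActorTable:
    n = len(gender)
    ids = tuple(f"a{k}" for k in range(n))
    return ActorTable(
        pwb=np.asarray(pwb, float),
        smf=np.asarray(smf, float),
        ses=np.asarray(ses, float),
        gender=np.asarray(gender, object),
        actor_ids=ids,
    )
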