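"""ERGM configuration statistics for two-layer directed networks.

Each effect is a network configuration whose count (possibly geometrically
damped, possibly attribute-weighted) enters the exponential family

    P(X = x) ∝ exp( Σ_A θ_A z_A(x) ).

The module provides the full-graph value z_A(x) of every effect, the vector
of values for an ordered model specification, and the single-tie change
statistic Δz_A = z_A(x⁺_ij) − z_A(x⁻_ij) computed incrementally — the
quantity that drives both Metropolis sampling and the interpretation of
estimates as conditional log-odds.

Effect kinds
------------
arc
    Tie count of one layer (the density/edge effect).
reciprocity
    Mutual dyads within one layer.
two_path
    Directed two-paths i→j→k ("simple connectivity").
alt_in_star / alt_out_star
    Alternating in-/out-star statistics (popularity / activity
    centralization): geometrically damped degree sums that model degree
    heterogeneity without degeneracy.
alt_transitive_triangle
    Alternating transitive-triangle statistic ("path closure"): a tie i→j
    weighted by a damped count of the two-paths i→k→j it closes.
alt_two_path
    Alternating two-path statistic ("multiple connectivity"): the same
    damped two-path count without requiring the closing tie.
exchange
    Cross-layer relational-dissonance count: i befriends j while j
    dislikes i (F_ij · D_ji).
sender / receiver
    Attribute-weighted out-/in-ties of one layer.
difference_homophily
    NEGATIVE summed absolute attribute difference over ties, so a positive
    parameter means attraction to similar others. Attributes enter raw
    (uncentered) throughout.
mutual_product
    Mutual dyads weighted by the product of both actors' attributes.
mutual_sum_exchange
    The dissonance pattern weighted by the SUM of both actors' attributes —
    the attribute-dependent dissonance effect at the heart of the model.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .network import ActorTable, TwoLayerDigraph

__all__ = [
    "EffectSpec",
    "ModelSpec",
    "STRUCTURAL_KINDS",
    "ATTRIBUTE_KINDS",
    "CROSS_KINDS",
    "statistic_value",
    "statistics",
    "change_statistics",
    "cohort_model_spec",
]

STRUCTURAL_KINDS = frozenset(
    {
        "arc",
        "reciprocity",
        "two_path",
        "alt_in_star",
        "alt_out_star",
        "alt_transitive_triangle",
        "alt_two_path",
        "exchange",
    }
)
ATTRIBUTE_KINDS = frozenset(
    {"sender", "receiver", "difference_homophily", "mutual_product", "mutual_sum_exchange"}
)
CROSS_KINDS = frozenset({"exchange", "mutual_sum_exchange"})
ALL_KINDS = STRUCTURAL_KINDS | ATTRIBUTE_KINDS

# integer codes shared with the numba kernels in _kernels.py
KIND_CODES = {
    "arc": 0,
    "reciprocity": 1,
    "two_path": 2,
    "alt_in_star": 3,
    "alt_out_star": 4,
    "alt_transitive_triangle": 5,
    "alt_two_path": 6,
    "exchange": 7,
    "sender": 8,
    "receiver": 9,
    "difference_homophily": 10,
    "mutual_product": 11,
    "mutual_sum_exchange": 12,
}
LAYER_CODES = {"F": 0, "D": 1, "cross": 2}


@dataclass(frozen=True)
class EffectSpec:
    """One model effect: a statistic kind bound to a layer and optionally an attribute."""

    kind: str
    layer: str = "F"
    attribute: str | None = None
    lam: float = 2.0

    def __post_init__(self):
        if self.kind not in ALL_KINDS:
            raise ValueError(f"unknown effect kind {self.kind!r}")
        if self.kind in CROSS_KINDS:
            if self.layer != "cross":
                raise ValueError(f"{self.kind} is a cross-layer effect; layer must be 'cross'")
        elif self.layer not in ("F", "D"):
            raise ValueError(f"layer must be 'F' or 'D' for {self.kind}, got {self.layer!r}")
        needs_attr = self.kind in ATTRIBUTE_KINDS
        if needs_attr and self.attribute is None:
            raise ValueError(f"{self.kind} requires an attribute")
        if not needs_attr and self.attribute is not None:
            raise ValueError(f"{self.kind} takes no attribute")
        if not self.lam > 1:
            raise ValueError("smoothing constant lambda must exceed 1")

    @property
    def key(self) -> tuple:
        return (self.kind, self.layer, self.attribute)

    @property
    def label(self) -> str:
        attr = f" ({self.attribute})" if self.attribute else ""
        return f"{self.kind}[{self.layer}]{attr}"


@dataclass(frozen=True)
class ModelSpec:
    """Ordered list of effects; defines the statistic vector z(x)."""

    effects: tuple[EffectSpec, ...]

    def __post_init__(self):
        effects = tuple(self.effects)
        if not effects:
            raise ValueError("a model needs at least one effect")
        keys = [e.key for e in effects]
        if len(set(keys)) != len(keys):
            raise ValueError("duplicate (kind, layer, attribute) effect")
        object.__setattr__(self, "effects", effects)

    def __len__(self) -> int:
        return len(self.effects)

    def __iter__(self):
        return iter(self.effects)

    @property
    def labels(self) -> list[str]:
        return [e.label for e in self.effects]

    def index_of(self, kind: str, layer: str = "F", attribute: str | None = None) -> int:
        key = (kind, layer, attribute)
        for k, e in enumerate(self.effects):
            if e.key == key:
                return k
        raise KeyError(f"effect {key} not in model")

    def to_records(self) -> list[dict]:
        return [
            {"kind": e.kind, "layer": e.layer, "attribute": e.attribute, "lambda": e.lam}
            for e in self.effects
        ]

    @classmethod
    def from_records(cls, records: Sequence[dict]) -> "ModelSpec":
        return cls(
            effects=tuple(
                EffectSpec(
                    kind=r["kind"],
                    layer=r.get("layer", "F"),
                    attribute=r.get("attribute"),
                    lam=float(r.get("lambda", 2.0)),
                )
                for r in records
            )
        )

    def encode(self, attrs: ActorTable | None, n: int):
        """Pack the spec into flat arrays for the compiled sampler kernels.

        Returns (kinds, layers, attr_index, lambdas, attr_matrix): integer
        codes per effect, a per-effect row index into ``attr_matrix`` (-1 for
        structural effects), and the stacked attribute vectors.
        """
        kinds = np.array([KIND_CODES[e.kind] for e in self.effects], dtype=np.int64)
        layers = np.array([LAYER_CODES[e.layer] for e in self.effects], dtype=np.int64)
        lams = np.array([e.lam for e in self.effects], dtype=np.float64)
        names = sorted({e.attribute for e in self.effects if e.attribute is not None})
        if names and attrs is None:
            raise ValueError("model has attribute effects but no actor table was given")
        attr_matrix = (
            np.vstack([np.asarray(attrs.attribute(a), dtype=np.float64) for a in names])
            if names
            else np.zeros((1, n), dtype=np.float64)
        )
        attr_index = np.array(
            [names.index(e.attribute) if e.attribute is not None else -1 for e in self.effects],
            dtype=np.int64,
        )
        return kinds, layers, attr_index, lams, attr_matrix


def cohort_model_spec(attributes: Sequence[str] = ("pwb", "smf", "ses")) -> ModelSpec:
    """The full multivariate specification used for the cohort analyses.

    Friendship carries all seven structural effects; dislike omits the
    two-path ("simple connectivity") and transitive-closure terms; a single
    cross-layer exchange effect links the layers. Sender/receiver/homophily
    effects enter per attribute on both layers, plus mutual product of
    wellbeing on friendship, mutual product of depressed mood on dislike, and
    mutual-sum-exchange effects for wellbeing and depressed mood.
    """
    eff: list[EffectSpec] = [
        EffectSpec("arc", "F"),
        EffectSpec("reciprocity", "F"),
        EffectSpec("two_path", "F"),
        EffectSpec("alt_in_star", "F"),
        EffectSpec("alt_out_star", "F"),
        EffectSpec("alt_transitive_triangle", "F"),
        EffectSpec("alt_two_path", "F"),
        EffectSpec("arc", "D"),
        EffectSpec("reciprocity", "D"),
        EffectSpec("alt_in_star", "D"),
        EffectSpec("alt_out_star", "D"),
        EffectSpec("alt_two_path", "D"),
        EffectSpec("exchange", "cross"),
    ]
    for a in attributes:
        for layer in ("F", "D"):
            eff.append(EffectSpec("sender", layer, a))
            eff.append(EffectSpec("receiver", layer, a))
            eff.append(EffectSpec("difference_homophily", layer, a))
    if "pwb" in attributes:
        eff.append(EffectSpec("mutual_product", "F", "pwb"))
        eff.append(EffectSpec("mutual_sum_exchange", "cross", "pwb"))
    if "smf" in attributes:
        eff.append(EffectSpec("mutual_product", "D", "smf"))
        eff.append(EffectSpec("mutual_sum_exchange", "cross", "smf"))
    return ModelSpec(effects=tuple(eff))


def _attr(attrs: ActorTable | None, e: EffectSpec) -> np.ndarray:
    if attrs is None:
        raise ValueError(f"effect {e.label} needs an actor table")
    return np.asarray(attrs.attribute(e.attribute), dtype=float)


def _alt_star(deg: np.ndarray, lam: float) -> float:
    # lambda^2 * sum_j [ (1-1/lambda)^q_j + q_j/lambda - 1 ]
    r = 1.0 - 1.0 / lam
    return float(lam * lam * (r**deg + deg / lam - 1.0).sum())


def statistic_value(
    g: TwoLayerDigraph, attrs: ActorTable | None, e: EffectSpec
) -> float:
    """Full-graph value z_e(x) of a single effect."""
    F = g.F.astype(float)
    D = g.D.astype(float)
    if e.kind == "exchange":
        return float((F * D.T).sum())
    if e.kind == "mutual_sum_exchange":
        a = _attr(attrs, e)
        return float(((F * D.T) * (a[:, None] + a[None, :])).sum())
    M = F if e.layer == "F" else D
    lam = e.lam
    if e.kind == "arc":
        return float(M.sum())
    if e.kind == "reciprocity":
        return float((M * M.T).sum()) / 2.0
    if e.kind == "two_path":
        # ordered distinct triples (i, j, k): x_ij x_jk; i=k pairs (mutual
        # dyads seen as i->j->i) are excluded by subtracting trace(M@M)
        P = M @ M
        return float(P.sum() - np.trace(P))
    if e.kind == "alt_in_star":
        return _alt_star(M.sum(axis=0), lam)
    if e.kind == "alt_out_star":
        return _alt_star(M.sum(axis=1), lam)
    if e.kind in ("alt_transitive_triangle", "alt_two_path"):
        r = 1.0 - 1.0 / lam
        P = M @ M  # P[i, j] = #{k: i->k->j}; diagonal never used (i≠j)
        damp = lam * (1.0 - r**P)
        np.fill_diagonal(damp, 0.0)
        if e.kind == "alt_transitive_triangle":
            return float((M * damp).sum())
        return float(damp.sum())
    a = _attr(attrs, e)
    if e.kind == "sender":
        return float((M * a[:, None]).sum())
    if e.kind == "receiver":
        return float((M * a[None, :]).sum())
    if e.kind == "difference_homophily":
        return -float((M * np.abs(a[:, None] - a[None, :])).sum())
    if e.kind == "mutual_product":
        return float((M * M.T * (a[:, None] * a[None, :])).sum()) / 2.0
    raise ValueError(f"unknown effect kind {e.kind!r}")


def statistics(
    g: TwoLayerDigraph, attrs: ActorTable | None, spec: ModelSpec
) -> np.ndarray:
    """Statistic vector z(x), ordered as the model specification."""
    return np.array([statistic_value(g, attrs, e) for e in spec], dtype=float)


def change_statistics(
    g: TwoLayerDigraph,
    attrs: ActorTable | None,
    spec: ModelSpec,
    i: int,
    j: int,
    layer: str,
) -> np.ndarray:
    """Change statistics Δz for the tie variable (i, j) on one layer.

    Δz = z(x with the tie present) − z(x with the tie absent), all other
    ties held fixed; each effect is updated from local neighbourhood counts
    rather than by recomputing the full statistic. The current state of the
    toggled tie does not matter: the delta is always presence-minus-absence.
    """
    if i == j:
        raise ValueError("self-ties are not tie variables")
    F = g.F.astype(float)
    D = g.D.astype(float)
    X = F if layer == "F" else D
    other = D if layer == "F" else F
    x_ij = X[i, j]
    X[i, j] = 0.0  # evaluate local counts in the tie-absent state
    delta = np.empty(len(spec), dtype=float)
    for k, e in enumerate(spec):
        delta[k] = _delta_one(X, other, layer, attrs, e, i, j)
    X[i, j] = x_ij
    return delta


def _delta_one(
    X: np.ndarray,
    other: np.ndarray,
    layer: str,
    attrs: ActorTable | None,
    e: EffectSpec,
    i: int,
    j: int,
) -> float:
    """Presence-minus-absence delta of one effect; X is the toggled layer
    with X[i,j] cleared, ``other`` the untouched companion layer."""
    if e.kind == "exchange":
        # F_ij D_ji: completing the pattern requires the reverse tie in the
        # other layer regardless of which layer is toggled
        return float(other[j, i])
    if e.kind == "mutual_sum_exchange":
        a = _attr(attrs, e)
        return float(other[j, i] * (a[i] + a[j]))
    if e.layer != layer:
        return 0.0
    lam = e.lam
    r = 1.0 - 1.0 / lam
    if e.kind == "arc":
        return 1.0
    if e.kind == "reciprocity":
        return float(X[j, i])
    if e.kind == "two_path":
        return float(X[j].sum() + X[:, i].sum() - 2.0 * X[j, i])
    if e.kind == "alt_in_star":
        return float(lam * (1.0 - r ** X[:, j].sum()))
    if e.kind == "alt_out_star":
        return float(lam * (1.0 - r ** X[i].sum()))
    if e.kind in ("alt_transitive_triangle", "alt_two_path"):
        p_row_i = X[i] @ X  # two-path counts i -> k -> j' for all j'
        p_col_j = X @ X[:, j]  # two-path counts i' -> k -> j for all i'
        if e.kind == "alt_two_path":
            # pairs (i, j') gaining the path i->j->j' and pairs (i', j)
            # gaining i'->i->j; the invalid diagonal pairs (i, i) and (j, j)
            # must be excluded by hand since a reverse tie X[j, i] exists
            gain_rows = float((X[j] * r ** p_row_i).sum() - X[j, i] * r ** p_row_i[i])
            gain_cols = float((X[:, i] * r ** p_col_j).sum() - X[j, i] * r ** p_col_j[j])
            return gain_rows + gain_cols
        closing = float(lam * (1.0 - r ** p_row_i[j]))
        gain_rows = float((X[i] * X[j] * r ** p_row_i).sum())
        gain_cols = float((X[:, j] * X[:, i] * r ** p_col_j).sum())
        return closing + gain_rows + gain_cols
    a = _attr(attrs, e)
    if e.kind == "sender":
        return float(a[i])
    if e.kind == "receiver":
        return float(a[j])
    if e.kind == "difference_homophily":
        return -abs(float(a[i] - a[j]))
    if e.kind == "mutual_product":
        return float(X[j, i] * a[i] * a[j])
    raise ValueError(f"unknown effect kind {e.kind!r}")
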