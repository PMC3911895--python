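"""Two-layer directed sociometric networks with actor attributes.

The unit of analysis is a roster-based cohort: every actor may nominate any
other actor on two binary directed relations, friendship (F) and dislike (D).
Adjacency is stored densely (``uint8`` matrices) because every model
computation downstream — configuration statistics, single-tie change
statistics, Metropolis sampling — touches ordered actor pairs directly.

Actor identifiers are arbitrary strings externally and dense 0-based indices
internally; every public output reports external ids.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "TwoLayerDigraph",
    "ActorTable",
    "NetworkSummary",
    "MixingProportions",
    "RosterError",
    "load_layer",
    "merge_dislike_items",
    "subnetwork_by_group",
    "summarize_layer",
    "count_reciprocated_pairs",
    "count_exchange_pairs",
    "mixing_proportions",
    "pooled_t",
    "n_tie_variables",
    "read_edge_list",
    "read_attribute_table",
    "write_edge_list",
    "write_attribute_table",
    "load_cohort",
]

PWB_RANGE = (14, 84)
SMF_RANGE = (0, 26)


class RosterError(ValueError):
    """Raised for input violating the roster contract (unknown actor ids, ...)."""


@dataclass(frozen=True)
class TwoLayerDigraph:
    """A friendship layer F and a dislike layer D on one actor roster.

    Both layers are binary directed adjacency matrices with zero diagonal
    (self-nomination is not a tie). ``actor_ids`` carries the stable external
    labels; row/column ``k`` of both layers belongs to ``actor_ids[k]``.
    """

    F: np.ndarray
    D: np.ndarray
    actor_ids: tuple = ()

    def __post_init__(self):
        F = np.ascontiguousarray(np.asarray(self.F, dtype=np.uint8))
        D = np.ascontiguousarray(np.asarray(self.D, dtype=np.uint8))
        if F.ndim != 2 or F.shape[0] != F.shape[1] or F.shape != D.shape:
            raise ValueError("F and D must be square matrices of equal shape")
        if F.max(initial=0) > 1 or D.max(initial=0) > 1:
            raise ValueError("adjacency entries must be 0/1")
        if np.trace(F) or np.trace(D):
            raise ValueError("self-ties are not permitted")
        ids = tuple(self.actor_ids) if self.actor_ids else tuple(range(F.shape[0]))
        if len(ids) != F.shape[0]:
            raise ValueError("actor_ids length must equal the adjacency dimension")
        object.__setattr__(self, "F", F)
        object.__setattr__(self, "D", D)
        object.__setattr__(self, "actor_ids", ids)

    @property
    def n(self) -> int:
        return self.F.shape[0]

    @property
    def n_tie_variables(self) -> int:
        """Number of modelled tie variables: 2n(n-1), both layers, no diagonal."""
        return n_tie_variables(self.n)

    def layer(self, name: str) -> np.ndarray:
        if name == "F":
            return self.F
        if name == "D":
            return self.D
        raise KeyError(f"unknown layer {name!r} (expected 'F' or 'D')")

    def index_of(self, actor_id) -> int:
        try:
            return self.actor_ids.index(actor_id)
        except ValueError:
            raise RosterError(f"unknown actor id {actor_id!r}") from None


@dataclass(frozen=True)
class ActorTable:
    """Per-actor attributes aligned with a graph's ``actor_ids``.

    pwb
        Psychological Wellbeing score (14-item subscale, range 14-84,
        higher = better wellbeing).
    smf
        Short Mood and Feelings depressed-mood score (13 items scored 0-2,
        range 0-26, higher = more depressive symptoms).
    ses
        Binary socio-economic indicator (1 = a parent holds a tertiary
        qualification).
    gender
        Categorical label used only for cohort subsetting.
    """

    pwb: np.ndarray
    smf: np.ndarray
    ses: np.ndarray
    gender: np.ndarray
    actor_ids: tuple = ()

    def __post_init__(self):
        pwb = np.asarray(self.pwb, dtype=float)
        smf = np.asarray(self.smf, dtype=float)
        ses = np.asarray(self.ses, dtype=float)
        gender = np.asarray(self.gender, dtype=object)
        n = len(pwb)
        if not (len(smf) == len(ses) == len(gender) == n):
            raise ValueError("attribute columns must have equal length")
        if n and (pwb.min() < PWB_RANGE[0] or pwb.max() > PWB_RANGE[1]):
            raise ValueError(f"pwb outside {PWB_RANGE}")
        if n and (smf.min() < SMF_RANGE[0] or smf.max() > SMF_RANGE[1]):
            raise ValueError(f"smf outside {SMF_RANGE}")
        if n and not np.isin(ses, (0.0, 1.0)).all():
            raise ValueError("ses must be binary 0/1")
        ids = tuple(self.actor_ids) if self.actor_ids else tuple(range(n))
        if len(ids) != n:
            raise ValueError("actor_ids length must equal the table length")
        object.__setattr__(self, "pwb", pwb)
        object.__setattr__(self, "smf", smf)
        object.__setattr__(self, "ses", ses)
        object.__setattr__(self, "gender", gender)
        object.__setattr__(self, "actor_ids", ids)

    def __len__(self) -> int:
        return len(self.pwb)

    def attribute(self, name: str) -> np.ndarray:
        if name not in ("pwb", "smf", "ses"):
            raise KeyError(f"unknown attribute {name!r}")
        return getattr(self, name)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "id": list(self.actor_ids),
                "gender": self.gender,
                "pwb": self.pwb.astype(int),
                "smf": self.smf.astype(int),
                "ses": self.ses.astype(int),
            }
        )


@dataclass(frozen=True)
class NetworkSummary:
    """Per-layer descriptive statistics in the style of a cohort report table."""

    n_actors: int
    density: float
    n_ties: int
    mean_degree: float
    min_outdegree: int
    max_outdegree: int
    min_indegree: int
    max_indegree: int
    n_reciprocated_pairs: int

    def to_series(self) -> pd.Series:
        return pd.Series(
            {
                "Density": round(self.density, 5),
                "Number of ties": self.n_ties,
                "Mean In/Out degree": round(self.mean_degree, 5),
                "Minimum outdegree": self.min_outdegree,
                "Maximum outdegree": self.max_outdegree,
                "Minimum indegree": self.min_indegree,
                "Maximum indegree": self.max_indegree,
                "Number of reciprocated pairs": self.n_reciprocated_pairs,
            }
        )


def n_tie_variables(n: int) -> int:
    """Number of tie variables in a two-layer digraph excluding self-nominations."""
    return 2 * n * (n - 1)


def _roster_index(roster: Sequence) -> dict:
    idx = {a: k for k, a in enumerate(roster)}
    if len(idx) != len(roster):
        raise RosterError("duplicate actor ids in roster")
    return idx


def _iter_edges(edge_table) -> Iterable[tuple]:
    if isinstance(edge_table, pd.DataFrame):
        cols = list(edge_table.columns)
        if "sender" in cols and "receiver" in cols:
            return list(zip(edge_table["sender"], edge_table["receiver"]))
        return [tuple(r) for r in edge_table.iloc[:, :2].itertuples(index=False)]
    return [(s, r) for s, r in edge_table]


def load_layer(edge_table, roster: Sequence) -> np.ndarray:
    """Build a binary adjacency layer from (sender, receiver) nominations.

    Duplicate nominations collapse to a single tie. A self-nomination is a
    survey artefact, not a tie: the row is dropped with a warning. An actor id
    absent from the roster is a fatal input error.
    """
    idx = _roster_index(roster)
    n = len(roster)
    layer = np.zeros((n, n), dtype=np.uint8)
    for sender, receiver in _iter_edges(edge_table):
        for who in (sender, receiver):
            if who not in idx:
                raise RosterError(f"unknown actor id {who!r} in edge list")
        if sender == receiver:
            warnings.warn(
                f"self-nomination by actor {sender!r} dropped", stacklevel=2
            )
            continue
        layer[idx[sender], idx[receiver]] = 1
    return layer


def merge_dislike_items(item_a, item_b, roster: Sequence) -> np.ndarray:
    """Union of two nomination items: a tie exists if either item nominates.

    Mirrors the instrument design where two dislike questions are merged with
    either/or semantics into one dislike layer.
    """
    a = load_layer(item_a, roster)
    b = load_layer(item_b, roster)
    return np.maximum(a, b)


def subnetwork_by_group(
    g: TwoLayerDigraph, attrs: ActorTable, group
) -> tuple[TwoLayerDigraph, ActorTable]:
    """Induced subgraph (both layers) on actors with the given gender label.

    Cross-group ties are discarded; attributes are subset and re-aligned.
    """
    mask = np.asarray([lab == group for lab in attrs.gender])
    if not mask.any():
        raise RosterError(f"no actors with gender label {group!r}")
    keep = np.flatnonzero(mask)
    ids = tuple(attrs.actor_ids[k] for k in keep)
    sub_g = TwoLayerDigraph(
        F=g.F[np.ix_(keep, keep)], D=g.D[np.ix_(keep, keep)], actor_ids=ids
    )
    sub_a = ActorTable(
        pwb=attrs.pwb[keep],
        smf=attrs.smf[keep],
        ses=attrs.ses[keep],
        gender=attrs.gender[keep],
        actor_ids=ids,
    )
    return sub_g, sub_a


def summarize_layer(layer: np.ndarray, n: int | None = None) -> NetworkSummary:
    """Descriptive statistics for one directed layer.

    density = ties / n(n-1); mean degree = ties / n (identical for in- and
    out-degree since every tie has one sender and one receiver).
    """
    layer = np.asarray(layer)
    if n is None:
        n = layer.shape[0]
    if n < 2:
        raise ValueError("a directed layer needs at least 2 actors")
    n_ties = int(layer.sum())
    outdeg = layer.sum(axis=1)
    indeg = layer.sum(axis=0)
    return NetworkSummary(
        n_actors=n,
        density=n_ties / (n * (n - 1)),
        n_ties=n_ties,
        mean_degree=n_ties / n,
        min_outdegree=int(outdeg.min()),
        max_outdegree=int(outdeg.max()),
        min_indegree=int(indeg.min()),
        max_indegree=int(indeg.max()),
        n_reciprocated_pairs=count_reciprocated_pairs(layer),
    )


def count_reciprocated_pairs(layer: np.ndarray) -> int:
    """Unordered pairs {i,j} with ties in both directions within one layer."""
    layer = np.asarray(layer)
    return int((layer * layer.T).sum()) // 2


def count_exchange_pairs(F: np.ndarray, D: np.ndarray) -> int:
    """Ordered pairs (i, j) where i befriends j while j dislikes i.

    Counting is over ORDERED pairs: "i befriends j, j dislikes i" and its
    mirror are distinct events, so a dyad dissonant in both orientations
    contributes 2. This matches the cross-layer exchange statistic the model
    uses (see :mod:`dissonet.effects`).
    """
    F = np.asarray(F)
    D = np.asarray(D)
    if F.shape != D.shape:
        raise ValueError("layers must cover the same actor set")
    return int((F * D.T).sum())


@dataclass(frozen=True)
class MixingProportions:
    """Tie proportions by sender/receiver gender; empty when the layer has no ties."""

    n_ties: int
    percent: Mapping[str, float] | None

    @property
    def defined(self) -> bool:
        return self.percent is not None


def mixing_proportions(
    layer: np.ndarray, gender: Sequence, girl="girl", boy="boy"
) -> MixingProportions:
    """Percent of ties in each of girl-girl, boy-boy, girl-to-boy, boy-to-girl."""
    layer = np.asarray(layer)
    gender = np.asarray(gender, dtype=object)
    senders, receivers = np.nonzero(layer)
    n_ties = len(senders)
    if n_ties == 0:
        return MixingProportions(n_ties=0, percent=None)
    keys = {
        (girl, girl): "girl-girl",
        (boy, boy): "boy-boy",
        (girl, boy): "girl-to-boy",
        (boy, girl): "boy-to-girl",
    }
    counts = dict.fromkeys(keys.values(), 0)
    for s, r in zip(senders, receivers):
        counts[keys[(gender[s], gender[r])]] += 1
    percent = {k: 100.0 * v / n_ties for k, v in counts.items()}
    return MixingProportions(n_ties=n_ties, percent=percent)


def pooled_t(
    mean1: float, sd1: float, n1: int, mean2: float, sd2: float, n2: int
) -> tuple[float, int]:
    """Two-sample pooled-variance t statistic and its degrees of freedom.

    Operates on summary statistics (means, SDs, group sizes) so published
    group summaries can be checked directly.
    """
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs n >= 2")
    if sd1 < 0 or sd2 < 0:
        raise ValueError("standard deviations must be non-negative")
    df = n1 + n2 - 2
    sp2 = ((n1 - 1) * sd1**2 + (n2 - 1) * sd2**2) / df
    if sp2 <= 0:
        raise ValueError("zero pooled variance: t undefined")
    t = (mean1 - mean2) / np.sqrt(sp2 * (1 / n1 + 1 / n2))
    return float(t), df


# ---------------------------------------------------------------------------
# File I/O: comma-separated roster dialects
# ---------------------------------------------------------------------------

def read_edge_list(path) -> pd.DataFrame:
    """Read a `sender,receiver` nomination file (one nomination per row)."""
    df = pd.read_csv(path, dtype=str)
    missing = {"sender", "receiver"} - set(df.columns)
    if missing:
        raise RosterError(f"{path}: missing columns {sorted(missing)}")
    return df


def read_attribute_table(path) -> ActorTable:
    """Read an `id,gender,pwb,smf,ses` attribute file (complete cases only)."""
    df = pd.read_csv(path, dtype={"id": str})
    missing = {"id", "gender", "pwb", "smf", "ses"} - set(df.columns)
    if missing:
        raise RosterError(f"{path}: missing columns {sorted(missing)}")
    if df.isna().any().any():
        raise RosterError(f"{path}: missing values are not permitted")
    return ActorTable(
        pwb=df["pwb"].to_numpy(float),
        smf=df["smf"].to_numpy(float),
        ses=df["ses"].to_numpy(float),
        gender=df["gender"].to_numpy(object),
        actor_ids=tuple(df["id"]),
    )


def write_edge_list(layer: np.ndarray, actor_ids: Sequence, path) -> None:
    senders, receivers = np.nonzero(np.asarray(layer))
    pd.DataFrame(
        {
            "sender": [actor_ids[s] for s in senders],
            "receiver": [actor_ids[r] for r in receivers],
        }
    ).to_csv(path, index=False)


def write_attribute_table(attrs: ActorTable, path) -> None:
    attrs.to_frame().to_csv(path, index=False)


def load_cohort(
    friendship_path, dislike_path, attribute_path, dislike_path_b=None
) -> tuple[TwoLayerDigraph, ActorTable]:
    """Assemble a two-layer cohort from roster CSV files.

    When two dislike item files are given they are merged with either/or
    semantics; otherwise the single file is the dislike layer.
    """
    attrs = read_attribute_table(attribute_path)
    roster = list(attrs.actor_ids)
    F = load_layer(read_edge_list(friendship_path), roster)
    if dislike_path_b is not None:
        D = merge_dislike_items(
            read_edge_list(dislike_path), read_edge_list(dislike_path_b), roster
        )
    else:
        D = load_layer(read_edge_list(dislike_path), roster)
    g = TwoLayerDigraph(F=F, D=D, actor_ids=tuple(roster))
    return g, attrs
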