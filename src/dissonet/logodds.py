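"""Conditional log-odds of a relationally dissonant dyad by actor attributes.

A dissonant dyad is the cross-layer pattern "i befriends j while j dislikes
i". Because the model is an exponential family, adding the two ties of the
pattern to a graph changes the log-probability by θ·Δz, so the
attribute-DEPENDENT part of that change — the part that varies with the two
actors' scores — is a weighted sum of the attribute effects:

    L(a_i, a_j) = s_F·a_i + r_F·a_j + s_D·a_j + r_D·a_i
                  − (h_F + h_D)·|a_i − a_j| + m·(a_i + a_j)

where s/r/h are the sender, receiver and homophily weights of the friendship
(F) and dislike (D) layers, m the mutual-sum-exchange weight, a_i the score
of the friendship sender (= dislike receiver) and a_j the score of the
friendship receiver (= dislike sender). Homophily is parameterised as the
negative absolute attribute difference, hence the minus sign; attributes
enter uncentered.

These values omit the attribute-independent structural contribution
(densities, reciprocity, the bare exchange count), which is constant across
attribute configurations of the same dyad; they are contrasts of dyad-level
log-odds across attribute values, not full tie log-probabilities.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd

from .estimator import EstimationResult

__all__ = [
    "AttributeEffects",
    "DissonantDyad",
    "dissonance_log_odds",
    "logodds_table",
    "extract_attribute_effects",
    "round_half_away",
]


@dataclass(frozen=True)
class AttributeEffects:
    """The seven attribute-effect weights entering the dissonance log-odds."""

    sender_F: float
    receiver_F: float
    sender_D: float
    receiver_D: float
    homophily_F: float
    homophily_D: float
    mutual_sum_exchange: float

    def __post_init__(self):
        for name in (
            "sender_F",
            "receiver_F",
            "sender_D",
            "receiver_D",
            "homophily_F",
            "homophily_D",
            "mutual_sum_exchange",
        ):
            if not math.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")


@dataclass(frozen=True)
class DissonantDyad:
    """Attribute scores of the two actors in a dissonant dyad.

    a_i belongs to the friendship sender (who receives the dislike tie),
    a_j to the friendship receiver (who sends the dislike tie).
    """

    a_i: float
    a_j: float


def dissonance_log_odds(eff: AttributeEffects, d: DissonantDyad) -> float:
    """Attribute-dependent conditional log-odds of the dissonant pattern."""
    return (
        eff.sender_F * d.a_i
        + eff.receiver_F * d.a_j
        + eff.sender_D * d.a_j
        + eff.receiver_D * d.a_i
        - (eff.homophily_F + eff.homophily_D) * abs(d.a_i - d.a_j)
        + eff.mutual_sum_exchange * (d.a_i + d.a_j)
    )


def round_half_away(x: float, decimals: int = 1) -> float:
    """Round half away from zero (the convention of printed report tables)."""
    scale = 10.0**decimals
    return math.copysign(math.floor(abs(x) * scale + 0.5), x) / scale


def logodds_table(eff: AttributeEffects, low: float, high: float) -> pd.DataFrame:
    """Four-configuration dyad table over a low and a high attribute value.

    Rows: A (both low), B (friendship sender low, receiver high),
    C (both high), D (friendship sender high, receiver low). Columns lay out
    the scores by network role: the friendship sender is the dislike
    receiver and vice versa. Log-odds are reported rounded to one decimal
    and unrounded.
    """
    if low > high:
        raise ValueError("low must be <= high")
    configs = {"A": (low, low), "B": (low, high), "C": (high, high), "D": (high, low)}
    rows = []
    for label, (a_i, a_j) in configs.items():
        lo = dissonance_log_odds(eff, DissonantDyad(a_i=a_i, a_j=a_j))
        rows.append(
            {
                "configuration": label,
                "friendship_sender": a_i,
                "friendship_receiver": a_j,
                "dislike_sender": a_j,
                "dislike_receiver": a_i,
                "log_odds": round_half_away(lo, 1),
                "log_odds_unrounded": lo,
            }
        )
    return pd.DataFrame(rows)


def extract_attribute_effects(r: EstimationResult, attribute: str) -> AttributeEffects:
    """Pull the seven attribute-effect weights for one attribute from a fit.

    Requires sender/receiver/homophily on both layers plus the
    mutual-sum-exchange effect; a missing component is a contract error
    naming the effect.
    """
    wanted = {
        "sender_F": ("sender", "F", attribute),
        "receiver_F": ("receiver", "F", attribute),
        "sender_D": ("sender", "D", attribute),
        "receiver_D": ("receiver", "D", attribute),
        "homophily_F": ("difference_homophily", "F", attribute),
        "homophily_D": ("difference_homophily", "D", attribute),
        "mutual_sum_exchange": ("mutual_sum_exchange", "cross", attribute),
    }
    values = {}
    for field_name, (kind, layer, attr) in wanted.items():
        try:
            k = r.spec.index_of(kind, layer, attr)
        except KeyError:
            raise KeyError(
                f"fitted model lacks the {kind}[{layer}] ({attr}) effect "
                f"needed for the dissonance log-odds"
            ) from None
        values[field_name] = float(r.theta[k])
    return AttributeEffects(**values)
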