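"""Shared fixtures and independent brute-force oracles.

The oracle functions here recompute every configuration statistic with naive
nested loops straight from the defining formulas. They deliberately share no
code with the package's vectorised/compiled implementations so that
agreement between the two is meaningful.
"""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from dissonet import ActorTable, TwoLayerDigraph


@pytest.fixture
def rng():
    return np.random.default_rng(20260926)


def random_two_layer(rng, n, p_f=0.3, p_d=0.2):
    F = (rng.random((n, n)) < p_f).astype(np.uint8)
    D = (rng.random((n, n)) < p_d).astype(np.uint8)
    np.fill_diagonal(F, 0)
    np.fill_diagonal(D, 0)
    return TwoLayerDigraph(F=F, D=D)


def random_attrs(rng, n, gender="boy"):
    return ActorTable(
        pwb=rng.integers(14, 85, n).astype(float),
        smf=rng.integers(0, 27, n).astype(float),
        ses=rng.integers(0, 2, n).astype(float),
        gender=np.full(n, gender, dtype=object),
    )


# ---------------------------------------------------------------------------
# naive loop oracles
# ---------------------------------------------------------------------------

def oracle_statistic(g, attrs, e):
    """Triple-loop recomputation of one effect straight from its formula."""
    n = g.n
    F, D = g.F, g.D
    if e.kind == "exchange":
        return float(sum(F[i, j] * D[j, i] for i in range(n) for j in range(n) if i != j))
    if e.kind == "mutual_sum_exchange":
        a = attrs.attribute(e.attribute)
        return float(
            sum(
                F[i, j] * D[j, i] * (a[i] + a[j])
                for i in range(n)
                for j in range(n)
                if i != j
            )
        )
    M = F if e.layer == "F" else D
    lam = e.lam
    if e.kind == "arc":
        return float(sum(M[i, j] for i in range(n) for j in range(n) if i != j))
    if e.kind == "reciprocity":
        return float(sum(M[i, j] * M[j, i] for i in range(n) for j in range(i + 1, n)))
    if e.kind == "two_path":
        return float(
            sum(
                M[i, j] * M[j, k]
                for i, j, k in itertools.permutations(range(n), 3)
            )
        )
    if e.kind in ("alt_in_star", "alt_out_star"):
        total = 0.0
        for j in range(n):
            q = sum(M[i, j] for i in range(n)) if e.kind == "alt_in_star" else sum(
                M[j, i] for i in range(n)
            )
            total += lam**2 * ((1 - 1 / lam) ** q + q / lam - 1)
        return float(total)
    if e.kind in ("alt_transitive_triangle", "alt_two_path"):
        total = 0.0
        for i in range(n):
            for j in range(n):
                if i == j:
                    continue
                p = sum(M[i, k] * M[k, j] for k in range(n) if k != i and k != j)
                damp = lam * (1 - (1 - 1 / lam) ** p)
                total += M[i, j] * damp if e.kind == "alt_transitive_triangle" else damp
        return float(total)
    a = attrs.attribute(e.attribute)
    if e.kind == "sender":
        return float(sum(M[i, j] * a[i] for i in range(n) for j in range(n) if i != j))
    if e.kind == "receiver":
        return float(sum(M[i, j] * a[j] for i in range(n) for j in range(n) if i != j))
    if e.kind == "difference_homophily":
        return -float(
            sum(M[i, j] * abs(a[i] - a[j]) for i in range(n) for j in range(n) if i != j)
        )
    if e.kind == "mutual_product":
        return float(
            sum(
                M[i, j] * M[j, i] * a[i] * a[j]
                for i in range(n)
                for j in range(i + 1, n)
            )
        )
    raise AssertionError(e.kind)


def oracle_statistics(g, attrs, spec):
    return np.array([oracle_statistic(g, attrs, e) for e in spec])


def enumerate_two_layer_states(n):
    """All 2^(2n(n-1)) two-layer digraphs on n actors (use only for n=3)."""
    pairs = [(i, j) for i in range(n) for j in range(n) if i != j]
    m = len(pairs)
    for bits in itertools.product((0, 1), repeat=2 * m):
        F = np.zeros((n, n), np.uint8)
        D = np.zeros((n, n), np.uint8)
        for k, (i, j) in enumerate(pairs):
            F[i, j] = bits[k]
            D[i, j] = bits[m + k]
        yield TwoLayerDigraph(F=F, D=D)
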