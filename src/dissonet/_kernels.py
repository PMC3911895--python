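"""Compiled inner loops for Metropolis sampling.

The model specification is packed into flat arrays (integer effect-kind and
layer codes, per-effect attribute row indices, smoothing constants) so that a
single jitted kernel can evaluate the change-statistic vector of any model
and advance the chain without returning to Python between proposals. Kind
and layer codes are defined in :mod:`dissonet.effects` (``KIND_CODES``,
``LAYER_CODES``).

The deltas computed here must agree exactly with
:func:`dissonet.effects.change_statistics`; the test suite audits both
against brute-force recomputation of full statistics.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["delta_vector", "advance_chain"]


@njit(cache=True)
def delta_vector(F, D, A, kinds, layers, attr_idx, lams, i, j, lyr, out):
    """Presence-minus-absence change statistics for tie (i, j) on layer lyr.

    F, D are float 0/1 matrices (mutated transiently, restored before
    return); A stacks attribute vectors row-wise; out receives the delta.
    """
    n = F.shape[0]
    if lyr == 0:
        X = F
        O = D
    else:
        X = D
        O = F
    xij = X[i, j]
    X[i, j] = 0.0  # all local counts are taken in the tie-absent state

    need_p = False
    for e in range(kinds.shape[0]):
        if (kinds[e] == 5 or kinds[e] == 6) and layers[e] == lyr:
            need_p = True
    p_row = np.zeros(0)
    p_col = np.zeros(0)
    if need_p:
        # p_row[m] = #{k: i->k->m}; p_col[m] = #{k: m->k->j}
        p_row = np.zeros(n)
        p_col = np.zeros(n)
        for k in range(n):
            if X[i, k] > 0.5:
                for m in range(n):
                    if X[k, m] > 0.5:
                        p_row[m] += 1.0
            if X[k, j] > 0.5:
                for m in range(n):
                    if X[m, k] > 0.5:
                        p_col[m] += 1.0

    for e in range(kinds.shape[0]):
        k = kinds[e]
        if k == 7:  # exchange: F_ij D_ji completed by the reverse cross tie
            out[e] = O[j, i]
            continue
        if k == 12:  # mutual sum exchange
            a = attr_idx[e]
            out[e] = O[j, i] * (A[a, i] + A[a, j])
            continue
        if layers[e] != lyr:
            out[e] = 0.0
            continue
        if k == 0:  # arc
            out[e] = 1.0
        elif k == 1:  # reciprocity
            out[e] = X[j, i]
        elif k == 2:  # two-path
            s = 0.0
            for m in range(n):
                s += X[j, m] + X[m, i]
            out[e] = s - 2.0 * X[j, i]
        elif k == 3:  # alternating in-star
            q = 0.0
            for m in range(n):
                q += X[m, j]
            lam = lams[e]
            out[e] = lam * (1.0 - (1.0 - 1.0 / lam) ** q)
        elif k == 4:  # alternating out-star
            q = 0.0
            for m in range(n):
                q += X[i, m]
            lam = lams[e]
            out[e] = lam * (1.0 - (1.0 - 1.0 / lam) ** q)
        elif k == 5:  # alternating transitive triangle
            lam = lams[e]
            r = 1.0 - 1.0 / lam
            s = lam * (1.0 - r ** p_row[j])  # the closing tie's own term
            for m in range(n):
                if X[i, m] > 0.5 and X[j, m] > 0.5:
                    s += r ** p_row[m]
                if X[m, j] > 0.5 and X[m, i] > 0.5:
                    s += r ** p_col[m]
            out[e] = s
        elif k == 6:  # alternating two-path
            lam = lams[e]
            r = 1.0 - 1.0 / lam
            s = 0.0
            for m in range(n):
                if X[j, m] > 0.5:
                    s += r ** p_row[m]
                if X[m, i] > 0.5:
                    s += r ** p_col[m]
            # remove the invalid diagonal pairs (i, i) and (j, j)
            if X[j, i] > 0.5:
                s -= r ** p_row[i] + r ** p_col[j]
            out[e] = s
        elif k == 8:  # sender
            out[e] = A[attr_idx[e], i]
        elif k == 9:  # receiver
            out[e] = A[attr_idx[e], j]
        elif k == 10:  # difference homophily (negative abs difference)
            out[e] = -abs(A[attr_idx[e], i] - A[attr_idx[e], j])
        elif k == 11:  # mutual product
            out[e] = X[j, i] * A[attr_idx[e], i] * A[attr_idx[e], j]
        else:
            out[e] = np.nan

    X[i, j] = xij


@njit(cache=True)
def advance_chain(F, D, A, kinds, layers, attr_idx, lams, theta, z, n_steps, seed):
    """Run n_steps single-toggle Metropolis proposals, updating F, D and z
    in place. Returns the number of accepted proposals.

    Proposal: uniform over the 2n(n-1) tie variables. Acceptance probability
    min(1, exp(theta . dz)) with dz the signed change of the statistic
    vector for the proposed toggle.
    """
    np.random.seed(seed)
    n = F.shape[0]
    p = theta.shape[0]
    delta = np.empty(p)
    accepted = 0
    for _ in range(n_steps):
        lyr = np.random.randint(2)
        i = np.random.randint(n)
        j = np.random.randint(n - 1)
        if j >= i:
            j += 1
        delta_vector(F, D, A, kinds, layers, attr_idx, lams, i, j, lyr, delta)
        if lyr == 0:
            present = F[i, j] > 0.5
        else:
            present = D[i, j] > 0.5
        lr = 0.0
        for e in range(p):
            lr += theta[e] * delta[e]
        if present:
            lr = -lr
        if lr >= 0.0 or np.random.random() < np.exp(lr):
            accepted += 1
            if present:
                if lyr == 0:
                    F[i, j] = 0.0
                else:
                    D[i, j] = 0.0
                for e in range(p):
                    z[e] -= delta[e]
            else:
                if lyr == 0:
                    F[i, j] = 1.0
                else:
                    D[i, j] = 1.0
                for e in range(p):
                    z[e] += delta[e]
    return accepted
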