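"""Numba kernels for the branched-chain propagator recursion.

These loops are the per-iteration hot path of the SCF solver: forward and
complementary propagators along the graft main chain, shared side-arm
propagators per distinct arm length, and per-rank normalized segment
densities.  The maths mirrors the pure-python reference in
``brushscf.scf`` (``propagate`` / ``compute_density``); agreement between
the two paths is asserted in the test suite.

Conventions: arrays are indexed 0..zmax-1 for shells z = 1..zmax; the graft
is anchored in shell 1 (index 0).  Propagators are renormalized rank by
rank to avoid under/overflow, with log-norms accumulated into lnQ.
Densities are normalized per rank (each rank of the chain is somewhere:
sum_z L * n_s = 1), which makes the total monomer count exact by
construction and independent of the renormalization.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["scf_density"]


@njit(cache=True)
def _step(f, li, ll, lo, out):
    """<f>(z) with reflecting boundaries at the axis and the outer wall."""
    zmax = f.size
    for z in range(zmax):
        v = ll[z] * f[z]
        if z > 0:
            v += li[z] * f[z - 1]
        else:
            v += li[0] * f[0]
        if z < zmax - 1:
            v += lo[z] * f[z + 1]
        else:
            v += lo[zmax - 1] * f[zmax - 1]
        out[z] = v
    return out


@njit(cache=True)
def scf_density(G, L, li, ll, lo, arm_len):
    """Segment densities and log-partition-function of one grafted comb.

    Parameters: Boltzmann weights ``G = exp(-u)`` per shell, shell areas
    ``L``, step weights, and ``arm_len[s]`` the arm length at main-chain
    rank s+1 (0 = no arm).

    Returns ``(countL, endL, fbL, lnQ)`` where ``countL[z]`` is the mean
    number of graft monomers in shell z (sums to N), ``endL`` / ``fbL``
    the distributions of the main-chain free end / first branch point
    (each sums to 1; ``fbL`` is zero if the graft has no arms), and
    ``lnQ`` the log partition function per anchor site.
    """
    zmax = G.size
    Nb = arm_len.size

    # distinct positive arm lengths (tiny set; insertion order)
    uniq = np.empty(Nb, dtype=np.int64)
    n_uniq = 0
    for s in range(Nb):
        if arm_len[s] > 0:
            found = False
            for j in range(n_uniq):
                if uniq[j] == arm_len[s]:
                    found = True
                    break
            if not found:
                uniq[n_uniq] = arm_len[s]
                n_uniq += 1
    max_len = 0
    for j in range(n_uniq):
        if uniq[j] > max_len:
            max_len = uniq[j]

    # ---- side-arm forward propagators, one table per distinct length ----
    # qs[j, k] = weight of a free arm of k+1 segments ending at shell z,
    # renormalized per k; c_arm[j] = accumulated log-norm of the full arm.
    qs = np.zeros((max(n_uniq, 1), max(max_len, 1), zmax))
    W = np.ones((max(n_uniq, 1), zmax))
    c_arm = np.zeros(max(n_uniq, 1))
    tmp = np.empty(zmax)
    for j in range(n_uniq):
        ln = uniq[j]
        for z in range(zmax):
            qs[j, 0, z] = G[z]
        m = np.max(qs[j, 0])
        qs[j, 0] /= m
        c_arm[j] = np.log(m)
        for k in range(1, ln):
            _step(qs[j, k - 1], li, ll, lo, tmp)
            for z in range(zmax):
                qs[j, k, z] = G[z] * tmp[z]
            m = np.max(qs[j, k])
            qs[j, k] /= m
            c_arm[j] += np.log(m)
        _step(qs[j, ln - 1], li, ll, lo, W[j])

    # map rank -> arm group index (-1: none)
    group = np.full(Nb, -1, dtype=np.int64)
    for s in range(Nb):
        if arm_len[s] > 0:
            for j in range(n_uniq):
                if uniq[j] == arm_len[s]:
                    group[s] = j
                    break

    # ---- main-chain forward propagator (anchored in shell 1) ----
    q = np.zeros((Nb, zmax))
    prev_avg = np.zeros((Nb, zmax))
    prev_avg[0, 0] = 1.0
    c_fwd = 0.0
    j = group[0]
    q[0, 0] = G[0] * (W[j, 0] if j >= 0 else 1.0)
    if j >= 0:
        c_fwd += c_arm[j]
    m = np.max(q[0])
    q[0] /= m
    c_fwd += np.log(m)
    for s in range(1, Nb):
        _step(q[s - 1], li, ll, lo, prev_avg[s])
        j = group[s]
        if j >= 0:
            for z in range(zmax):
                q[s, z] = G[z] * W[j, z] * prev_avg[s, z]
            c_fwd += c_arm[j]
        else:
            for z in range(zmax):
                q[s, z] = G[z] * prev_avg[s, z]
        m = np.max(q[s])
        q[s] /= m
        c_fwd += np.log(m)

    lnQ = 0.0
    for z in range(zmax):
        lnQ += L[z] * q[Nb - 1, z]
    lnQ = np.log(lnQ) + c_fwd - np.log(L[0])

    # ---- complementary propagator from the free end ----
    # sc[s] = <qc(s+2)> seen by rank s+1 (sc of the last rank is 1).
    sc = np.zeros((Nb, zmax))
    sc[Nb - 1] = 1.0
    qc = np.empty(zmax)
    j = group[Nb - 1]
    for z in range(zmax):
        qc[z] = G[z] * (W[j, z] if j >= 0 else 1.0)
    qc /= np.max(qc)
    for s in range(Nb - 2, -1, -1):
        _step(qc, li, ll, lo, sc[s])
        j = group[s]
        if j >= 0:
            for z in range(zmax):
                qc[z] = G[z] * W[j, z] * sc[s, z]
        else:
            for z in range(zmax):
                qc[z] = G[z] * sc[s, z]
        qc /= np.max(qc)

    # ---- per-rank normalized main-chain densities ----
    countL = np.zeros(zmax)
    endL = np.zeros(zmax)
    fbL = np.zeros(zmax)
    rho = np.empty(zmax)
    fb_rank = -1
    for s in range(Nb):
        if arm_len[s] > 0:
            fb_rank = s
            break
    for s in range(Nb):
        w = 0.0
        for z in range(zmax):
            rho[z] = q[s, z] * sc[s, z] * L[z]
            w += rho[z]
        for z in range(zmax):
            countL[z] += rho[z] / w
        if s == Nb - 1:
            for z in range(zmax):
                endL[z] = rho[z] / w
        if s == fb_rank:
            for z in range(zmax):
                fbL[z] = rho[z] / w

    # ---- arm densities, complementary arm propagated once per length ----
    # E_tot = sum over branches of the branch-site weight of everything
    # except the arm, each branch normalized by its own partition sum.
    rbar = np.empty(zmax)
    for j in range(n_uniq):
        ln = uniq[j]
        p = 0
        E = np.zeros(zmax)
        for s in range(Nb):
            if group[s] == j:
                p += 1
                nb = 0.0
                for z in range(zmax):
                    nb += L[z] * G[z] * W[j, z] * prev_avg[s, z] * sc[s, z]
                for z in range(zmax):
                    E[z] += G[z] * prev_avg[s, z] * sc[s, z] / nb
        _step(E, li, ll, lo, rbar)
        for k in range(ln - 1, -1, -1):
            w = 0.0
            for z in range(zmax):
                rho[z] = qs[j, k, z] * rbar[z] * L[z]
                w += rho[z]
            for z in range(zmax):
                countL[z] += p * rho[z] / w
            if k > 0:
                for z in range(zmax):
                    rho[z] = G[z] * rbar[z]
                _step(rho, li, ll, lo, rbar)

    return countL, endL, fbL, lnQ
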