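"""Propagator engine against an exhaustive walk-enumeration oracle.

The oracle enumerates every lattice walk of the (branched) chain
explicitly — weights are products of per-segment Boltzmann factors and
the step weights of the receiving shell, with reflecting boundaries —
and computes rank-resolved densities and the partition function by brute
force.  It shares no code with the propagator recursion.
"""

from __future__ import annotations

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from brushscf import (
    BrushParameters,
    GraftArchitecture,
    build_lattice,
    compute_density,
    propagate,
)
from brushscf.architecture import segment_map
from brushscf.scf import SCFNumericalError
from brushscf._kernels import scf_density


def step_weight(lat, to: int, frm: int) -> float:
    """Weight of a step from shell index ``frm`` into shell index ``to``."""
    w = 0.0
    if to == frm - 1:
        w = lat.lam_out[to]
    elif to == frm + 1:
        w = lat.lam_in[to]
    elif to == frm:
        w = lat.lam_lat[to]
        if frm == 0:
            w += lat.lam_in[0]           # reflection at the axis
        if frm == lat.zmax - 1:
            w += lat.lam_out[lat.zmax - 1]  # reflection at the wall
    return w


def enumerate_chain(lat, u, arm_length):
    """Brute-force rank densities and partition function of one graft.

    ``arm_length[s]`` is the arm length at main-chain rank s+1.  Returns
    (Q per anchor site, main-rank density n[s, z], arm density
    a[(rank, k), z]) with every rank distribution summing to 1.
    """
    zmax = lat.zmax
    G = np.exp(-np.asarray(u, float))
    Nb = len(arm_length)
    shells = range(zmax)
    Q = 0.0
    n = np.zeros((Nb, zmax))
    arms = {(s, k): np.zeros(zmax) for s in range(Nb) for k in range(arm_length[s])}

    def arm_walks(attach_z, length):
        """Yield (positions, weight) of arm walks; last step enters the branch site."""
        if length == 0:
            yield (), 1.0
            return
        for pos in itertools.product(shells, repeat=length):
            w = G[pos[0]]
            ok = True
            for k in range(1, length):
                sw = step_weight(lat, pos[k], pos[k - 1])
                if sw == 0.0:
                    ok = False
                    break
                w *= G[pos[k]] * sw
            if not ok:
                continue
            sw = step_weight(lat, attach_z, pos[-1])
            if sw == 0.0:
                continue
            yield pos, w * sw

    for walk in itertools.product(shells, repeat=Nb - 1):
        walk = (0,) + walk  # anchored in shell 1
        w = G[0]
        ok = True
        for s in range(1, Nb):
            sw = step_weight(lat, walk[s], walk[s - 1])
            if sw == 0.0:
                ok = False
                break
            w *= G[walk[s]] * sw
        if not ok:
            continue
        # attach arms: sum over arm conformations, tracking arm densities
        arm_sums = []
        arm_dists = []
        for s in range(Nb):
            if arm_length[s] == 0:
                arm_sums.append(1.0)
                arm_dists.append(None)
                continue
            tot = 0.0
            dist = np.zeros((arm_length[s], zmax))
            for pos, aw in arm_walks(walk[s], arm_length[s]):
                tot += aw
                for k, z in enumerate(pos):
                    dist[k, z] += aw
            arm_sums.append(tot)
            arm_dists.append(dist)
        w_full = w * np.prod(arm_sums) * lat.L[walk[-1]]
        Q += w_full
        for s in range(Nb):
            n[s, walk[s]] += w_full
            if arm_dists[s] is not None:
                arms[(s, 0)]  # keys exist
                for k in range(arm_length[s]):
                    arms[(s, k)] += w_full / arm_sums[s] * arm_dists[s][k]
    for s in range(Nb):
        n[s] /= Q
        for k in range(arm_length[s]):
            arms[(s, k)] /= Q
    return Q / lat.L[0], n, arms


CASES = [
    # (architecture kwargs, zmax) -- linear and one-branch chains <= 4 segments
    (dict(P1=1, P2=0, m1=1, m2=0, n1=0, n2=0), 4),   # 1 segment
    (dict(P1=1, P2=0, m1=3, m2=0, n1=0, n2=0), 6),   # 3-segment linear
    (dict(P1=1, P2=0, m1=4, m2=0, n1=0, n2=0), 7),   # 4-segment linear
    (dict(P1=1, P2=0, m1=2, m2=0, n1=1, n2=0), 6),   # 2 + 1-segment branch
    (dict(P1=1, P2=0, m1=2, m2=0, n1=2, n2=0), 5),   # 2 + 2-segment branch
    (dict(P1=2, P2=0, m1=1, m2=0, n1=1, n2=0), 5),   # branches at ranks 1 and 2
]


@pytest.mark.parametrize("kwargs, zmax", CASES)
@pytest.mark.parametrize("field", ["zero", "random"])
def test_enumeration_oracle_equivalence(kwargs, zmax, field):
    """Rank densities and lnQ match exhaustive enumeration to 1e-12."""
    arch = GraftArchitecture(**kwargs)
    lat = build_lattice(zmax)
    rng = np.random.default_rng(42)
    u = np.zeros(zmax) if field == "zero" else rng.normal(0.0, 0.8, zmax)
    smap = segment_map(arch)

    Q_o, n_o, arms_o = enumerate_chain(lat, u, smap.arm_length)

    props = propagate(arch, lat, u)
    dens = compute_density(props, sigma=1.0)
    assert props.lnQ == pytest.approx(np.log(Q_o), abs=1e-12)
    n_main = dens.phi_main * lat.L  # sigma = 1 -> per-rank distributions
    for s in range(smap.backbone_length):
        assert np.max(np.abs(n_main[s] - n_o[s])) < 1e-12
    arm_total_o = sum(arms_o.values()) if arms_o else np.zeros(zmax)
    assert np.max(np.abs(dens.phi_arm * lat.L - arm_total_o)) < 1e-12

    # the accelerated kernel agrees with the same oracle
    countL, endL, fbL, lnQ = scf_density(
        np.exp(-u), lat.L, lat.lam_in, lat.lam_lat, lat.lam_out,
        np.asarray(smap.arm_length, dtype=np.int64),
    )
    assert lnQ == pytest.approx(np.log(Q_o), abs=1e-12)
    assert np.max(np.abs(countL - (n_o.sum(axis=0) + arm_total_o))) < 1e-12
    assert np.max(np.abs(endL - n_o[-1])) < 1e-12


def test_single_segment_zero_field():
    """A one-segment graft sits in shell 1 with lnQ = 0."""
    lat = build_lattice(5)
    arch = GraftArchitecture(P1=1, P2=0, m1=1, m2=0, n1=0, n2=0)
    props = propagate(arch, lat, np.zeros(5))
    dens = compute_density(props, sigma=0.3)
    assert props.lnQ == pytest.approx(0.0, abs=1e-14)
    assert dens.phi[0] * lat.L[0] == pytest.approx(0.3, abs=1e-14)
    assert np.all(dens.phi[1:] == 0)


def test_branched_lnQ_end_symmetry_linear_field():
    """2-segment graft with a 1-segment branch: lnQ from either end agrees."""
    lat = build_lattice(8)
    u = 0.1 * np.arange(8)
    arch = GraftArchitecture(P1=1, P2=0, m1=2, m2=0, n1=1, n2=0)
    props = propagate(arch, lat, u)
    assert props.lnQ == pytest.approx(props.lnQ_reverse, abs=1e-12)


@settings(derandomize=True, max_examples=100)
@given(
    P1=st.integers(1, 3), m1=st.integers(1, 3), n1=st.integers(0, 3),
    P2=st.integers(0, 2), m2=st.integers(1, 2), n2=st.integers(0, 2),
    seed=st.integers(0, 10_000),
)
def test_lnQ_end_symmetry_random_architectures(P1, m1, n1, P2, m2, n2, seed):
    """Partition function is identical computed from the grafted or free end."""
    arch = GraftArchitecture(P1=P1, P2=P2, m1=m1, m2=m2, n1=n1, n2=n2)
    lat = build_lattice(7)
    u = np.random.default_rng(seed).normal(0.0, 1.0, 7)
    props = propagate(arch, lat, u)
    assert props.lnQ == pytest.approx(props.lnQ_reverse, abs=1e-10)


def test_rank_slices_partition_total_density():
    """Per-rank densities (main + arms) sum exactly to the total phi."""
    arch = GraftArchitecture(P1=3, P2=2, m1=2, m2=3, n1=4, n2=2)
    lat = build_lattice(15)
    u = np.random.default_rng(3).normal(0.0, 0.5, 15)
    dens = compute_density(propagate(arch, lat, u), sigma=0.7)
    total = dens.phi_main.sum(axis=0) + dens.phi_arm
    assert np.max(np.abs(total - dens.phi)) < 1e-14
    # mass adds up to N * sigma
    assert np.sum(dens.phi * lat.L) == pytest.approx(
        arch.total_monomers * 0.7, rel=1e-12
    )


def test_kernel_matches_reference_on_random_brush():
    arch = GraftArchitecture(P1=4, P2=3, m1=3, m2=2, n1=5, n2=2)
    lat = build_lattice(20)
    u = np.random.default_rng(11).normal(0.0, 0.7, 20)
    smap = segment_map(arch)
    props = propagate(arch, lat, u)
    dens = compute_density(props, sigma=0.4)
    countL, endL, fbL, lnQ = scf_density(
        np.exp(-u), lat.L, lat.lam_in, lat.lam_lat, lat.lam_out,
        np.asarray(smap.arm_length, dtype=np.int64),
    )
    assert lnQ == pytest.approx(props.lnQ, abs=1e-11)
    assert np.max(np.abs(0.4 * countL / lat.L - dens.phi)) < 1e-12
    assert np.max(np.abs(0.4 * endL / lat.L - dens.end_profile)) < 1e-12
    assert np.max(np.abs(0.4 * fbL / lat.L - dens.first_branch_profile)) < 1e-12


def test_field_derivative_of_lnQ_is_density():
    """d(-lnQ)/du contracted with a perturbation equals sum phi du L / sigma."""
    arch = GraftArchitecture(P1=3, P2=0, m1=2, m2=0, n1=3, n2=0)
    lat = build_lattice(12)
    rng = np.random.default_rng(5)
    u = rng.normal(0.0, 0.4, 12)
    du = rng.normal(0.0, 1.0, 12)
    sigma = 1.0
    dens = compute_density(propagate(arch, lat, u), sigma)
    eps = 1e-6
    lnQ_p = propagate(arch, lat, u + eps * du).lnQ
    lnQ_m = propagate(arch, lat, u - eps * du).lnQ
    lhs = -(lnQ_p - lnQ_m) / (2 * eps)
    rhs = np.sum(dens.phi * du * lat.L) / sigma
    assert lhs == pytest.approx(rhs, rel=1e-6, abs=1e-9)


def test_nonfinite_field_rejected():
    lat = build_lattice(5)
    arch = GraftArchitecture(P1=1, P2=0, m1=2, m2=0, n1=0, n2=0)
    with pytest.raises(SCFNumericalError):
        propagate(arch, lat, np.array([0.0, np.inf, 0, 0, 0]))
    with pytest.raises(SCFNumericalError):
        propagate(arch, lat, np.zeros(4))
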