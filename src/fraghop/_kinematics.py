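"""Internal-coordinate chain building (NeRF) kernels.

The hot loop is written in scalar Python so it can be JIT-compiled by numba
when available; without numba the same code runs as-is, only slower.
"""

from __future__ import annotations

import math

import numpy as np

try:  # optional acceleration
    from numba import njit

    _HAVE_NUMBA = True
except Exception:  # pragma: no cover - exercised only without numba
    _HAVE_NUMBA = False

    def njit(*args, **kwargs):
        if args and callable(args[0]):
            return args[0]

        def wrap(fn):
            return fn

        return wrap


# Geometry parameter vector layout (lengths in Angstrom, angles in radians):
#  0 b(N-CA)   1 b(CA-C)   2 b(C-N)    3 b(C=O)    4 b(CA-CB)
#  5 a(N-CA-C) 6 a(CA-C-N) 7 a(C-N-CA) 8 a(CA-C-O) 9 a(N-CA-CB)
# 10 improper dihedral (C, N, CA, CB)
N_GEOM_PARAMS = 11


@njit(cache=True)
def _place(ax, ay, az, bx, by, bz, cx, cy, cz, bond, theta, chi):
    """Place atom D from reference atoms A, B, C.

    D is bonded to C with length ``bond``, angle B-C-D ``theta`` and
    dihedral A-B-C-D ``chi`` (radians).
    """
    bcx = cx - bx
    bcy = cy - by
    bcz = cz - bz
    nbc = math.sqrt(bcx * bcx + bcy * bcy + bcz * bcz)
    bcx /= nbc
    bcy /= nbc
    bcz /= nbc

    abx = bx - ax
    aby = by - ay
    abz = bz - az
    # n = ab x bc, normalized
    nx = aby * bcz - abz * bcy
    ny = abz * bcx - abx * bcz
    nz = abx * bcy - aby * bcx
    nn = math.sqrt(nx * nx + ny * ny + nz * nz)
    nx /= nn
    ny /= nn
    nz /= nn
    # m = n x bc
    mx = ny * bcz - nz * bcy
    my = nz * bcx - nx * bcz
    mz = nx * bcy - ny * bcx

    d2x = -bond * math.cos(theta)
    d2y = bond * math.sin(theta) * math.cos(chi)
    d2z = bond * math.sin(theta) * math.sin(chi)

    dx = cx + bcx * d2x + mx * d2y + nx * d2z
    dy = cy + bcy * d2x + my * d2y + ny * d2z
    dz = cz + bcz * d2x + mz * d2y + nz * d2z
    return dx, dy, dz


@njit(cache=True)
def build_backbone(phi, psi, omega, geom, backbone, cb):
    """Fill ``backbone`` (L,4,3: N,CA,C,O) and ``cb`` (L,3) in place.

    Angles in radians.  Frame anchor: N1 at the origin, CA1 on +x, C1 in
    the xy-plane (y > 0).  Conventions: phi[i] governs C(i), psi[i] governs
    N(i+1), omega[i] is the peptide dihedral between residues i and i+1
    and governs CA(i+1); phi[0] and the last psi/omega entries do not move
    backbone atoms (the last psi still orients the terminal carbonyl O).
    """
    L = phi.shape[0]
    b_n_ca = geom[0]
    b_ca_c = geom[1]
    b_c_n = geom[2]
    b_c_o = geom[3]
    b_ca_cb = geom[4]
    a_n_ca_c = geom[5]
    a_ca_c_n = geom[6]
    a_c_n_ca = geom[7]
    a_ca_c_o = geom[8]
    a_n_ca_cb = geom[9]
    chi_cb = geom[10]

    backbone[0, 0, 0] = 0.0
    backbone[0, 0, 1] = 0.0
    backbone[0, 0, 2] = 0.0
    backbone[0, 1, 0] = b_n_ca
    backbone[0, 1, 1] = 0.0
    backbone[0, 1, 2] = 0.0
    backbone[0, 2, 0] = b_n_ca - b_ca_c * math.cos(a_n_ca_c)
    backbone[0, 2, 1] = b_ca_c * math.sin(a_n_ca_c)
    backbone[0, 2, 2] = 0.0

    for i in range(1, L):
        # N(i) from N(i-1), CA(i-1), C(i-1) via psi(i-1)
        x, y, z = _place(
            backbone[i - 1, 0, 0], backbone[i - 1, 0, 1], backbone[i - 1, 0, 2],
            backbone[i - 1, 1, 0], backbone[i - 1, 1, 1], backbone[i - 1, 1, 2],
            backbone[i - 1, 2, 0], backbone[i - 1, 2, 1], backbone[i - 1, 2, 2],
            b_c_n, a_ca_c_n, psi[i - 1],
        )
        backbone[i, 0, 0] = x
        backbone[i, 0, 1] = y
        backbone[i, 0, 2] = z
        # CA(i) from CA(i-1), C(i-1), N(i) via omega(i-1)
        x, y, z = _place(
            backbone[i - 1, 1, 0], backbone[i - 1, 1, 1], backbone[i - 1, 1, 2],
            backbone[i - 1, 2, 0], backbone[i - 1, 2, 1], backbone[i - 1, 2, 2],
            backbone[i, 0, 0], backbone[i, 0, 1], backbone[i, 0, 2],
            b_n_ca, a_c_n_ca, omega[i - 1],
        )
        backbone[i, 1, 0] = x
        backbone[i, 1, 1] = y
        backbone[i, 1, 2] = z
        # C(i) from C(i-1), N(i), CA(i) via phi(i)
        x, y, z = _place(
            backbone[i - 1, 2, 0], backbone[i - 1, 2, 1], backbone[i - 1, 2, 2],
            backbone[i, 0, 0], backbone[i, 0, 1], backbone[i, 0, 2],
            backbone[i, 1, 0], backbone[i, 1, 1], backbone[i, 1, 2],
            b_ca_c, a_n_ca_c, phi[i],
        )
        backbone[i, 2, 0] = x
        backbone[i, 2, 1] = y
        backbone[i, 2, 2] = z

    for i in range(L):
        # carbonyl O, anti to the following amide N (psi + pi)
        x, y, z = _place(
            backbone[i, 0, 0], backbone[i, 0, 1], backbone[i, 0, 2],
            backbone[i, 1, 0], backbone[i, 1, 1], backbone[i, 1, 2],
            backbone[i, 2, 0], backbone[i, 2, 1], backbone[i, 2, 2],
            b_c_o, a_ca_c_o, psi[i] + math.pi,
        )
        backbone[i, 3, 0] = x
        backbone[i, 3, 1] = y
        backbone[i, 3, 2] = z
        # CB off CA via the improper dihedral C-N-CA-CB
        x, y, z = _place(
            backbone[i, 2, 0], backbone[i, 2, 1], backbone[i, 2, 2],
            backbone[i, 0, 0], backbone[i, 0, 1], backbone[i, 0, 2],
            backbone[i, 1, 0], backbone[i, 1, 1], backbone[i, 1, 2],
            b_ca_cb, a_n_ca_cb, chi_cb,
        )
        cb[i, 0] = x
        cb[i, 1] = y
        cb[i, 2] = z


def warm_up() -> None:
    """Trigger JIT compilation ahead of timed work (no-op without numba)."""
    phi = np.full(3, math.pi)
    geom = np.array(
        [1.458, 1.525, 1.329, 1.231, 1.521,
         math.radians(111.2), math.radians(116.2), math.radians(121.7),
         math.radians(120.8), math.radians(110.5), math.radians(-122.6)]
    )
    bb = np.empty((3, 4, 3))
    cb = np.empty((3, 3))
    build_backbone(phi, phi, phi, geom, bb, cb)
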