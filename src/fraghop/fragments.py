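"""Trimer fragment configuration libraries.

A fragment configuration is a block of 9 backbone dihedral angles
(phi, psi, omega for each residue of a trimer).  Both the perturbation and
the minimization moves of the basin-hopping search replace the angles of a
randomly chosen trimer window with a configuration drawn from a library.
Libraries are either per-position (one pool per window 1..L-2) or a single
shared pool.  Window positions are 1-based throughout, matching the file
format and the CLI.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional

import numpy as np

from .chain import Conformation, normalize_degrees

FRAGMENT_LENGTH = 3

# canonical (phi, psi) centers per secondary-structure class, degrees
SS_CENTERS = {
    "H": (-57.0, -47.0),
    "E": (-119.0, 113.0),
}
# coil phi is drawn uniformly from the broadly allowed left half of the
# Ramachandran plane, psi uniformly over the full circle
COIL_PHI_RANGE = (-180.0, -40.0)


class FragmentLibraryError(ValueError):
    """Malformed fragment library file or inconsistent pools."""


@dataclass
class FragmentLibrary:
    """Pools of trimer configurations, shared or per window position.

    ``pools`` maps 1-based window position to an array of shape (k, 3, 3);
    a shared library stores its single pool under the key 0.  ``provenance``
    records where the pools came from (file path or synthetic parameters).
    """

    pools: Dict[int, np.ndarray]
    shared: bool
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        if not self.pools:
            raise FragmentLibraryError("library has no pools")
        for pos, pool in self.pools.items():
            pool = np.asarray(pool, dtype=float)
            if pool.ndim != 3 or pool.shape[1:] != (3, 3) or pool.shape[0] < 1:
                raise FragmentLibraryError(f"pool at position {pos} must be (k, 3, 3), k >= 1")
            self.pools[pos] = normalize_degrees(pool)
        if self.shared and set(self.pools) != {0}:
            raise FragmentLibraryError("shared library must have exactly the pool key 0")

    @property
    def n_positions(self) -> Optional[int]:
        """Number of covered windows (None for a shared library)."""
        return None if self.shared else len(self.pools)

    def pool_for(self, position: int) -> np.ndarray:
        if self.shared:
            return self.pools[0]
        try:
            return self.pools[position]
        except KeyError:
            raise FragmentLibraryError(f"no pool for window position {position}") from None

    def check_covers(self, L: int) -> None:
        """Ensure every window 1..L-2 of an L-residue chain has a pool."""
        if self.shared:
            return
        missing = [p for p in range(1, L - 1) if p not in self.pools]
        if missing:
            raise FragmentLibraryError(f"library lacks pools for windows {missing}")


def sample_window(L: int, rng: np.random.Generator) -> int:
    """A uniformly random 1-based trimer window position in 1..L-2."""
    if L < 3:
        raise ValueError("chain must have at least 3 residues")
    return int(rng.integers(1, L - 1))


def sample_config(library: FragmentLibrary, position: int,
                  rng: np.random.Generator) -> np.ndarray:
    """A uniformly random configuration (3, 3 degrees) from the pool."""
    pool = library.pool_for(position)
    return pool[int(rng.integers(0, len(pool)))]


def apply_fragment(conf: Conformation, position: int, config: np.ndarray) -> Conformation:
    """Replace the 9 angles of the trimer at ``position`` (1-based).

    Returns a new conformation; the input is untouched and all caches on
    the result are cleared.
    """
    config = np.asarray(config, dtype=float)
    if config.shape == (9,):
        config = config.reshape(3, 3)
    if config.shape != (3, 3):
        raise ValueError("trimer configuration must have 9 angles")
    L = conf.n_residues
    if not 1 <= position <= L - 2:
        raise ValueError(f"window position {position} out of range 1..{L - 2}")
    angles = conf.angles.copy()
    angles[position - 1: position + 2] = config
    return conf.with_angles(angles)


def build_synthetic_library(
    profile: str,
    pool_size: int,
    noise_sd,
    rng: np.random.Generator,
    shared: bool = False,
) -> FragmentLibrary:
    """A synthetic per-position library around a secondary-structure profile.

    ``profile`` assigns each residue one of H (helix), E (strand), C (coil).
    Helix and strand angles are Gaussian around the canonical textbook
    centers; coil phi/psi are drawn uniformly (see COIL_PHI_RANGE); omega is
    Gaussian around 180.  ``noise_sd`` (degrees) is the Gaussian sd applied
    to all non-uniform angles; a sequence of sds builds a mixture pool
    (configuration k uses ``noise_sd[k % len(noise_sd)]``), giving the
    library both near-native and strongly displaced configurations.
    Deterministic for a given rng state.
    """
    profile = profile.upper()
    if len(profile) < 3:
        raise ValueError("profile must cover at least 3 residues")
    bad = set(profile) - set("HEC")
    if bad:
        raise ValueError(f"profile labels must be H/E/C, got {sorted(bad)}")
    if pool_size < 1:
        raise ValueError("pool_size must be >= 1")
    sds = [float(s) for s in (np.atleast_1d(noise_sd))]
    if any(s < 0 for s in sds):
        raise ValueError("noise_sd must be >= 0")

    def draw_residue(label: str, sd: float) -> np.ndarray:
        if label in SS_CENTERS:
            phi0, psi0 = SS_CENTERS[label]
            phi = phi0 + rng.normal(0.0, sd)
            psi = psi0 + rng.normal(0.0, sd)
        else:
            phi = rng.uniform(*COIL_PHI_RANGE)
            psi = rng.uniform(-180.0, 180.0)
        omega = 180.0 + rng.normal(0.0, sd)
        return np.array([phi, psi, omega])

    pools: Dict[int, np.ndarray] = {}
    positions = [0] if shared else range(1, len(profile) - 1)
    for pos in positions:
        window = profile[0:3] if shared else profile[pos - 1: pos + 2]
        pool = np.empty((pool_size, 3, 3))
        for k in range(pool_size):
            sd = sds[k % len(sds)]
            for j, label in enumerate(window):
                pool[k, j] = draw_residue(label, sd)
        pools[pos] = pool
    return FragmentLibrary(
        pools=pools, shared=shared,
        provenance={"kind": "synthetic", "profile": profile,
                    "pool_size": pool_size, "noise_sd": sds},
    )


def profile_angles(profile: str, rng: Optional[np.random.Generator] = None) -> np.ndarray:
    """Noiseless (L, 3) angles at the canonical center of each profile label.

    Coil residues need a concrete draw; pass ``rng`` to resolve them (a
    fixed fallback of phi=-80, psi=150 is used otherwise).
    """
    out = np.empty((len(profile), 3))
    for i, label in enumerate(profile.upper()):
        if label in SS_CENTERS:
            out[i, 0], out[i, 1] = SS_CENTERS[label]
        elif rng is not None:
            out[i, 0] = rng.uniform(*COIL_PHI_RANGE)
            out[i, 1] = rng.uniform(-180.0, 180.0)
        else:
            out[i, 0], out[i, 1] = -80.0, 150.0
        out[i, 2] = 180.0
    return out


def write_library(library: FragmentLibrary, path) -> None:
    """Write the line-oriented text format (see read_library)."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("# fraghop fragment library\n")
        for pos in sorted(library.pools):
            header = "*" if library.shared else str(pos)
            fh.write(f"# position {header}\n")
            for config in library.pools[pos]:
                fh.write(" ".join(f"{a:.4f}" for a in config.ravel()) + "\n")


def read_library(path) -> FragmentLibrary:
    """Parse a fragment library file.

    Format: ``# position <p>`` headers (``# position *`` for a single
    shared pool) followed by one configuration per line — 9 whitespace-
    separated degrees ordered phi1 psi1 omega1 phi2 psi2 omega2 phi3 psi3
    omega3.  Other ``#`` lines are comments.  Errors carry line numbers.
    """
    pools: Dict[int, list] = {}
    shared = False
    current: Optional[int] = None
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line.lstrip("#").strip()
                if body.lower().startswith("position"):
                    token = body.split(None, 1)[1].strip()
                    if token == "*":
                        shared = True
                        current = 0
                    else:
                        try:
                            current = int(token)
                        except ValueError:
                            raise FragmentLibraryError(
                                f"{path}:{lineno}: bad position header {token!r}"
                            ) from None
                        if current < 1:
                            raise FragmentLibraryError(
                                f"{path}:{lineno}: positions are 1-based, got {current}"
                            )
                    pools.setdefault(current, [])
                continue
            if current is None:
                raise FragmentLibraryError(
                    f"{path}:{lineno}: configuration before any '# position' header"
                )
            fields = line.split()
            if len(fields) != 9:
                raise FragmentLibraryError(
                    f"{path}:{lineno}: expected 9 angles, got {len(fields)}"
                )
            try:
                values = [float(x) for x in fields]
            except ValueError:
                raise FragmentLibraryError(f"{path}:{lineno}: non-numeric angle") from None
            pools[current].append(np.array(values).reshape(3, 3))
    if shared and len(pools) > 1:
        raise FragmentLibraryError(f"{path}: mixes '# position *' with numbered positions")
    empty = [p for p, v in pools.items() if not v]
    if empty or not pools:
        raise FragmentLibraryError(f"{path}: empty pool(s) at positions {sorted(empty)}")
    return FragmentLibrary(
        pools={p: np.stack(v) for p, v in pools.items()},
        shared=shared,
        provenance={"kind": "file", "path": str(path)},
    )
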