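"""Coarse-grained backbone chain model.

A conformation is represented by its sequence plus three backbone dihedral
angles (phi, psi, omega) per residue; bond lengths and bond angles are held
at idealized values, so Cartesian coordinates follow deterministically from
the angles by forward kinematics.  The modeled atoms are the heavy backbone
atoms N, CA, C, O plus a single side-chain pseudo-atom (CB, or a centroid
placed at the CB position).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterator, Literal, Optional

import numpy as np

from . import _kinematics

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

THREE_LETTER = {
    "A": "ALA", "C": "CYS", "D": "ASP", "E": "GLU", "F": "PHE",
    "G": "GLY", "H": "HIS", "I": "ILE", "K": "LYS", "L": "LEU",
    "M": "MET", "N": "ASN", "P": "PRO", "Q": "GLN", "R": "ARG",
    "S": "SER", "T": "THR", "V": "VAL", "W": "TRP", "Y": "TYR",
}
ONE_LETTER = {v: k for k, v in THREE_LETTER.items()}


def normalize_degrees(angles):
    """Map angles (degrees) to the canonical interval (-180, 180]."""
    a = np.asarray(angles, dtype=float)
    out = -np.remainder(-a + 180.0, 360.0) + 180.0
    return out


@dataclass(frozen=True)
class Sequence:
    """An amino-acid sequence in one-letter codes, length >= 3."""

    residues: str

    def __post_init__(self):
        if len(self.residues) < 3:
            raise ValueError("sequence must have at least 3 residues (one trimer window)")
        bad = set(self.residues) - set(AMINO_ACIDS)
        if bad:
            raise ValueError(f"unknown residue codes: {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.residues)

    def __iter__(self) -> Iterator[str]:
        return iter(self.residues)


@dataclass(frozen=True)
class BackboneGeometry:
    """Idealized bond lengths (Angstrom) and bond angles (degrees).

    Defaults are standard idealized backbone values; every number is
    configurable so an alternative parameterization can be dropped in.
    """

    bond_n_ca: float = 1.458
    bond_ca_c: float = 1.525
    bond_c_n: float = 1.329
    bond_c_o: float = 1.231
    bond_ca_cb: float = 1.521
    angle_n_ca_c: float = 111.2
    angle_ca_c_n: float = 116.2
    angle_c_n_ca: float = 121.7
    angle_ca_c_o: float = 120.8
    angle_n_ca_cb: float = 110.5
    improper_c_n_ca_cb: float = -122.6

    def __post_init__(self):
        for name in ("bond_n_ca", "bond_ca_c", "bond_c_n", "bond_c_o", "bond_ca_cb"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("angle_n_ca_c", "angle_ca_c_n", "angle_c_n_ca",
                     "angle_ca_c_o", "angle_n_ca_cb"):
            if not 0.0 < getattr(self, name) < 180.0:
                raise ValueError(f"{name} must lie in (0, 180) degrees")

    def as_array(self) -> np.ndarray:
        r = math.radians
        return np.array(
            [self.bond_n_ca, self.bond_ca_c, self.bond_c_n, self.bond_c_o,
             self.bond_ca_cb, r(self.angle_n_ca_c), r(self.angle_ca_c_n),
             r(self.angle_c_n_ca), r(self.angle_ca_c_o), r(self.angle_n_ca_cb),
             r(self.improper_c_n_ca_cb)]
        )


DEFAULT_GEOMETRY = BackboneGeometry()

BACKBONE_ATOMS = ("N", "CA", "C", "O")

RepresentationMode = Literal["cb", "centroid"]


@dataclass
class CoordinateSet:
    """Cartesian coordinates for one conformation.

    ``backbone`` has shape (L, 4, 3) ordered N, CA, C, O; ``side`` has
    shape (L, 3) and holds the CB (or centroid) position, NaN where the
    pseudo-atom is absent (glycine in "cb" mode, or a missing atom in a
    read-in structure).
    """

    backbone: np.ndarray
    side: np.ndarray
    mode: RepresentationMode = "cb"

    @property
    def n_residues(self) -> int:
        return self.backbone.shape[0]

    def superposition_atoms(self) -> np.ndarray:
        """The (4L, 3) array of N, CA, C, O positions used for lRMSD."""
        return self.backbone.reshape(-1, 3)

    def contact_centers(self) -> np.ndarray:
        """Per-residue side-chain contact point: CB where present, else CA."""
        centers = self.side.copy()
        missing = ~np.isfinite(centers).all(axis=1)
        centers[missing] = self.backbone[missing, 1]
        return centers

    def iter_atoms(self):
        """Yield (residue index 0-based, atom name, position)."""
        for i in range(self.n_residues):
            for j, name in enumerate(BACKBONE_ATOMS):
                pos = self.backbone[i, j]
                if np.isfinite(pos).all():
                    yield i, name, pos
            if np.isfinite(self.side[i]).all():
                yield i, "CB" if self.mode == "cb" else "CEN", self.side[i]


def build_coordinates(
    angles: np.ndarray,
    geometry: BackboneGeometry = DEFAULT_GEOMETRY,
    sequence: Optional[Sequence] = None,
    mode: RepresentationMode = "cb",
) -> CoordinateSet:
    """Forward kinematics: dihedral angles (degrees, shape (L, 3)) to Cartesians.

    The chain is grown residue by residue, each atom placed from the three
    preceding atoms with its fixed bond length, fixed bond angle and the
    governing dihedral.  The frame is anchored at residue 1 (N at the
    origin, CA on +x, C in the xy-plane); lRMSD makes the absolute frame
    irrelevant.  In "cb" mode glycine gets no side pseudo-atom; "centroid"
    mode places the pseudo-atom at the CB position for every residue.
    """
    angles = np.asarray(angles, dtype=float)
    if angles.ndim != 2 or angles.shape[1] != 3:
        raise ValueError("angles must have shape (L, 3)")
    if not np.isfinite(angles).all():
        raise ValueError("non-finite dihedral angle")
    L = angles.shape[0]
    if sequence is not None and len(sequence) != L:
        raise ValueError("sequence length does not match angle array")

    rad = np.radians(angles)
    backbone = np.empty((L, 4, 3))
    side = np.empty((L, 3))
    _kinematics.build_backbone(
        np.ascontiguousarray(rad[:, 0]),
        np.ascontiguousarray(rad[:, 1]),
        np.ascontiguousarray(rad[:, 2]),
        geometry.as_array(), backbone, side,
    )
    if mode == "cb" and sequence is not None:
        gly = np.fromiter((r == "G" for r in sequence), dtype=bool, count=L)
        side[gly] = np.nan
    return CoordinateSet(backbone=backbone, side=side, mode=mode)


@dataclass
class Conformation:
    """A sequence plus per-residue (phi, psi, omega) angles in degrees.

    Coordinates are derived lazily and cached; the per-term energy cache is
    attached by the energy module.  Treat instances as values: fragment
    application returns a new object and never mutates its input.
    """

    sequence: Sequence
    angles: np.ndarray
    geometry: BackboneGeometry = DEFAULT_GEOMETRY
    mode: RepresentationMode = "cb"
    _coords: Optional[CoordinateSet] = field(default=None, repr=False, compare=False)
    terms: Optional[object] = field(default=None, repr=False, compare=False)

    def __post_init__(self):
        a = normalize_degrees(self.angles)
        if a.shape != (len(self.sequence), 3):
            raise ValueError("angles must have shape (L, 3) matching the sequence")
        object.__setattr__(self, "angles", a)

    @property
    def n_residues(self) -> int:
        return len(self.sequence)

    @property
    def coords(self) -> CoordinateSet:
        if self._coords is None:
            self._coords = build_coordinates(
                self.angles, self.geometry, self.sequence, self.mode
            )
        return self._coords

    @property
    def total_energy(self) -> Optional[float]:
        return None if self.terms is None else self.terms.total

    def with_angles(self, angles: np.ndarray) -> "Conformation":
        """A new conformation with replaced angles and cleared caches."""
        return replace(self, angles=np.array(angles, dtype=float),
                       _coords=None, terms=None)


def extended_chain(sequence: Sequence, geometry: BackboneGeometry = DEFAULT_GEOMETRY,
                   mode: RepresentationMode = "cb") -> Conformation:
    """The default start state: all phi = psi = omega = 180 degrees."""
    angles = np.full((len(sequence), 3), 180.0)
    return Conformation(sequence=sequence, angles=angles, geometry=geometry, mode=mode)


def _superposition_coords(x) -> np.ndarray:
    if isinstance(x, Conformation):
        return x.coords.superposition_atoms()
    if isinstance(x, CoordinateSet):
        return x.superposition_atoms()
    return np.asarray(x, dtype=float)


def compute_lrmsd(a, b) -> float:
    """Least RMSD (Angstrom) over backbone N, CA, C, O after optimal
    rigid-body superposition (Kabsch/SVD).

    Accepts Conformation, CoordinateSet or raw (n, 3) arrays.  Atom rows
    that are NaN in either argument (e.g. a missing terminal O in a read-in
    structure) are excluded from the superposition.
    """
    pa = _superposition_coords(a)
    pb = _superposition_coords(b)
    if pa.shape != pb.shape:
        raise ValueError("conformations have different atom counts")
    ok = np.isfinite(pa).all(axis=1) & np.isfinite(pb).all(axis=1)
    pa = pa[ok]
    pb = pb[ok]
    if len(pa) < 3:
        raise ValueError("need at least 3 common atoms for superposition")
    pa = pa - pa.mean(axis=0)
    pb = pb - pb.mean(axis=0)
    h = pb.T @ pa
    u, s, vt = np.linalg.svd(h)
    # proper rotation: flip the smallest singular direction if needed
    d = np.sign(np.linalg.det(u @ vt))
    rot = (u * np.array([1.0, 1.0, d])) @ vt
    # explicit residual (not the singular-value identity): numerically exact
    # near zero, where the identity cancels catastrophically
    diff = pa - pb @ rot
    return math.sqrt(float(np.einsum("ij,ij->", diff, diff)) / len(pa))
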