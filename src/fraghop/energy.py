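"""Coarse-grained multi-term energy models.

The sampler only needs two things from an energy model: a per-term energy
decomposition (a TermVector, which the Pareto reduction consumes) and a
strict evaluation counter for budget accounting.  The bundled "AMW-lite"
model sums five physically motivated non-local terms over the reduced
backbone + CB representation:

    E = E_lj + E_hbond + E_compaction + E_burial + E_water

Functional forms are deliberately simple and fully documented below; every
parameter lives in :class:`AMWLiteParams` so a finer-grained potential can
be dropped in behind the same interface.

Default parameter table (kcal/mol and Angstrom):

==================  =======  ==============================================
parameter           default  meaning
==================  =======  ==============================================
lj_epsilon          0.20     Lennard-Jones well depth per atom pair
lj_sigma            3.40     Lennard-Jones zero-crossing distance
lj_cap_fraction     0.60     below lj_cap_fraction * sigma the repulsive
                             branch continues linearly (soft core)
hbond_depth         0.50     well depth per backbone O(i)..N(j) hydrogen
                             bond, |i - j| >= 3
hbond_rmin/rmax     2.6/3.4  O..N distance window; cosine-squared kernel,
                             -depth at the window center
compaction_kappa    0.50     harmonic weight on (Rg - Rg_target)^2
rg_coeff            2.20     Rg_target = rg_coeff * L ** 0.38
burial_weight       0.30     reward scale for buried hydrophobic residues
burial_radius       8.0      CB contact radius defining the contact number
burial_saturation   6        contacts at which the burial reward saturates
water_depth         0.08     well depth per CB pair in the water-mediated
                             shell (cosine-squared kernel)
water_rmin/rmax     6.5/9.5  water-mediated CB..CB distance shell
==================  =======  ==============================================
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional, Protocol, Sequence as TypingSequence, Tuple

import numpy as np

from .chain import Conformation, CoordinateSet

# Kyte-Doolittle hydropathy, rescaled to [0, 1] (1 = most hydrophobic)
_KD = {
    "I": 4.5, "V": 4.2, "L": 3.8, "F": 2.8, "C": 2.5, "M": 1.9, "A": 1.8,
    "G": -0.4, "T": -0.7, "S": -0.8, "W": -0.9, "Y": -1.3, "P": -1.6,
    "H": -3.2, "E": -3.5, "Q": -3.5, "D": -3.5, "N": -3.5, "K": -3.9,
    "R": -4.5,
}
HYDROPHOBICITY = {aa: (v + 4.5) / 9.0 for aa, v in _KD.items()}


class BudgetExhausted(RuntimeError):
    """Raised when an evaluation is requested past the configured budget."""


@dataclass
class EvaluationCounter:
    """Strict accounting of energy-function evaluations against a budget."""

    budget: int = 10_000_000
    count: int = 0

    def __post_init__(self):
        if self.budget < 1:
            raise ValueError("budget must be >= 1")

    @property
    def remaining(self) -> int:
        return self.budget - self.count

    def spend(self) -> None:
        if self.count >= self.budget:
            raise BudgetExhausted(f"evaluation budget of {self.budget} exhausted")
        self.count += 1


@dataclass(frozen=True)
class TermVector:
    """An ordered per-term energy decomposition; total = sum of terms."""

    names: Tuple[str, ...]
    values: np.ndarray

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.names),):
            raise ValueError("one value per term name required")
        object.__setattr__(self, "values", v)

    @property
    def total(self) -> float:
        return float(self.values.sum())

    def as_dict(self) -> Dict[str, float]:
        return dict(zip(self.names, map(float, self.values)))


class EnergyModel(Protocol):
    """Contract shared by the sampler and the Pareto reduction."""

    term_names: TypingSequence[str]

    def evaluate_terms(self, conf: Conformation) -> TermVector: ...


def evaluate(model: EnergyModel, conf: Conformation,
             counter: Optional[EvaluationCounter] = None) -> TermVector:
    """Score a conformation, caching the TermVector on it.

    Spends exactly one unit of ``counter`` (raising BudgetExhausted first
    when the budget is gone, so search loops terminate cleanly).
    """
    if counter is not None:
        counter.spend()
    terms = model.evaluate_terms(conf)
    conf.terms = terms
    return terms


@dataclass(frozen=True)
class AMWLiteParams:
    lj_epsilon: float = 0.20
    lj_sigma: float = 3.40
    lj_cap_fraction: float = 0.60
    hbond_depth: float = 0.50
    hbond_rmin: float = 2.6
    hbond_rmax: float = 3.4
    compaction_kappa: float = 0.50
    rg_coeff: float = 2.20
    rg_exponent: float = 0.38
    burial_weight: float = 0.30
    burial_radius: float = 8.0
    burial_saturation: int = 6
    water_depth: float = 0.08
    water_rmin: float = 6.5
    water_rmax: float = 9.5
    min_sequence_separation: int = 2

    def as_dict(self) -> Dict[str, float]:
        return {f.name: getattr(self, f.name) for f in self.__dataclass_fields__.values()}

    @classmethod
    def from_file(cls, path) -> "AMWLiteParams":
        """Flat ``key = value`` text; unknown keys are an error."""
        values = {}
        known = set(cls.__dataclass_fields__)
        with open(path, "r", encoding="utf-8") as fh:
            for lineno, raw in enumerate(fh, start=1):
                line = raw.split("#", 1)[0].strip()
                if not line:
                    continue
                if "=" not in line:
                    raise ValueError(f"{path}:{lineno}: expected 'key = value'")
                key, val = (s.strip() for s in line.split("=", 1))
                if key not in known:
                    raise ValueError(f"{path}:{lineno}: unknown parameter {key!r}")
                values[key] = int(val) if key == "burial_saturation" else float(val)
        return cls(**values)


def _atom_table(coords: CoordinateSet) -> Tuple[np.ndarray, np.ndarray]:
    """(positions, residue indices) for all present (finite) atoms."""
    L = coords.n_residues
    bb = coords.backbone.reshape(-1, 3)
    res_bb = np.repeat(np.arange(L), 4)
    bb_ok = np.isfinite(bb).all(axis=1)
    side_ok = np.isfinite(coords.side).all(axis=1)
    pos = np.concatenate([bb[bb_ok], coords.side[side_ok]])
    res = np.concatenate([res_bb[bb_ok], np.arange(L)[side_ok]])
    return pos, res


def _pair_distances(pos: np.ndarray, res: np.ndarray, min_sep: int):
    """Upper-triangle distances for pairs with residue separation >= min_sep."""
    d = pos[:, None, :] - pos[None, :, :]
    dist = np.sqrt(np.einsum("ijk,ijk->ij", d, d))
    sep = np.abs(res[:, None] - res[None, :])
    mask = np.triu(sep >= min_sep)
    return dist[mask]


def lj_term(coords: CoordinateSet, params: AMWLiteParams = AMWLiteParams()) -> float:
    """12-6 Lennard-Jones over non-bonded atom pairs with a soft core.

    Pairs with residue separation < min_sequence_separation are excluded
    (local geometry is fixed by the idealized model).  Below
    ``r_cap = lj_cap_fraction * sigma`` the potential continues linearly
    with the slope at r_cap, keeping clashes finite.
    """
    pos, res = _atom_table(coords)
    if len(pos) < 2:
        return 0.0
    r = _pair_distances(pos, res, params.min_sequence_separation)
    if r.size == 0:
        return 0.0
    eps, sig = params.lj_epsilon, params.lj_sigma
    r_cap = params.lj_cap_fraction * sig

    def lj(rr):
        x6 = (sig / rr) ** 6
        return 4.0 * eps * (x6 * x6 - x6)

    clash = r < r_cap
    e = np.empty_like(r)
    e[~clash] = lj(r[~clash])
    if clash.any():
        x6 = (sig / r_cap) ** 6
        slope = 4.0 * eps * (-12.0 * x6 * x6 + 6.0 * x6) / r_cap
        e[clash] = lj(r_cap) + slope * (r[clash] - r_cap)
    return float(e.sum())


def _cos2_well(r: np.ndarray, rmin: float, rmax: float, depth: float) -> np.ndarray:
    """-depth at the window center, 0 at and outside the edges."""
    center = 0.5 * (rmin + rmax)
    inside = (r >= rmin) & (r <= rmax)
    out = np.zeros_like(r)
    out[inside] = -depth * np.cos(
        np.pi * (r[inside] - center) / (rmax - rmin)
    ) ** 2
    return out


def hbond_term(coords: CoordinateSet, params: AMWLiteParams = AMWLiteParams()) -> float:
    """Geometric backbone hydrogen-bond well.

    For residue pairs (i, j) with |i - j| >= 3, the O(i)..N(j) distance
    contributes -depth * cos^2 kernel inside [rmin, rmax].  Always <= 0.
    """
    o = coords.backbone[:, 3]
    n = coords.backbone[:, 0]
    L = coords.n_residues
    d = o[:, None, :] - n[None, :, :]
    dist = np.sqrt(np.einsum("ijk,ijk->ij", d, d))
    sep = np.abs(np.arange(L)[:, None] - np.arange(L)[None, :])
    r = dist[sep >= 3]
    return float(_cos2_well(r, params.hbond_rmin, params.hbond_rmax,
                            params.hbond_depth).sum())


def radius_of_gyration(coords: CoordinateSet) -> float:
    ca = coords.backbone[:, 1]
    c = ca - ca.mean(axis=0)
    return float(np.sqrt((c * c).sum(axis=1).mean()))


def compaction_term(coords: CoordinateSet,
                    params: AMWLiteParams = AMWLiteParams()) -> float:
    """kappa * (Rg - Rg_target)^2 with Rg over CA and Rg_target = c * L^0.38."""
    L = coords.n_residues
    target = params.rg_coeff * L ** params.rg_exponent
    return float(params.compaction_kappa * (radius_of_gyration(coords) - target) ** 2)


def _contact_numbers(coords: CoordinateSet, params: AMWLiteParams) -> np.ndarray:
    centers = coords.contact_centers()
    L = len(centers)
    d = centers[:, None, :] - centers[None, :, :]
    dist = np.sqrt(np.einsum("ijk,ijk->ij", d, d))
    sep = np.abs(np.arange(L)[:, None] - np.arange(L)[None, :])
    return ((dist <= params.burial_radius) & (sep >= params.min_sequence_separation)).sum(axis=1)


def burial_contributions(conf_sequence, coords: CoordinateSet,
                         params: AMWLiteParams = AMWLiteParams()) -> np.ndarray:
    """Per-residue burial energies; their sum is the burial term.

    Each residue contributes -weight * h * min(n, n_sat) / n_sat where h is
    its rescaled Kyte-Doolittle hydrophobicity and n its CB contact number
    (CA stands in for the missing CB of glycine).
    """
    n = _contact_numbers(coords, params)
    h = np.array([HYDROPHOBICITY[aa] for aa in conf_sequence])
    sat = np.minimum(n, params.burial_saturation) / params.burial_saturation
    return -params.burial_weight * h * sat


def burial_term(conf_sequence, coords: CoordinateSet,
                params: AMWLiteParams = AMWLiteParams()) -> float:
    return float(burial_contributions(conf_sequence, coords, params).sum())


def water_term(coords: CoordinateSet, params: AMWLiteParams = AMWLiteParams()) -> float:
    """Water-mediated pairwise well for CB pairs in the 6.5-9.5 A shell."""
    centers = coords.contact_centers()
    L = len(centers)
    d = centers[:, None, :] - centers[None, :, :]
    dist = np.sqrt(np.einsum("ijk,ijk->ij", d, d))
    sep = np.abs(np.arange(L)[:, None] - np.arange(L)[None, :])
    r = dist[np.triu(sep >= params.min_sequence_separation)]
    return float(_cos2_well(r, params.water_rmin, params.water_rmax,
                            params.water_depth).sum())


@dataclass
class AMWLite:
    """The bundled five-term coarse-grained model (see module docstring)."""

    params: AMWLiteParams = field(default_factory=AMWLiteParams)
    term_names: Tuple[str, ...] = (
        "lj", "hbond", "compaction", "burial", "water",
    )

    def evaluate_terms(self, conf: Conformation) -> TermVector:
        coords = conf.coords
        values = np.array([
            lj_term(coords, self.params),
            hbond_term(coords, self.params),
            compaction_term(coords, self.params),
            burial_term(conf.sequence, coords, self.params),
            water_term(coords, self.params),
        ])
        return TermVector(names=self.term_names, values=values)
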