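"""Synthetic fixtures: toy chain systems and statistically controlled
decoy ensembles.

These generators make every other module exercisable without any external
structure or fragment database.  The ensemble generator follows a latent-
factor model: each decoy has a latent "quality" value q ~ N(0, 1), each
energy term is loading * q plus independent Gaussian noise, and an
lRMSD-like variable is base + slope * q + noise, floored at zero.  Large
loadings relative to the noise give strongly correlated terms (a
well-funneled surface); zero loadings give independent terms.  This is the
regime where a handful of decoys dominates most others, so the Pareto
front is a tiny fraction of the ensemble — mimicking how real
coarse-grained decoy sets collapse under a dominance filter — while the
weak energy/lRMSD linkage mimics their weakly funneled character.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np
import pandas as pd

from .chain import Conformation, Sequence
from .fragments import FragmentLibrary, build_synthetic_library, profile_angles
from .pareto import DecoyEnsemble

#: Residue composition cycled to build toy sequences: hydrophobic/polar
#: alternation so the burial and water terms have something to act on.
TOY_COMPOSITION = "LKAVESILGD"


@dataclass(frozen=True)
class SyntheticEnsembleSpec:
    """Parameters of the latent-factor decoy ensemble generator."""

    n_decoys: int = 1000
    n_terms: int = 5
    loadings: Tuple[float, ...] = ()          # default: all 1.0
    noise_sd: Tuple[float, ...] = ()          # default: all 0.5
    lrmsd_base: float = 6.0
    lrmsd_slope: float = 1.5
    lrmsd_noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if self.n_decoys < 1:
            raise ValueError("n_decoys must be >= 1")
        if self.n_terms < 2:
            raise ValueError("n_terms must be >= 2")
        load = self.loadings or tuple([1.0] * self.n_terms)
        noise = self.noise_sd or tuple([0.5] * self.n_terms)
        if len(load) != self.n_terms or len(noise) != self.n_terms:
            raise ValueError("loadings and noise_sd must have one entry per term")
        if any(s < 0 for s in noise) or self.lrmsd_noise_sd < 0:
            raise ValueError("noise sds must be >= 0")
        object.__setattr__(self, "loadings", tuple(load))
        object.__setattr__(self, "noise_sd", tuple(noise))


def generate_ensemble(spec: SyntheticEnsembleSpec) -> DecoyEnsemble:
    """Draw a decoy ensemble from the latent-factor model (reproducible)."""
    rng = np.random.default_rng(spec.seed)
    q = rng.standard_normal(spec.n_decoys)
    terms = np.empty((spec.n_decoys, spec.n_terms))
    for j in range(spec.n_terms):
        terms[:, j] = spec.loadings[j] * q + rng.normal(
            0.0, spec.noise_sd[j], size=spec.n_decoys
        ) if spec.noise_sd[j] > 0 else spec.loadings[j] * q
    lrmsd = spec.lrmsd_base + spec.lrmsd_slope * q + (
        rng.normal(0.0, spec.lrmsd_noise_sd, size=spec.n_decoys)
        if spec.lrmsd_noise_sd > 0 else 0.0
    )
    lrmsd = np.maximum(lrmsd, 0.0)
    frame = pd.DataFrame({"id": [f"d{i:06d}" for i in range(spec.n_decoys)]})
    for j in range(spec.n_terms):
        frame[f"E_t{j + 1}"] = terms[:, j]
    frame["total"] = terms.sum(axis=1)
    frame["lrmsd_native"] = lrmsd
    return DecoyEnsemble(frame)


def toy_sequence(length: int) -> Sequence:
    """A deterministic toy sequence of the documented composition."""
    if length < 3:
        raise ValueError("length must be >= 3")
    s = (TOY_COMPOSITION * (length // len(TOY_COMPOSITION) + 1))[:length]
    return Sequence(s)


def default_profile(length: int) -> str:
    """A mixed helix/coil/strand profile: helix N-half, coil turn, strand tail."""
    n_helix = max(3, length // 2 - 1)
    n_coil = max(2, length // 6)
    n_strand = length - n_helix - n_coil
    if n_strand < 3:
        n_strand = 3
        n_coil = length - n_helix - n_strand
        if n_coil < 0:
            n_helix += n_coil
            n_coil = 0
    return "H" * n_helix + "C" * n_coil + "E" * n_strand


def generate_toy_system(
    length: int,
    profile: Optional[str] = None,
    pool_size: int = 30,
    noise_sd: float = 18.0,
    seed: int = 0,
) -> Tuple[Sequence, FragmentLibrary, Conformation]:
    """A self-contained search fixture: sequence, library, "native".

    The library is built around the secondary-structure profile with
    Gaussian angle noise; the "native" conformation is the noiseless
    profile itself (coil residues resolved with the same seed), so lRMSD
    to native is meaningful and, with zero noise, exactly reachable.
    """
    if length < 3:
        raise ValueError("length must be >= 3")
    if profile is None:
        profile = default_profile(length)
    if len(profile) != length:
        raise ValueError("profile length must match the sequence length")
    seq = toy_sequence(length)
    native_rng = np.random.default_rng(seed)
    native = Conformation(sequence=seq, angles=profile_angles(profile, native_rng))
    lib_rng = np.random.default_rng(seed + 1)
    library = build_synthetic_library(profile, pool_size, noise_sd, lib_rng)
    return seq, library, native
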