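"""Run-level statistics: hop step sizes, lRMSD distributions, run comparison.

Summaries are pure functions of the recorded minima — nothing is
re-evaluated — so recomputing them from a written score table reproduces
them exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import List, Optional, Tuple

import numpy as np
import pandas as pd

from .chain import Conformation, compute_lrmsd
from .pareto import DecoyEnsemble
from .sampling import Trajectory

#: Histogram bin width (Angstrom) for mu_|MM| distributions.
DEFAULT_BIN_WIDTH = 0.5

COMPARISON_COLUMNS = ["label", "n_minima", "hops", "acceptance_rate",
                      "mean_mu", "lowest_energy", "lowest_lrmsd"]


@dataclass
class RunSummary:
    """Descriptive statistics of one basin-hopping run."""

    label: str
    n_minima: int
    hops: int
    acceptance_rate: float
    mean_mu: float                      # mean lRMSD between consecutive minima
    mu_histogram: Tuple[np.ndarray, np.ndarray]  # (counts, bin edges)
    lowest_energy: float
    lowest_lrmsd: float                 # NaN when no native reference
    returns_to_previous: int


def _mu_histogram(mu: np.ndarray, bin_width: float) -> Tuple[np.ndarray, np.ndarray]:
    if mu.size == 0:
        return np.zeros(0, dtype=int), np.array([0.0])
    top = max(bin_width, float(np.max(mu)))
    edges = np.arange(0.0, top + bin_width, bin_width)
    counts, edges = np.histogram(mu, bins=edges)
    return counts, edges


def summarize_table(
    ensemble: DecoyEnsemble,
    label: str = "run",
    returns_to_previous: int = 0,
    bin_width: float = DEFAULT_BIN_WIDTH,
) -> RunSummary:
    """Summarize a score table (one row per recorded minimum)."""
    frame = ensemble.frame
    if len(frame) == 0:
        raise ValueError("empty trajectory")
    mu = frame["mu_prev"].to_numpy(dtype=float) if "mu_prev" in frame else np.array([])
    mu = mu[np.isfinite(mu)]
    hops = int(frame["hop"].max()) if "hop" in frame else len(frame) - 1
    if "accepted" in frame and hops > 0:
        accepted = frame["accepted"].to_numpy()[1:]
        rate = float(np.mean(accepted.astype(float)))
    else:
        rate = math.nan
    lrmsd = ensemble.lrmsd
    return RunSummary(
        label=label,
        n_minima=len(frame),
        hops=hops,
        acceptance_rate=rate,
        mean_mu=float(np.mean(mu)) if mu.size else math.nan,
        mu_histogram=_mu_histogram(mu, bin_width),
        lowest_energy=float(frame["total"].min()),
        lowest_lrmsd=float(np.nanmin(lrmsd)) if lrmsd is not None else math.nan,
        returns_to_previous=returns_to_previous,
    )


def summarize(trajectory: Trajectory, native: Optional[Conformation] = None,
              label: str = "run", bin_width: float = DEFAULT_BIN_WIDTH) -> RunSummary:
    """Summarize a trajectory, optionally re-deriving lRMSD to a native.

    When ``native`` is given it overrides any lRMSD stored on the records
    (useful when the run was made without a reference).
    """
    from .tables import trajectory_to_ensemble  # local import avoids a cycle

    if native is not None:
        if len(native.sequence) != len(trajectory.sequence):
            raise ValueError("native length does not match the trajectory sequence")
        for rec in trajectory.records:
            conf = Conformation(sequence=trajectory.sequence, angles=rec.angles.copy())
            rec.lrmsd_native = compute_lrmsd(conf, native)
    ensemble = trajectory_to_ensemble(trajectory)
    return summarize_table(ensemble, label=label,
                           returns_to_previous=trajectory.returns_to_previous,
                           bin_width=bin_width)


def compare_runs(summaries: List[RunSummary]) -> pd.DataFrame:
    """Side-by-side table of run summaries (lowest energy / lRMSD / hops)."""
    if len(summaries) < 2:
        raise ValueError("need at least two summaries to compare")
    rows = [
        {
            "label": s.label,
            "n_minima": s.n_minima,
            "hops": s.hops,
            "acceptance_rate": s.acceptance_rate,
            "mean_mu": s.mean_mu,
            "lowest_energy": s.lowest_energy,
            "lowest_lrmsd": s.lowest_lrmsd,
        }
        for s in summaries
    ]
    return pd.DataFrame(rows, columns=COMPARISON_COLUMNS)
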