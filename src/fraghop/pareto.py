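"""Multi-objective reduction of decoy ensembles.

A decoy ensemble carries one per-term energy decomposition per decoy.
Decoy a *strongly* dominates decoy b when every term of a is strictly
lower; *weak* dominance relaxes this to lower-or-equal with at least one
term strictly lower (so exact duplicates never dominate each other — the
strictness clause is a deliberate interpretation, without it the weak
front of an ensemble containing duplicates could be empty).

Reduction methods:

- ``pareto_front``: keep the non-dominated decoys (Omega_PF);
- ``reduce_by_count``: keep the n% of decoys dominating the most others
  (Omega_PC(n));
- ``reduce_by_total_energy``: keep the n% lowest-total-energy decoys
  (Omega_TE(n)), the single-objective baseline.

All orientations are minimization (energies; lower is better).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Literal, Optional, Sequence

import numpy as np
import pandas as pd

Mode = Literal["strong", "weak"]

#: The printed five-group combination of the ten Rosetta score3 terms,
#: grouped by inter-term correlation (the beta-sheet terms ss_pair, rsigma
#: and sheet move together, as do the compactness/environment terms).
ROSETTA_SCORE3_5GROUP: Dict[str, str] = {
    "env": "env_pair_cbeta_rg",
    "pair": "env_pair_cbeta_rg",
    "cbeta": "env_pair_cbeta_rg",
    "rg": "env_pair_cbeta_rg",
    "vdw": "vdw",
    "cenpack": "cenpack",
    "hs_pair": "hs_pair",
    "ss_pair": "ss_pair_rsigma_sheet",
    "rsigma": "ss_pair_rsigma_sheet",
    "sheet": "ss_pair_rsigma_sheet",
}

GROUPING_PRESETS: Dict[str, Dict[str, str]] = {
    "rosetta-score3-5group": ROSETTA_SCORE3_5GROUP,
}

#: Coefficient of variation below which a term is flagged as low-variance
#: (weak dominance may then be more appropriate than strong).
LOW_VARIANCE_THRESHOLD = 1e-8


@dataclass
class DecoyEnsemble:
    """An ordered set of decoys with a shared term schema.

    Backed by a DataFrame with columns ``id``, one ``E_<term>`` column per
    energy term, ``total`` (= sum of the term columns) and optionally
    ``lrmsd_native`` plus sampler bookkeeping columns (hop, accepted, ...).
    """

    frame: pd.DataFrame

    def __post_init__(self):
        if "id" not in self.frame.columns:
            raise ValueError("ensemble frame needs an 'id' column")
        if self.frame["id"].duplicated().any():
            raise ValueError("decoy ids must be unique")
        if not self.term_columns:
            raise ValueError("ensemble has no E_ term columns")
        if "total" not in self.frame.columns:
            self.frame = self.frame.copy()
            self.frame["total"] = self.frame[self.term_columns].sum(axis=1)
        self.frame = self.frame.reset_index(drop=True)

    @property
    def term_columns(self) -> List[str]:
        return [c for c in self.frame.columns if c.startswith("E_")]

    @property
    def term_names(self) -> List[str]:
        return [c[2:] for c in self.term_columns]

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def terms_matrix(self) -> np.ndarray:
        return self.frame[self.term_columns].to_numpy(dtype=float)

    @property
    def totals(self) -> np.ndarray:
        return self.frame["total"].to_numpy(dtype=float)

    @property
    def lrmsd(self) -> Optional[np.ndarray]:
        if "lrmsd_native" not in self.frame.columns:
            return None
        v = self.frame["lrmsd_native"].to_numpy(dtype=float)
        return None if np.isnan(v).all() else v

    def subset(self, index: np.ndarray) -> "DecoyEnsemble":
        return DecoyEnsemble(self.frame.iloc[np.asarray(index)].reset_index(drop=True))

    def record(self, i: int) -> np.ndarray:
        """The term vector of decoy i (for pairwise dominance checks)."""
        return self.terms_matrix[i]


def _check_schema(a: np.ndarray, b: np.ndarray) -> None:
    a, b = np.asarray(a, dtype=float), np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("decoys have different term schemas")


def strongly_dominates(a, b) -> bool:
    """True iff every term of a is strictly lower than b's."""
    a, b = np.asarray(a, dtype=float), np.asarray(b, dtype=float)
    _check_schema(a, b)
    return bool(np.all(a < b))


def weakly_dominates(a, b) -> bool:
    """True iff every term of a is <= b's and at least one is strictly lower."""
    a, b = np.asarray(a, dtype=float), np.asarray(b, dtype=float)
    _check_schema(a, b)
    return bool(np.all(a <= b) and np.any(a < b))


def _dominates_block(a: np.ndarray, b: np.ndarray, mode: Mode) -> np.ndarray:
    """Boolean (len(a), len(b)) matrix: a[i] dominates b[j]."""
    if mode == "strong":
        return np.all(a[:, None, :] < b[None, :, :], axis=2)
    if mode == "weak":
        le = np.all(a[:, None, :] <= b[None, :, :], axis=2)
        lt = np.any(a[:, None, :] < b[None, :, :], axis=2)
        return le & lt
    raise ValueError(f"unknown dominance mode {mode!r}")


def pareto_front_mask(
    terms: np.ndarray, mode: Mode = "strong", method: str = "auto"
) -> np.ndarray:
    """Boolean membership mask of the Pareto front (non-dominated set).

    ``method="bruteforce"`` is the O(N^2 d) reference; ``"skyline"`` sorts
    by total (a dominator always has the smaller term sum) and tests each
    decoy only against the front found so far, which is equivalent because
    both dominance relations are transitive.  ``"auto"`` picks skyline for
    large N.
    """
    terms = np.asarray(terms, dtype=float)
    n = len(terms)
    if method == "auto":
        method = "skyline" if n > 256 else "bruteforce"
    if method == "bruteforce":
        dominated = np.zeros(n, dtype=bool)
        block = 256
        for lo in range(0, n, block):
            dom = _dominates_block(terms, terms[lo:lo + block], mode)
            dominated[lo:lo + block] = dom.any(axis=0)
        return ~dominated
    if method != "skyline":
        raise ValueError(f"unknown method {method!r}")
    order = np.argsort(terms.sum(axis=1), kind="stable")
    front_rows: List[np.ndarray] = []
    mask = np.zeros(n, dtype=bool)
    front_matrix = np.empty((0, terms.shape[1]))
    for idx in order:
        row = terms[idx]
        if len(front_rows):
            if mode == "strong":
                dominated = bool(np.any(np.all(front_matrix < row, axis=1)))
            else:
                dominated = bool(np.any(
                    np.all(front_matrix <= row, axis=1)
                    & np.any(front_matrix < row, axis=1)
                ))
        else:
            dominated = False
        if not dominated:
            front_rows.append(row)
            front_matrix = np.vstack([front_matrix, row])
            mask[idx] = True
    return mask


def pareto_front(ensemble: DecoyEnsemble, mode: Mode = "strong",
                 method: str = "auto") -> DecoyEnsemble:
    """The non-dominated subset Omega_PF, input order preserved."""
    if len(ensemble) == 0:
        raise ValueError("ensemble is empty")
    mask = pareto_front_mask(ensemble.terms_matrix, mode, method)
    return ensemble.subset(np.flatnonzero(mask))


def pareto_count(ensemble: DecoyEnsemble, mode: Mode = "strong") -> np.ndarray:
    """Per-decoy count of other decoys it dominates."""
    if len(ensemble) == 0:
        raise ValueError("ensemble is empty")
    terms = ensemble.terms_matrix
    n = len(terms)
    counts = np.zeros(n, dtype=np.int64)
    block = 256
    for lo in range(0, n, block):
        counts[lo:lo + block] = _dominates_block(terms[lo:lo + block], terms, mode).sum(axis=1)
    return counts


def _reduced_size(n_percent: float, n_total: int) -> int:
    if not 0 < n_percent <= 100:
        raise ValueError("n must be a percentage in (0, 100]")
    return max(1, int(np.floor(n_percent * n_total / 100.0 + 0.5)))


def reduce_by_count(ensemble: DecoyEnsemble, n_percent: float,
                    mode: Mode = "strong") -> DecoyEnsemble:
    """Omega_PC(n): the n% of decoys with the highest Pareto count.

    Deterministic tie-breaking ladder: higher count, then lower total
    energy, then id.  Subsets are nested across n (a prefix of one fixed
    ordering), so retention curves are monotone.
    """
    counts = pareto_count(ensemble, mode)
    size = _reduced_size(n_percent, len(ensemble))
    order = np.lexsort((ensemble.frame["id"].to_numpy(),
                        ensemble.totals, -counts))
    keep = np.sort(order[:size])
    return ensemble.subset(keep)


def reduce_by_total_energy(ensemble: DecoyEnsemble, n_percent: float) -> DecoyEnsemble:
    """Omega_TE(n): the n% lowest-total-energy decoys (same tie ladder)."""
    if len(ensemble) == 0:
        raise ValueError("ensemble is empty")
    size = _reduced_size(n_percent, len(ensemble))
    order = np.lexsort((ensemble.frame["id"].to_numpy(), ensemble.totals))
    keep = np.sort(order[:size])
    return ensemble.subset(keep)


def percent_reduction(ensemble: DecoyEnsemble, reduced: DecoyEnsemble) -> float:
    """100 * (1 - |reduced| / |ensemble|)."""
    return 100.0 * (1.0 - len(reduced) / len(ensemble))


def group_terms(ensemble: DecoyEnsemble, grouping: Dict[str, str]) -> DecoyEnsemble:
    """Sum term columns into groups; totals are preserved exactly.

    ``grouping`` maps every term name (without the E_ prefix) to a group
    name; every schema term must be covered and no unknown terms allowed.
    """
    schema = set(ensemble.term_names)
    covered = set(grouping)
    if schema - covered:
        raise ValueError(f"grouping does not cover terms {sorted(schema - covered)}")
    if covered - schema:
        raise ValueError(f"grouping names unknown terms {sorted(covered - schema)}")
    groups: Dict[str, List[str]] = {}
    for term in ensemble.term_names:  # preserve schema order
        groups.setdefault(grouping[term], []).append(term)
    out = ensemble.frame.drop(columns=ensemble.term_columns).copy()
    for gname, members in groups.items():
        out[f"E_{gname}"] = ensemble.frame[[f"E_{m}" for m in members]].sum(axis=1)
    # keep id first, groups next, bookkeeping after
    cols = ["id"] + [f"E_{g}" for g in groups] + [
        c for c in out.columns if c != "id" and not c.startswith("E_")
    ]
    return DecoyEnsemble(out[cols])


def auto_group(ensemble: DecoyEnsemble, target_groups: int) -> Dict[str, str]:
    """Group terms by agglomerative merging on absolute correlation.

    Repeatedly merges the two clusters with the highest average absolute
    pairwise correlation of their member terms until ``target_groups``
    remain.  Zero-variance terms have undefined correlation; they are
    given similarity -inf so they merge only when forced, last.  Ties are
    broken by term-name order, making the result deterministic.
    """
    names = ensemble.term_names
    if not 1 <= target_groups <= len(names):
        raise ValueError("target_groups must be in 1..#terms")
    x = ensemble.terms_matrix
    sd = x.std(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(x, rowvar=False)
    corr = np.atleast_2d(corr)
    sim = np.abs(corr)
    bad = (sd == 0)
    sim[bad, :] = -np.inf
    sim[:, bad] = -np.inf

    clusters: List[List[int]] = [[i] for i in range(len(names))]
    while len(clusters) > target_groups:
        best = (-np.inf, None)
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                pair_sims = [sim[a, b] for a in clusters[i] for b in clusters[j]]
                score = float(np.mean(pair_sims))
                if score > best[0]:
                    best = (score, (i, j))
        i, j = best[1]
        clusters[i] = clusters[i] + clusters[j]
        del clusters[j]
    mapping: Dict[str, str] = {}
    for members in clusters:
        members = sorted(members)
        gname = "_".join(names[m] for m in members)
        for m in members:
            mapping[names[m]] = gname
    return mapping


def low_variance_terms(ensemble: DecoyEnsemble,
                       threshold: float = LOW_VARIANCE_THRESHOLD) -> List[str]:
    """Terms whose variance is below ``threshold`` (strong dominance is
    then impossible through that term; weak dominance may be preferable)."""
    sd = ensemble.terms_matrix.std(axis=0)
    return [name for name, s in zip(ensemble.term_names, sd) if s ** 2 < threshold]


def retention_curve(
    ensemble: DecoyEnsemble,
    method: Literal["pf", "pc", "te"],
    n_grid: Sequence[float],
    mode: Mode = "strong",
) -> pd.DataFrame:
    """Minimum retained lRMSD-to-native as a function of the kept percent n.

    For ``pf`` the front ignores n and the same minimum is reported at each
    grid point.  Requires lRMSD on every decoy.
    """
    lrmsd = ensemble.lrmsd
    if lrmsd is None or np.isnan(lrmsd).any():
        raise ValueError("retention_curve requires lrmsd_native on every decoy")
    rows = []
    if method == "pf":
        front = pareto_front(ensemble, mode)
        value = float(np.min(front.lrmsd))
        for n in n_grid:
            rows.append((float(n), value))
    elif method in ("pc", "te"):
        if method == "pc":
            counts = pareto_count(ensemble, mode)
            order = np.lexsort((ensemble.frame["id"].to_numpy(),
                                ensemble.totals, -counts))
        else:
            order = np.lexsort((ensemble.frame["id"].to_numpy(), ensemble.totals))
        sorted_lrmsd = lrmsd[order]
        running_min = np.minimum.accumulate(sorted_lrmsd)
        for n in n_grid:
            size = _reduced_size(float(n), len(ensemble))
            rows.append((float(n), float(running_min[size - 1])))
    else:
        raise ValueError(f"unknown reduction method {method!r}")
    return pd.DataFrame(rows, columns=["n_percent", "min_lrmsd"])
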