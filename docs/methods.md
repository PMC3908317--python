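# Methods

## Molecular representation and kinematics

A conformation is an amino-acid sequence plus three backbone dihedrals
(φ, ψ, ω) per residue, normalized to (−180°, 180°]. Bond lengths and bond
angles are fixed at idealized values (defaults below, all configurable via
`BackboneGeometry`), so the only degrees of freedom are the dihedrals and
Cartesian coordinates follow deterministically by forward kinematics
(NeRF-style sequential placement: each atom is placed from the three
preceding atoms using its bond length, bond angle and governing dihedral).

| quantity | default | quantity | default |
|---|---|---|---|
| N–CA | 1.458 Å | N-CA-C | 111.2° |
| CA–C | 1.525 Å | CA-C-N | 116.2° |
| C–N | 1.329 Å | C-N-CA | 121.7° |
| C=O | 1.231 Å | CA-C-O | 120.8° |
| CA–CB | 1.521 Å | N-CA-CB | 110.5°, improper C-N-CA-CB −122.6° |

Indexing convention: φ_i governs the placement of C_i, ψ_i governs
N_{i+1} (and orients the carbonyl O_i, anti to the amide), and ω_i is the
peptide dihedral between residues i and i+1 governing CA_{i+1}. φ_1 and
the final ω therefore move no backbone atom; they are stored but inert.
The frame is anchored at residue 1 (N at the origin, CA on +x, C in the
xy-plane). Modeled atoms are N, CA, C, O plus one side-chain pseudo-atom:
CB (absent for glycine) in "cb" mode, or a centroid placed at the CB
position in "centroid" mode (true side-chain centroids are not available
at this resolution, so the CB position is the documented stand-in).

The default start state of a search is the fully extended chain
(φ = ψ = ω = 180°). Note that under idealized geometry this chain is
exactly planar but its CA trace is *not* straight — the three backbone
bond angles do not cancel over one residue, so the trace curves with a
virtual CA-CA-CA angle of ≈147°; the planarity, not collinearity, is the
invariant the tests assert.

lRMSD between two conformations is the least RMSD over all backbone
N, CA, C, O atoms after optimal rigid superposition, computed by the
Kabsch SVD construction with the explicit post-rotation residual (the
singular-value identity cancels catastrophically near zero and cannot
certify rigid-transform invariance at 1e−8 Å). Atoms missing from a
read-in structure (e.g. a terminal O) are masked out of the superposition.

## AMW-lite energy model

The bundled model sums five non-local terms over the reduced
representation; local interactions are fixed by the idealized geometry and
contribute nothing. The functional forms are deliberately simple,
documented stand-ins with the same term structure as the coarse-grained
potentials used in decoy sampling; the model makes no claim of numeric
equivalence to any published parameterization, and any object satisfying
the `EnergyModel` contract (term names + per-term evaluation) drops in.

- **Lennard-Jones** — 4ε[(σ/r)¹² − (σ/r)⁶] over all modeled-atom pairs
  with residue separation ≥ 2; below r_cap = 0.6 σ the potential continues
  linearly with the slope at r_cap ("soft core"), so clashes are finite.
  ε = 0.20 kcal/mol, σ = 3.40 Å.
- **H-bond** — for residue pairs |i−j| ≥ 3, the O(i)···N(j) distance
  contributes −w·cos²(π(r−r₀)/(r_max−r_min)) inside the 2.6–3.4 Å window
  (r₀ = 3.0 Å); zero outside, never positive. w = 0.50 kcal/mol.
- **Compaction** — κ(Rg − Rg_target)² with Rg over CA atoms and
  Rg_target = 2.2·L^0.38 Å. κ = 0.50 kcal/mol/Å².
- **Burial** — Σ_i −w_b·h_i·min(n_i, n_sat)/n_sat, where h_i is
  Kyte-Doolittle hydropathy rescaled to [0, 1], n_i the number of CB atoms
  within 8 Å (sequence separation ≥ 2; CA stands in for glycine's CB) and
  n_sat = 6. w_b = 0.30 kcal/mol. By construction the term is exactly the
  sum of its per-residue contributions.
- **Water-mediated** — the same cos² well applied to CB–CB distances in
  the 6.5–9.5 Å shell, depth 0.08 kcal/mol per pair.

All parameters live in `AMWLiteParams` (overridable from a flat key=value
file; the CLI echoes the resolved values to the log). Every term depends
on interatomic distances only, so the total is rigid-transform invariant.

Evaluations are counted strictly: `evaluate` spends one unit of the
budget per call and raises `BudgetExhausted` once the budget is gone, so a
search performs at most `budget` evaluations and the per-record counts
reconcile exactly with the counter. Perturbation candidate generation
performs no evaluations — only the selected perturbed conformation is
scored.

## Basin-hopping search

One hop = perturb → minimize → Metropolis accept/reject at the hop
temperature. Defaults follow the standard calibration of this search
family: tolerance t = 0.5 Å, candidate cap n = 20, d ~ N(D, 1 Å) redrawn
while d ≤ 0 (redrawing rather than clamping keeps the target distribution
unimodal near D), minimizer termination after k consecutive rejections
with k defaulting to the sequence length (overridable for fixtures), and
an evaluation budget of 10⁷. Minimizer temperatures are specified either
directly (kcal/mol) or through presets T0/T1/T2 calibrated so that energy
increases of 1.4, 1.7 and 2.6 kcal/mol are accepted with probability 0.1
(T = −ΔE/ln p; T0 ≈ 0.608, T1 ≈ 0.738, T2 ≈ 1.129 kcal/mol). At T = 0 the
Metropolis rule degenerates to strict descent — ΔE = 0 proposals are
rejected to prevent neutral cycling — and is byte-identical to the
independent greedy implementation (`greedy_minimize`), which exists as a
separate code path precisely so that equivalence is a real check.

The hop-level acceptance temperature is a genuinely open knob (no
canonical value exists); the default uses the same calibration style as
the minimizer presets, at the T1 point (0.1 probability of accepting a
1.7 kcal/mol increase). It is configurable.

Every sampled minimum is recorded, rejected hops included (flagged), so
downstream analysis can use either the accepted-state trajectory or the
full sampled ensemble. Each record carries the lRMSD to the previously
*sampled* minimum (a μ_|MM| sample), the evaluations it consumed, and —
when the perturbation was biased — the drawn target d, the achieved
distance and the attempts used. A hop whose new minimum lies within
0.1 Å lRMSD of the current state counts as a return to the previous
minimum (threshold configurable). The run start is `extended_chain`
minimized once, recorded as hop 0, so the trajectory begins at a
legitimate minimum. A single seeded numpy Generator drives the whole run;
the consumption order (perturbation draws, minimization draws, one
uniform per uphill decision) is fixed, making runs exactly reproducible.

## Pareto reduction

Strong dominance: every term strictly lower. Weak dominance: every term
≤ with at least one strictly lower — the strictness clause is a
deliberate interpretation (without it exact duplicates would mutually
dominate and a duplicate-containing ensemble could have an empty weak
front); it reproduces the standard strong-4/weak-5 counting on the
two-term textbook instance. Lower is always better; there is no
maximization support. Strong dominance is the default; when a term's
variance is near zero the CLI warns that strong dominance cannot act
through it and suggests weak dominance, but never switches silently.

`pareto_front` has two required-identical paths: the O(N²d) brute force
(reference) and a skyline fast path that sorts by term sum — a dominator
always has the strictly smaller sum — and tests each decoy only against
the front found so far (valid because both relations are transitive).
`pareto_count` is the full blocked O(N²d) count. Ω_PC(n) and Ω_TE(n) keep
round(n·N/100) records (half-up, minimum 1) under the deterministic tie
ladder count-desc → total-asc → id-asc; because both are prefixes of one
fixed ordering, the reductions are nested in n and retention curves are
monotone.

Term grouping sums member columns and preserves totals exactly; the
shipped `rosetta-score3-5group` preset maps the ten Rosetta score3 terms
to the standard five groups {env, pair, cbeta, rg} / {vdw} / {cenpack} /
{hs_pair} / {ss_pair, rsigma, sheet}. `auto_group` merges terms
agglomeratively by highest average absolute correlation with
term-name-order tie-breaks; zero-variance terms (undefined correlation)
merge only when forced, last.

## Synthetic fixtures

`generate_ensemble` draws decoys from a latent-factor model: quality
q ~ N(0,1) per decoy, term_j = loading_j·q + N(0, noise_j), lRMSD =
base + slope·q + noise, floored at 0 (defaults: 5 terms, unit loadings,
noise sd 0.5, base 6 Å, slope 1.5, lRMSD noise sd 1.0). The implied
inter-term correlation is l²/(l²+s²) ≈ 0.8 at the defaults — the
correlated-terms / weak-energy-funnel regime in which a dominance filter
collapses a large ensemble to a tiny front. What it does **not** emulate:
real decoy term marginals (heavy tails, term-specific scales), structural
clustering of minima, or any geometric consistency between the term
values and an actual conformation. Passing tests on these ensembles
certify the reduction machinery, not the physics of any particular
potential.

`generate_toy_system` builds a search fixture: a deterministic
hydrophobic/polar toy sequence, a per-position fragment library of
Gaussian-noised configurations around a helix/coil/strand profile, and a
"native" defined as the noiseless profile conformation so lRMSD-to-native
is meaningful (and exactly reachable at zero noise). `noise_sd` may be a
sequence, giving a mixture pool whose entries alternate noise levels —
needed so one library admits both small (~1 Å) and large (~5 Å)
single-fragment jumps.

## Benchmark problem sizes

The behavioural test suite runs at desk scale, chosen once: the
distance-control benchmark uses the 20-residue system with a
mixture-noise library (pool 60, sds 8°/25°/60°), greedy minimization with
k = 3, and one 2,000-hop run per target distance D ∈ {1,…,5} Å; the
achieved-vs-target hit rate is pooled over all draws of the five runs.
Pareto checks use ten 20,000-decoy synthetic ensembles at the default
latent-factor settings, and oracle-equivalence checks 100 random
instances up to N = 500, d ≤ 6. Full-scale sampling (10⁷ evaluations,
60–120-residue chains) uses exactly the same code paths via the CLI.

## Numerical choices and edge cases

- Angles normalized to (−180°, 180°]; window positions and residue
  numbers are 1-based in all user-facing I/O.
- Score tables are written with 6 decimal places and the total column is
  the sum of the *rounded* terms, so a written table always passes its own
  read-time validation (total = ΣE to 1e−6) and repeated writes are
  byte-identical. `NA` marks missing optional values.
- Budget exhaustion inside a minimization truncates the run: the partial
  record is flagged, the table is still written, and the CLI exits 4.
- `reduce_by_*` with N = 1 or n small keeps at least one record.
- PDB output carries backbone + CB/centroid ATOM records, chain A; the
  reader tolerates missing atoms (NaN-masked) but requires N, CA, C on
  every residue.

## Known limitations

- AMW-lite is a structural stand-in: term shapes are plausible but not
  fitted; absolute energies are not comparable to published potentials.
- No side-chain reconstruction, no gradient-based minimization, no
  replica exchange; a run is a single trajectory.
- The fragment library builder is synthetic (profile + noise); it does not
  parse Rosetta fragment files or mine structure databases.
- Weak-dominance fronts on ensembles with many exact ties can be much
  smaller than strong fronts; with continuous scores the two nearly
  coincide.
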