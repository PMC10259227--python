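# Methods

This note documents the models, parameters and design choices behind
`yappis`, in the spirit of the methods documentation of packages like
msprime or statsmodels: enough detail to reproduce or deliberately change
any step.

## Interface demarcation

Two heavy atoms on different chains of a complex are an atomic contact
pair (ACP) when `d < r_vdw(a) + r_vdw(b) + t`, with the tolerance
`t = 1.0 Å` and Bondi van der Waals radii (C 1.70, N 1.55, O 1.52, S 1.80,
P 1.80, Se 1.90 Å; `data/vdw_radii.tsv`, swappable). The comparison is
strict, distances are measured on deposited coordinates, and a k-d tree
only prunes the search — acceptance is always the exact distance test, so
results are identical to an all-pairs scan (asserted against a dense
oracle in the tests). An unordered cross-chain pair is counted once.
Interfaces below 20 ACPs are dropped as too tenuous; the bound is
inclusive ("at least 20").

Parsing policies (gemmi underneath): heavy atoms only; waters and HETATM
records dropped except residues with a configured standard parent (MSE→MET,
SEC→CYS, HYP→PRO); alternate conformers resolved to the highest occupancy,
ties to altloc `A`; first MODEL by default. Unmapped non-standard residues
are kept for geometry and energy but flagged and excluded from propensity
scoring and demarcation.

## Score scales and per-atom decomposition

Three per-residue scales characterise composition:

* **RIP** (dimensionless): enrichment of a residue type at interfaces.
  No published table accompanies the method, so `derive_rip` estimates
  one from any demarcated interface set as a pseudocounted frequency
  ratio, interface residues (counted once per interface when ≥1 atom
  interacts) against all residues of the reference chains. The default
  pseudocount is 0.5 (Jeffreys-style stabiliser); surface-area weighting
  of the reference is deliberately omitted to avoid a SASA dependency.
  Any user table can be loaded from a `residue<TAB>score` TSV.
* **Hydrophobicity ϕ** (kcal/mol): Hessa et al. (2005) apparent
  membrane-insertion free energies; lower = more hydrophobic.
* **Solvation ΔG** (kcal/mol): Wimley–White (1996) interfacial
  partitioning free energies (charged forms for Asp/Glu/Lys/Arg, neutral
  His); lower = partitions more readily out of water.

Residue scores are spread uniformly over the residue's heavy atoms
*excluding* the peptide-bond backbone atoms N, C and O; CA and the side
chain are counted (Gly = 1 … Trp = 11, `data/residue_atom_counts.tsv`).
The three atoms excluded are exactly those forming the amide linkage; CA
is retained because it is not part of the bond. A patch score is the
linear sum of per-atom scores of its interacting atoms, which makes patch
scores additive over disjoint patches and exactly reconstructable from
residue scores — both asserted to 1e-12 in the tests.

## Outlier removal and domains

Patch-score distributions are cleaned with the Tukey rule (keep
`Q1 − 1.5·IQR ≤ v ≤ Q3 + 1.5·IQR`, type-7 linearly interpolated quartiles,
single pass) and divided into equal-width bins by Scott's rule
`3.49·s·n^(−1/3)` (sample standard deviation). Bins are half-open
`[lo, hi)` with the last bin closed, tile `[min, max]` exactly, and the
final partial bin is extended to include the maximum, so domain
membership is a partition. Degenerate inputs raise: fewer than four
observations (IQR) or zero variance (Scott).

## Energy grid and probe

The chain's bounding box, padded by 4.5 Å, is discretised at 0.9 Å. At
each point a united-atom methyl probe accumulates a 12-6 Lennard-Jones
energy with Lorentz–Berthelot combination (geometric-mean ε, summed
r_min/2), an 8 Å cutoff with no switching function, and a hard clamp of
+1000 kcal/mol inside atomic cores (pair distances floored at 1e-3 Å to
avoid overflow at exact overlap). The per-element parameters
(`data/methyl_probe_lj.tsv`) are GRID/Goodford-style empirical values and
are swappable; the pair minimum is exactly −ε_ij at r_min,ij, which the
tests verify analytically. The clamp means interior points can never pass
a negative retention threshold, restricting prediction to the surface.
The padding (≈ one probe contact distance) ensures the favourable shell
around surface pockets lies inside the box.

**Occlusion radius.** The per-point propensity operations default to a
1.6 Å atom-to-grid-point radius, the historical probe-site contact
criterion. A favourable methyl-probe position, however, sits near the
pair Lennard-Jones minimum — 3.7–4.5 Å from the nearest heavy atom — so
protein atoms are never within 1.6 Å of a retained point; used verbatim
inside the pipeline that radius would occlude nothing. The pipeline
therefore uses its own default of 4.5 Å (`RunConfig.propensity_radius`),
about one probe–carbon contact distance: the atoms "occluded" by a bound
probe are those lining its first coordination shell. Both radii are
configurable.

**Combining the scales.** Per-scale point propensities are z-scored over
the retained points (so kcal/mol scales and the dimensionless RIP are
commensurable) and combined with weights (+1, −1, −1) for (RIP, ϕ, ΔG).
The signs orient every term so that larger means more interface-like:
RIP rises toward interfaces while both free-energy scales fall toward
hydrophobic, interface-prone composition; an equal-sign sum would cancel
the hydrophobic signal against the propensity signal. Weights are
configurable.

## Clustering, ranking, Ƭ

Retained points are clustered by single-linkage connected components at
`0.9·√3 + 1e-9 Å` — the 26-neighbourhood of the cubic grid, so one
cluster is one connected favourable region. At most 15 clusters are kept
(the cap is an upper bound, not a forced count), largest first, ties
toward lower total energy, then lowest grid index; every retained point
belongs to at most one cluster. A site's atoms are the union of atoms
within the occlusion radius of any member point.

Sites are ranked by the sum of two z-scores computed across the candidate
set: cumulative overall propensity and |total probe energy| (both
extensive — a large favourable pocket should outrank a speck). Ties break
by cluster size, then lowest grid index, making ranking fully
deterministic.

The overlap score between predicted atoms P and actual patch atoms A is
precision/coverage combined by harmonic mean, `Ƭ = 2pc/(p+c)`, with
`min(p, c)` available as a stricter alternative; Ƭ is 0 for an empty or
disjoint prediction, and comparing against an empty actual patch is an
error. Ƭ is computed at the atom level, matching the atom-level interface
definition; `Ƭ ≥ 0.25` (boundary inclusive) marks a correct prediction.
Note that the harmonic mean lies between min(p, c) and max(p, c).

## Training scan and prediction

Training examines every unbound chain (a complex chain with its partner
simply removed, no relaxation) over a grid of retention thresholds,
default {−0.5, −1.0, …, −3.0} kcal/mol. For each candidate site the three
patch-style scores are reduced to *per-atom means* before domain lookup:
cumulative scores grow with site size, so a small but perfectly
interface-like site would otherwise fall below every patch-derived
domain; the mean makes patches and sites of any size commensurable
(`RunConfig.domain_score_mode` switches back to cumulative sums). Taking
the scales two at a time, a candidate with Ƭ ≥ 0.25 against the actual
patch marks its (bin_x, bin_y) pair as accepting. Accepting bins
accumulate across the scan; the retained threshold is the one that gave
the most chains an accepted site (ties to the first in the list).

The optimal range per scale, per pair, is the contiguous hull from the
lowest to the highest accepting bin — correct sites sample an underlying
range, and at small training sizes the individually hit bins are a gappy
sample of it. A hull touching the first or last domain is open at that
end, since the training patches bound the domain grid but not the scores
a genuine site may take; scores beyond the grid clamp to the edge domain
during the scan, symmetrically. If training produced no accepted range at
all, prediction falls back to returning the ranked candidates unfiltered.

Prediction: grid → retain at the trained threshold → cluster (≤15) → drop
candidates whose mean scores satisfy no accepted scale pair → return the
top 10 by rank. A chain with no favourable points yields an empty
prediction with a warning.

Everything is deterministic given inputs and configuration; the ranges
JSON and site tables are byte-identical across repeated runs, which the
acceptance checks assert.

## Synthetic complexes

The fixture generator emulates, at desk scale, the two properties of real
interfaces the method exploits:

* **Shape complementarity.** Each chain is a slab of idealised residues —
  compact balls of carbon spheres (one per counted heavy atom, ~1.5 Å
  spacing) on a jittered 5.5 Å lattice, with one or two tip atoms on the
  contact plane. Chain B stands on a half-cell-offset lattice, so its
  central "knob" residues descend between chain A's tips: removing the
  partner leaves concave pockets whose lining atoms are exactly the
  demarcated patch, the way a probe map recognises real unbound
  interfaces. Residue bodies are kept thin and disordered so no straight
  inter-column channel stays probe-accessible below the surface.
* **Compositional bias.** Contact-zone residues are drawn 85% from
  hydrophobic types (Ile, Leu, Val, Phe, Met, Trp, Tyr) and the rest 90%
  from polar types, giving the RIP/ϕ/ΔG machinery a realistic signal.

The generator solves deterministically for the smallest contact zone (and,
if needed, a deeper interdigitation in 0.1 Å steps) that meets the
requested ACP count; ground truth is the demarcated interface itself, so
recovery tests close the loop through the same demarcation used on real
complexes. Batch datasets draw ACP targets uniformly from 60–300
(6–12 contact residues per chain on the default 40-residue chains),
reflecting the several-fold spread of buried-contact counts across real
interfaces. All randomness flows from one seeded generator; identical
specs give byte-identical PDB output.

What the fixtures do **not** emulate: covalent connectivity, backbone
geometry and rotamers, element diversity (all atoms are carbons),
electrostatics, crystallographic artefacts, and conformational change on
binding. Passing the recovery tests therefore demonstrates that the
pipeline's geometry, scoring, training and evaluation logic are correct
and self-consistent — not that the default parameters achieve any
particular accuracy on experimental structures.

## Default parameters

| Parameter | Default | Units | Rationale |
| --- | --- | --- | --- |
| contact tolerance | 1.0 | Å | standard demarcation slack over vdW sum |
| min ACPs per interface | 20 | – | filters crystal-packing contacts |
| grid spacing | 0.9 | Å | resolves pocket shape below atomic radius |
| grid padding | 4.5 | Å | covers the probe's favourable shell |
| LJ cutoff / clamp | 8.0 / +1000 | Å, kcal/mol | only the favourable tail matters |
| energy thresholds scanned | −0.5 … −3.0 | kcal/mol | brackets observed pocket depths |
| occlusion radius (pipeline) | 4.5 | Å | probe first coordination shell |
| linkage cutoff | 0.9·√3 | Å | 26-connectivity of the grid |
| max clusters / max sites | 15 / 10 | – | candidate and report caps |
| Ƭ threshold | 0.25 | – | correctness boundary, inclusive |
| IQR multiplier | 1.5 | – | Tukey default |
| RIP pseudocount | 0.5 | – | keeps propensities positive and finite |

## Known limitations

* The RIP table is an estimator, not a published reference; absolute RIP
  values depend on the training interfaces supplied.
* One global energy threshold is trained; per-scale-pair thresholds are
  not explored.
* Site ranking weights (propensity vs energy magnitude) are heuristic and
  exposed rather than learned.
* The evaluation is atom-level throughout; residue-level metrics used by
  some servers are out of scope.
* Runtime is dominated by the energy field; chains beyond a few thousand
  atoms will want a larger grid spacing.
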