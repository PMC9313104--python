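# Methods

## Scope and model of the system

`ppiface` analyses ensembles of receptor–ligand complex structures for a
membrane-embedded, two-subunit receptor — concretely, the Na,K-ATPase α1β1
pump interacting with the 42-residue amyloid-β peptide (Aβ42) and with
small-molecule candidate inhibitors of that interaction.  The package does
not dock, refine or screen: those stages run in external engines
(docking servers, an MD package, a virtual-screening program) and `ppiface`
consumes their end-frame PDB outputs.  What it owns is the analysis layer:
contact maps, interface calling, pose triage, cross-conformation
comparison, compound-fate classification and ITC-derived thermodynamics.

Three geometric abstractions keep the analysis independent of any
particular force field or bilayer model:

- **Membrane slab.**  The bilayer is a z-slab `[z_min, z_max]` with the
  normal along z.  Bounds come from explicit membrane atoms when present
  (min/max z of a selected atom-name pattern) or from the config.  The
  package never rebuilds a bilayer.
- **Inter-subunit cavity.**  The ligand-binding cavity between the α- and
  β-subunits is summarised by the unweighted Cα centroid of the declared
  target segments, with a vertical axis through it and a radius
  (default 12 Å).
- **Heavy atoms only.**  Hydrogens are dropped on reading; every distance
  criterion is defined on heavy atoms, because protonation conventions
  differ between docking and MD outputs.

Residue numbering is author (PDB) numbering, 1-based, with inclusive
segment ranges (`α 119–124` style).  Alternate locations resolve to the
highest-occupancy conformer (tie → first encountered).  Insertion codes
are rejected with a clear error; none occur in the systems this package
targets, and silently renumbering them would corrupt segment arithmetic.

## Contacts, profiles and interface segments

A *contact* is a (receptor residue, ligand unit) pair whose minimum
heavy-atom distance is ≤ a cutoff.  The default cutoff is **5.0 Å**, a
standard protein–protein interface definition; it is configurable because
published contact analyses range from 4 to 6 Å.  Ligand units are peptide
residues by default; for compounds the whole HETATM group is one unit, and
an atom-level grouping is available when per-atom resolution matters.

The production implementation uses a k-d tree (`scipy.spatial.cKDTree`);
the test suite holds it equal to an all-pairs O(N²) oracle on randomized
fixtures, so the tree is an optimisation, never a definition.

Per-model profiles count, for each receptor residue, the number of
distinct ligand units touching it (`pair_count`) or a 0/1 flag
(`binary`).  Ensemble aggregation is a plain element-wise sum — the
isoform-to-isoform differences in contact counts are treated as noise at
ensemble sizes of ~15 models, so no weighting is attempted.

Interface segments are called from an aggregated profile by a
relative-threshold rule: residues with count ≥ max(2, f·max) are seeds
(default f = 0.25), seed runs on one chain separated by ≤ 2 non-seed
residues merge, and runs shorter than 3 residues are dropped.  The
threshold is relative to the profile maximum because peak heights differ
substantially between receptor conformations; the absolute floor of 2
stops single stray contacts from seeding a site in sparse profiles.

The per-pose rating used for complex selection is a transparent surrogate
score: `distinct contacted receptor residues + 0.1 × contact pairs`.
Published docking-analysis servers do not disclose their exact rating
function; this surrogate rewards broad, multi-residue engagement, is
deterministic and is documented as a surrogate.  Ranking is descending
with lexicographic model-id tie-breaks.

## Pose acceptance criteria

Peptide poses from full-blind docking are accepted only if all three of
the following numeric criteria hold (each individually toggleable for
ablation):

1. **Cavity localisation** — ≥ 30% of ligand residue centroids within
   15 Å of the cavity centre.  The qualitative notion "mainly positioned
   in or near the cavity" has no published number; both thresholds are
   config parameters and the boundary is inclusive.
2. **Membrane avoidance** — exactly zero ligand heavy atoms inside the
   slab.  Strict zero, because any membrane-touching pose is discarded in
   this workflow.
3. **Multipoint binding** — contacted receptor residues fall into ≥ 3
   clusters pairwise separated by ≥ 20 residues in sequence (clusters on
   different chains always count separately).  Three sites matches the
   number of α-subunit interface regions in the target system.

## Cross-conformation consensus and orientation

Consensus over conformations is the strict intersection of per-conformation
interface residue sets, re-segmented with the same merge rule (by default
without gap bridging, so pure set semantics); the union is also reported,
since a universal inhibitor must cover every site.  Pairwise Jaccard
indices are reported, not thresholded — "practically identical" has no
canonical cut-off, and imposing one would manufacture a verdict.

Refinement narrowing is quantified as (total refined residues)/(total
docking residues), with refined segments matched to docking segments by
maximal residue overlap; identical stages give exactly 1.0.

Peptide orientation ("which terminus points into the cavity") compares
the heavy-atom centroid of the first five and last five peptide residues
to the cavity centre; a difference below 2 Å is called ambiguous.  The
5-residue window and the 2 Å band are design choices: the window is short
enough to represent a terminus and long enough to be robust to a single
flexible residue.

Regions deliberately excluded from the target site (β-subunit areas far
from the cavity) are subtracted from intersection/union segments but kept
in the report with their reason text.

## Compound fate classification and triage

Each post-refinement compound pose receives exactly one fate, tested in a
fixed precedence order:

| order | fate | rule (defaults) |
|---|---|---|
| 1 | `membrane_embedded` | ≥ 50% of heavy atoms inside the slab |
| 2 | `cavity_entered` | centroid within 12 Å of the cavity axis **and** below the interface Cα centroid z |
| 3 | `interface_bound` | contacts ≥ 3 distinct interface residues at the contact cutoff |
| 4 | `displaced` | none of the above |

The membrane fraction (0.5) and cavity radius (12 Å) have no experimental
definition and are config parameters.

Triage across conformations eliminates a compound on a *single* membrane
or cavity event — bilayer partitioning and channel entry reflect the
compound's chemistry, not the receptor conformation, so one event
predicts failure everywhere.  Survivors must be interface-bound in ≥ 2
conformations and are ranked by that count, with mean docking affinity
(more negative first) breaking ties; docking rank itself is ignored
except through affinity, because post-MD fate is empirically independent
of the initial rank.

## ITC thermodynamics

From each measured (Ka, ΔH) pair the package derives, exactly:
Kd = 1/Ka (reported in µM), ΔG = −RT ln Ka, TΔS = ΔH − ΔG, with
R = 1.9872×10⁻³ kcal·mol⁻¹·K⁻¹ and T = 298.15 K (25 °C).  Rounding occurs
only at the presentation layer: Kd to 2 significant figures, energies to
2 decimals, matching published ITC table conventions.

Published tables print rounded Ka values, so a ΔG recomputed from the
printed Ka can disagree with the printed ΔG by a few hundredths of a
kcal/mol.  `reconcile_row` therefore compares with a 0.02 kcal/mol
reconciliation tolerance and *flags* rows outside it instead of adjusting
them: in the five-state Aβ42 table shipped in `datasets`, four rows
reconcile within 0.01 (two exactly) and the E1 row is internally
inconsistent by 0.04 (printed Ka 3.7×10⁵ implies −7.60; printed ΔG is
−7.56).  The flag is the product; the printed numbers stay authoritative.

State similarity is the maximum pairwise |ΔΔG| with a default tolerance
of 0.6 kcal/mol, chosen from the stated ±20% relative uncertainty of the
Ka measurements (a 20% Ka shift moves ΔG by RT ln 1.2 ≈ 0.11 kcal/mol;
0.6 accommodates the observed spread plus enthalpy/entropy compensation
noise).  The competition check compares derived ΔG of the free receptor
vs the receptor pre-bound with a co-ligand at the same tolerance.

## Synthetic fixture generator

The generator produces the study conditions for every structural test:
two pseudo-helical residue walls (α = chain A, 100 residues; β = chain B,
60 residues) at x = ±8 Å, each with a 20-residue transmembrane stretch
inside a slab at z ∈ [−34, −4] Å and an extracellular grid above it, with
the 16 Å gap between the walls playing the inter-subunit cavity.  Each
residue carries a Cα and one side-chain pseudo-atom pointing into the
gap — sufficient for minimum-distance contacts without rotamer modelling.
Four interface segments are planted (three on α, one on β) with sequence
separations ≥ 20 so the multipoint criterion sees three α sites, as in
the real receptor.

Ensembles default to 15 models per conformation over three conformations
(E1P, E2P, OBN) with a 20% decoy fraction — 12 good poses plus one each
of the three violator classes — and peptide isoform tags cycling through
Aβ42/isoD7/pS8, mirroring the modelled study design (five models per
isoform per conformation).  Good poses anchor one peptide residue near
every one or two planted-segment residues and cluster the remaining
residues at the cavity mouth; violator poses break exactly the criterion
they are named for (the `far` class necessarily loses its contacts too).
Orientation series plant a prescribed C-in/N-in split (default 17/13 over
30 poses).  Placement jitter is Gaussian with σ = 0.3 Å — large enough to
perturb distances, small enough that planted contacts stay inside the
5 Å cutoff with margin.

All randomness flows from one `numpy` PRNG per planted object, seeded
from the fixture spec, so equal specs give byte-identical files; ground
truth (slab, cavity centre, planted segments, per-model class) is
serialised beside the fixtures so tests never re-derive it.

What the generator does *not* emulate: real side-chain packing, pose
diversity within a class, partial/fuzzy interfaces, conformational
differences between the three receptor states, or force-field energetics.
Passing the closed-loop tests therefore shows that the classifiers
implement their stated geometric rules and recover planted ground truth
under noise — not that the thresholds are optimal for any particular
experimental system.

## Problem sizes and numerical choices

Test and acceptance runs use the default fixture sizes above
(45 poses of ~530 atoms each, 100-fixture oracle comparisons), which keep
the full suite in the seconds range while exercising every code path at
the study's own ensemble sizes.  Distances are exact floating point
(no grid binning); contact comparisons against the oracle use a 1e-9 Å
tolerance; determinism tests compare files byte for byte.  Degenerate
inputs are defined, not special-cased: an empty contact list yields an
all-zero profile, an all-zero profile yields no segments, an empty pose
set filters to an empty verdict list, and a one-atom ligand inside the
slab has membrane fraction 1.0.

## Known limitations

- Contact chemistry (H-bonds, salt bridges) and buried surface area are
  out of scope; contacts are purely distance-based.
- The complex score is a surrogate; absolute values are not comparable to
  any published rating.
- The slab abstraction ignores membrane curvature and lipid identity.
- mmCIF, trajectories and insertion-coded structures are unsupported.
- Error propagation for ITC quantities is limited to the stated
  tolerances; no isotherm fitting from raw power traces.
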