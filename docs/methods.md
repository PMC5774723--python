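# Methods

This note documents the models, the synthetic-data design, the numerical
choices and the known limitations of `asitekit`. It states no empirical
result beyond what the test suite and `scripts/acceptance.py` compute.

## Sequence model and numbering

The two A-site constructs are bipartite duplexes: strand A (21 nt) and
strand B (23 nt) spanning the helix 44 region that contains both the
paromomycin/kanamycin bulge (A1408, A1492, A1493) and the hygromycin B
pocket (C1402–U1406 / U1495–A1500), with four stabilising G:C pairs
added at each terminus. Residues carry E. coli small-subunit numbering
through a single affine map — strand A position k ↦ 1396+k (1397–1417),
strand B position k ↦ 1483+k (1484–1506). The map is anchored on
text-verifiable labels (the named pairs G1401:C1501, C1407:G1494,
C1412:G1488; A1493 at strand-B position 10; the 1489–1498 oligomer
target window) and extended through the termini, where it is consistent
with every terminal residue mentioned in the source results (G1399,
A1413, G1486, G1502, G1504). Terminal labels outside the anchored span
are therefore a well-corroborated default, not an independent ground
truth; user-supplied numbering (including `"ext"` markers) overrides it.

The declared reference secondary structure contains only canonical
Watson-Crick pairs (16 prokaryotic, 15 eukaryotic — the C1409:G1491 pair
is lost to the C→A/G→A mutations). Non-canonical crystal-structure
pairs (U1406:U1495, C1403:U1498, C1402:A1499/A1500) are deliberately not
"reference pairs": the reference list feeds pair-complementarity
invariants and flip-angle flanking definitions, both of which require
canonical pairing.

Mismatch counting slides the oligomer over every contiguous target
window, pairing oligomer position k with window position L−k+1
(hybridization is antiparallel) and counting strict A:U / G:C matches
only. G:U wobbles count as mismatches — the reported 3/2/1 mismatch
counts of the three decamers against the eukaryotic strand B only
reconcile under strict Watson-Crick matching. Ties prefer the smallest
window start.

## Synthetic duplex scaffold

Trajectory analyses need coordinates with specific verifiable
properties, not physical realism. The generator builds an ideal
A-form-like lattice (rise 2.81 Å, twist 32.7°/step) of "rungs": each
reference pair occupies one rung; unpaired stretches between anchor
pairs are zipped into single- or double-residue bulge rungs, placed
intra-helically; opposed non-canonical residues are displaced ±1.2 Å
outward so that they neither clash nor hydrogen-bond in the ideal frame.

Bases are rigid planar templates: regular polygon rings (bond 1.38 Å)
with exocyclic heavy atoms and polar hydrogens at in-plane sp² positions.
The pairing geometry (C1'–C1' = 10.217 Å, per-class glycosidic opening
angles and in-plane base rotations) was calibrated once, by least
squares on the five canonical contacts, so that every A:U pair shows
exactly its two and every G:C pair exactly its three hydrogen bonds at
2.85–2.95 Å / 168–174°, with zero spurious bonds anywhere in the ideal
duplex. The exact template coordinates ship as package data
(`data/nucleotide_templates.csv`) and a test guards the file against the
code. The pseudo-ribose/phosphate backbone is schematic: the phosphate
bridges consecutive C1' atoms at larger radius, the 2'-OH points
outward; only phosphate centres of mass (flip dihedral) and O2' donors
(sugar-edge contacts) are load-bearing.

Scheduled extra-helical states rotate the nucleobase about the axis
through its own and its 3'-neighbour's phosphate groups. That axis is
exactly the central (b–c) axis of the flip pseudo-dihedral, so a
rotation by δ changes the dihedral by exactly δ and the ±165° target
pose is reached in closed form — no iterative tuning. (An alternative —
rotation about the glycosidic bond plus a backbone pivot, tuned to the
angle target — achieves the same contract less directly; the phosphate-
axis rotation was chosen because it makes schedule recovery exact by
construction.) The per-frame out-state sequence realises the requested
fraction to the nearest frame, with seeded placement; isotropic Gaussian
jitter is added last. All generators are bit-reproducible per seed.

Scaffold limitations: with zero base inclination the 2.81 Å rise puts
successive base planes closer than the ~3.3 Å perpendicular separation
of relaxed A-RNA, so absolute stacking energies on the scaffold are not
comparable to energy-minimized structures (the Lennard-Jones term can be
repulsive). The stacking module is therefore validated by brute-force
oracle equivalence, rigid-motion invariance and charge-scaling laws, not
by reproducing literature magnitudes. The scaffold likewise has no
sequence-dependent helical parameters, no solvent, no ions and no
backbone torsional realism; passing tests certify the *analysis
operators*, and the generator's statistical contracts, not force-field
physics.

## Hydrogen bonds and edge classification

Criteria: donor–acceptor ≤ 3.5 Å and acceptor–hydrogen–donor ≥ 150°,
intra-residue contacts excluded; donors missing their hydrogen are
skipped with a logged warning. The donor/acceptor catalogue covers the
standard base amine/imine donors, carbonyl/ring-N acceptors, the O2'
hydroxyl (donor and acceptor) and backbone phosphate/ester oxygens as
acceptors.

Each bonded base atom maps to one or two of the three Leontis–Westhof
edges via a per-base table (module data, overridable); atoms shared by
two edges (A:N6, G:O6, G:N2, C:N4, C:O2, U:O4, U:O2) are the "corner"
atoms. A residue's edge is the intersection of its bonded atoms' edge
sets; a two-edge intersection from a genuinely single-bond contact is
reported as the ambiguous asterisk type (e.g. `WC*HG`); with several
bonds the first-listed edge is kept; an empty intersection falls back to
a majority vote with WC > HG > Sugar priority. These tables are a
documented convention — the annotation tool used by the source study
does not publish its variant — so they are data, not hard-coded truth.
A pair is WC-WC iff both partners resolve to the plain WC edge;
H-bond counters attribute every classified pair to exactly one of the
WC-WC / non-WC-WC totals. Pairs bonded solely through phosphate
backbone atoms are not base pairs. Occupancy tables keep all raw
fractions and suppress entries at or below the reporting threshold
(default 5% of frames) only in the reported view.

## Stacking energetics

Two bases are stacked when their six-membered-ring centroids are within
4.5 Å and their ring planes within 30° (defaults, config-overridable;
detection thresholds are an assumption, as the source pipeline does not
print its criterion), excluding pairs that are hydrogen-bonded in the
same frame. The energy is the no-cutoff sum over heavy base atoms of
k·qᵢqⱼ/r (k = 332.0636 kcal·Å·mol⁻¹·e⁻²) and
ε_ij[(R_ij/r)¹² − 2(R_ij/r)⁶] with ε_ij = √(εᵢεⱼ),
R_ij = R_i/2 + R_j/2. Charges and LJ parameters ship as an
Amber-94-lineage table (`data/base_charges.csv`, user-replaceable).
Region averages attribute each stacked pair's energy half to each
partner, so pairs interior to a region count exactly once in the region
sum; per-nucleotide values divide by the region size, and means ± std
are taken across frames.

## Flip angle

Four mass-weighted centres: (i) flipping nucleobase heavy atoms,
(ii) own phosphate {P, OP1, OP2}, (iii) 3'-neighbour's phosphate,
(iv) base heavy atoms of the two reference pairs flanking the residue
along its own strand (base atoms only — including sugars would mix in
backbone geometry the angle is meant to factor out). Flanking pairs
come from the declared reference structure, not per-frame detection, so
the angle stays defined when neighbours transiently unpair. States:
|angle| < 50° in, |angle| ≥ 140° out, intermediate between; the out
threshold interpolates between the stated "roughly (−50°, +50°)"
intra-helical range and "close to ±180°" extra-helical poses. Angles in
(−180°, 0) face the major groove, (0, 180°) the minor groove.

## Global metrics

RMSD uses Kabsch superposition (SVD with determinant correction),
mass-unweighted, on heavy atoms by default (terminal residues included;
both inclusive and restricted selections are supported since the source
figures do not state theirs). RMSF superposes each frame onto the
average structure in a single pass and reports per-residue
root-mean-square deviations from the time-average positions; the single
pass is standard practice and its difference from full iteration is far
below fixture tolerances. gromos clustering repeatedly extracts the
structure with the most neighbours within the cutoff (ties to the lowest
frame index) together with its neighbours; stride is configurable (the
source sampled one structure per 100 ps).

Blocked standard errors use power-of-two block sizes up to N/4 with
sample standard deviations, so BSE(1) = std/√N exactly. The optional
analytic fit assumes the autocorrelation is a sum of two exponentials,
giving block-mean variance σ²·Σaᵢ·g(m/τᵢ), g(x) = 2(x−1+e⁻ˣ)/x²; it is
fit in log-τ with normalised amplitudes.

## Thermodynamics

The duplex-fraction quadratic is inverted analytically in the
cancellation-free form f = a/(1 + a + √(1+2a)), a = Ka·c₀. The melting
fit floats (ΔH, ΔS) and four baseline coefficients; initial guesses take
baselines from the first/last 15% of points, Tm from the absorbance-
derivative extremum, and ΔS from the Tm relation Ka(Tm) = 4/c₀ at
ΔH₀ = −80 kcal/mol. Tm has the closed form ΔH/(ΔS − R ln(4/c₀)).
A fit is flagged unsuccessful when its midpoint falls outside the
measured range or when a straight line explains the data essentially as
well as the two-state model (no transition signal) — mirroring the
curves in the source data that could not be fit for lack of plateaus.
Van't Hoff analysis reconstructs f from the fitted baselines, keeps
f ∈ [0.15, 0.85] by default (the baseline-dominated tails carry no
slope information; the window is configurable as the source does not
state its own), and runs OLS of ln Ka against 1/T with
R = 1.987204×10⁻³ kcal·mol⁻¹·K⁻¹. ΔG and TΔS are reported at
T_ref = 294.15 K (21 °C). A temperature-dependent-ΔH (nonzero Δcp)
variant is intentionally not implemented; the linear van't Hoff form is
the analysis of record here.

The ITC model tracks total concentrations with the standard well-mixed
displacement bookkeeping (each injection expels a fraction v/V₀ of both
species before adding titrant; default active volume 190 μL, the
low-volume calorimeter class used in the study), solves the single-site
quadratic for the bound concentration and assigns injection heats
ΔH·V₀·(Bᵢ − Bᵢ₋₁(1 − vᵢ/V₀)). The same forward model serves generator
and fitter; independent checks are the thermodynamic closure of summed
heats and the printed-value consistency tests. Dilution-heat handling:
fixed value, post-saturation average of the last k = 3 injections
(default; requires a detected plateau — tail spread under 2% of the heat
range), or free parameter (automatic fallback, with a warning, when no
plateau exists — both modes exist because the source does not state
which it used per dataset). A titration of identical heats is flagged:
ΔH = 0 and Ka indeterminate. Ka is fit in log space within
[1, 10¹⁴] M⁻¹.

## Reference tables and the acceptance computation

`asitekit.reference` carries the measured duplex thermodynamics
(UV melting and ITC at 21 °C) for the five systems, used as simulation
conditions and consistency surfaces. Two systematic caveats surfaced by
the analysis scripts: free energies derived from association constants
printed to one significant figure carry ~0.1 kcal/mol of print-rounding,
and the eukaryotic model's ΔH/TΔS imply a melting midpoint ~2 °C below
its separately reported Tm — the table rows are independently rounded
replicate averages, not jointly consistent parameter sets. The
acceptance script therefore anchors on the prokaryotic melting round
trip (whose implied midpoint matches the reported 52.9 ± 0.5 °C) and
the eukaryotic ITC round trip (Ka to two significant figures).

Problem sizes: melting curves use 161 points over 10–90 °C; titrations
use the study's 20/25-injection schemes; synthetic trajectories in the
analysis scripts use 40 frames of the ~1 070-atom duplexes with 0.15 Å
jitter, and the statistical tests use 2¹⁰–2¹⁵-point series — sizes
chosen so every property they certify is already at its asymptote while
the whole suite runs in seconds.

## Simulation-scale results are out of reach by design

The source study's occupancy percentages, cluster populations and
absolute stacking sums emerge from 1.15 μs of explicit-solvent MD; no
desk-scale computation reproduces them. The package's contract is
correctness of every operator on data with known ground truth (oracle
equivalence, exact schedule recovery, closed-form statistics) plus
reproduction of the desk-derivable printed numbers (sequence mismatch
counts, thermodynamic self-consistency, fit round trips).
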