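# Model and methods

`rootprime` simulates a 2-D longitudinal cross-section of the *Arabidopsis
thaliana* root tip to study how transient, periodic elevations of auxin in
cells entering the elongation zone ("priming") are converted into stable
prebranch sites (PBSs) — pericycle cells that persistently maintain elevated
auxin signalling and mark future lateral-root positions.  The model couples
four layers: grid-level auxin transport, cell-level gene regulation, a
slow chromatin state that time-integrates auxin signalling, and
deterministic root growth.

## Tissue representation

The root is a regular grid (default 141 x 1516 points at dx = 2 um, i.e.
282 x 3032 um; row 0 is the tip).  Each point is cell interior, membrane,
wall, or outside.  Cell files (lateral-root cap, epidermis, cortex,
endodermis, pericycle, and two vasculature files per side, bilaterally
symmetric) are vertical strips of rectangular cells separated by
one-point-thick walls.  The curved tip (quiescent centre, columella, lower
LR cap) is a static stepped template whose cells never grow.  Developmental
zones are superimposed by distance from the tip: meristem up to 514 um
(LR cap: 314 um), with the 364–514 um band a transition zone (growth
without division), the elongation zone beyond, and the differentiation zone
once a cell's differentiation factor exceeds 85.  A `zone_scale` parameter
shrinks these boundaries proportionally for the miniature test tissue
(45 x 200 points, `zone_scale` = 0.25).

## Auxin transport

Intracellular auxin obeys a reaction–transport equation per grid point:
production, first-order degradation, diffusion (D_cell = 600 um²/s within a
cell, D_wall = 40 um²/s between wall points), and carrier-mediated membrane
transport across each membrane|wall interface,

    efflux = (eff_basal + p_PIN · PIN_mem) · a_cell,
    influx = (inf_pas + p_auxlax · (AUX1_mem + LAX3_mem)) · a_wall,

where membrane carrier levels are the product of a cell-type- and
zone-specific placement prepattern (weights in [0, 1]) and the cellular
expression level (PIN constant at 100; AUX1 and LAX3 dynamic).  Transport
parameters are permeabilities (um/s): p_PIN = p_auxlax = 0.2 per expression
unit (20 um/s at full expression), eff_basal = 0.3, inf_pas = 2.5.  PIN
polarity encodes the root-tip reflux loop: rootward in the stele, outward
in the columella, shootward in LR cap and epidermis, rotating inward at the
elongation zone, and more apolar endodermal/cortical placement in the DZ.
The DZ epidermal conveyor is largely depolarised so that auxin arriving
shootward dissipates with distance rather than accumulating at the domain
top; this dissipation is what makes priming transient in the baseline
model.

Production per point is `p_auxin_baseline · (celltypefactor +
yucca4factor · YUCCA4) · (h_ref / h)`; the height normalisation keeps a
cell's total production independent of its current height.
`celltypefactor` is 100 for the QC, the top columella layer and the
vascular initials, 50 for lower columella, 30 for the LR cap and 1
elsewhere.  `yucca4factor` = 0.1525 makes maximal YUCCA4 expression (100)
raise production 16.25-fold.  At the shootward boundary, walls above the
topmost vascular/pericycle/endodermal cells receive an inflow equal to a
small external auxin level times those cells' efflux capacity, and walls
above the topmost epidermal/cortical cells lose wall auxin at 10 % of those
cells' influx capacity.  A weak left–right exchange between laterally
symmetric wall points, scaled inversely with their radial distance, emulates
the 3-D tissue (D_rad = 10 um/s); a variant adds efflux:influx-ratio
weighted exchange between symmetric cell points, and an "enhanced" variant
multiplies the coupling fivefold.

### Numerics

The PDE advances with an alternating-direction semi-implicit scheme:
a Strang composition of implicit tridiagonal sweeps (half-step along rows,
full step along columns, half-step along rows), with production, decay,
boundary and radial terms applied explicitly in half-steps around the
sweeps.  Because carrier transport enters the sweep operators implicitly,
the scheme is unconditionally stable and positivity-preserving for the
stiff membrane rates, and the implicit solves conserve mass exactly (the
transport operator's columns sum to zero).  The stiff epidermal/cortical
boundary-outflow term is likewise folded into the column sweep's diagonal.
The directional splitting is formally first order in dt for the stiff
carrier terms: at the production step of 0.4 s, halving dt changes
per-cell auxin after one simulated hour by roughly 10 % (max-norm; mean
~2 %).  Default steps are dt = 0.4 s and dx = 2 um; the miniature test
tissue runs at dt = 2 s, trading accuracy for suite speed — all activation
thresholds are calibrated at that step.  A non-negativity clip backstops
the explicit reaction terms; it does not trigger at default settings.
Gene-expression ODEs use forward Euler at the same dt, after the PDE step
(operator splitting with a single clock).

## Auxin signalling

Baseline signalling is equated to cellular auxin (ubiquitously expressed
ARFs are not modelled).  Where priming-induced ARF expression is enabled,
total signalling S = auxin + the free part of the induced ARF pool.  Free
ARF follows from a quasi-steady-state reduction of ARF–AUX/IAA binding with
AUX/IAA produced at rate pIAA·IAAreg and degraded basally plus through
TIR1 in proportion to auxin:

    ARFfree = ARFtotal / (1 + (bind/unbind) · IAA_qss),
    IAA_qss = pIAA · IAAreg / (d_IAAbasal + dIAATIR1 · auxin).

The reduction matches the equilibrium of the unreduced two-ODE system to
numerical precision and is monotone increasing in auxin.  ARF expression has
a basal part (steady level 10) and an auxin-induced part (combined maximum
300, half-activation Km = 30) restricted to elongation/differentiation-zone
cells past the differentiation gate.

## Gene expression

All genes are protein-level ODEs with a 1:100 degradation:production ratio
(maximum level 100) and decay rates in 1.0–1.5 x 10⁻⁴ s⁻¹ (half-lives
1.3–1.9 h).  AUX1 production saturates in auxin (Km = 75; the
symmetry-breaking experiment uses 85).  LAX3 is constant (40) in the
baseline model; in the direct-feedback model it gains an auxin-induced part
(Km = 20); in the time-integrated model its auxin-dependent expression is
split into an ungated vascular part and a chromatin-gated priming part.
YUCCA4 (auxin-biosynthesis; induced only in vasculature and pericycle of
the EZ/DZ) and the priming part of LAX3 use deliberately high
half-activation constants (150 a.u.) so that they engage only in cells
mounting the secondary response.  A generalized differentiation factor
Diff is produced only outside the meristem (1:100 ratio,
d = 5 x 10⁻⁵ s⁻¹, so the Diff > 80 expression gate opens several hours
after elongation-zone entry — after the priming signal has declined) and
decays otherwise, allowing dedifferentiation.  All auxin-induced LAX3,
YUCCA4 and ARF expression requires Diff > 80, producing the delayed
secondary response; bridging the gap between priming and that gate is
exactly the role of the chromatin integrator's retentive memory.

## Chromatin integrator (EpiO)

EpiO represents the open-chromatin state of the priming-response locus:

    dEpiO/dt = open · F1(S) · (1 − EpiO/EpiO_cap)
               − close · max(frac_min, (1−F1)(1−F2(EpiO))) · EpiO

Opening is capacity-limited (a finite pool of chromatin sites; the
capacity constant is set so the saturating-input steady state is exactly
100) and driven by a steeply cooperative function of signalling, F1
(half-max Km_EpiO_1 = 290 a.u., exponent 8): chromatin modifications are
highly cooperative, and the steep switch places opening just beneath the
elongation-zone priming spike, so both the spike's amplitude and the time
spent in it set the integrated exposure.  Closing is inhibited by
signalling and — crucially — by the open state itself through F2
(half-max Km_EpiO_2 = 35, exponent 12, representing transcription from
open chromatin opposing closing), with a floor frac_min = 0.05.
open = 3 x 10⁻² and close = 1.5 x 10⁻⁴ give the steady state of 100.

This composition makes the integrator's memory bistable: a cell whose
time-integrated priming exposure drives EpiO above the F2 knee (~45)
enters the protected regime where the closing rate collapses to its floor
(half-life ~26 h) and the state is retained across the hours separating
the priming peak from the differentiation gate; weaker exposures leave
EpiO in the unprotected regime where it evaporates within one to a few
hours.  Because opening integrates F1(S) over time, equal-amplitude
inputs of longer duration leave more open chromatin, and normalized
differences between cells are amplified relative to their input
differences.  A sigmoidal gate F3(EpiO) (half-max Km_trans = 32,
exponent 6) multiplies the auxin-induced production of ARF, YUCCA4 and
priming-LAX3 in the time-integrated model.

Absolute simulated auxin concentrations are arbitrary (transport models
reproduce relative patterns only), so all activation thresholds are placed
relative to the realized gradient such that activation occurs in the right
spatial domains.  On the miniature tissue the pericycle profile runs at
~110–140 a.u. through the meristem, spikes to ~260–390 for one to a few
hours as the cell transits the elongation-zone auxin-loading domain (the
spike's amplitude oscillates with the priming events), and then dissipates
from ~100 down to ~15 through the differentiation zone.  Km_EpiO_1 = 290
sits far above the meristem and ambient-DZ levels and inside the range of
the oscillating spike, so strongly primed cells open chromatin several
times faster than their neighbours; the retention knee then keeps only the
most-exposed cells' state alive until the expression gate.  These
thresholds are the model's principal discrimination dials: lowering them
makes every differentiating cell mount the secondary response (the
phenotype of the auxin-homeostasis mutants), raising them abolishes the
response altogether.

## Lateral inhibition (TOLS2)

The peptide pathway is reduced to one species: TOLS2 production saturates in
free ARF (Km = 100, exponent 2) at a maximum rate 1000-fold its decay rate
(compensating for production in few cells), moves by conservative
cell-to-cell diffusion over the adjacency graph, and raises AUX/IAA
production in receiving cells via

    IAAreg = 1 + p · F(TOLS2; Km_IAA_1) · (1 − F(ARFfree; Km_IAA_2)),

so that a cell's own high free ARF protects it while low-ARF neighbours are
repressed — the asymmetry that lets the rootward, stronger PBS shut down the
shootward, weaker one.  On the miniature tissue the mutual repression thins
the set of cells maintaining a secondary response roughly three-fold and
lowers the survivors' signalling (the underlying study likewise notes that
levels drop somewhat in the surviving PBS).

## Growth and division

Cells carry a continuous length advancing exponentially at ln2/cellcycle
per um (cell cycle 9 h in the meristem; expansion timescale 7 h in the EZ;
the transition zone uses the meristem rate); when the continuous length
exceeds the integer grid length by one, a row is inserted at mid-height,
duplicating the local auxin concentration (no dilution; expression states
are per-cell and unaffected).  Meristematic cells divide on doubling their
birth length; the division plane inserts one wall row, the rootward daughter
receives the extra row for odd sizes, and daughters inherit expression state
and membrane prepattern verbatim.  Whole-meristem synchrony is broken
deterministically: a cell's growth rate is shifted by +5 %, −5 % or 0
according to the birth row of its centre modulo 3.  The domain is constant
size: cells whose apical wall reaches the top row are culled, and LR-cap
cells are shed once displaced past the LR-cap meristem boundary.  There is
no random number generator anywhere; runs are bit-identical and forks resume
exactly.

At simulation start the upper domain is seeded with a differentiation ramp
(cells beyond the EZ onset begin partly or fully differentiated) and the
auxin field is zero.  Scenario runs that study the time-integrated feedback
hold EpiO closed during a burn-in (12 h on the growing miniature tissue;
20 h in the no-growth experiment, whose fixed point takes longer to
establish) so the feedback engages on the established baseline root rather
than on the start-up transient.

## In-silico experiments

Ten presets reproduce the study's perturbations: baseline (signalling =
auxin), direct feedback (LAX3+YUCCA4+ARF induction gated by differentiation
only), time-integrated feedback (EpiO gating), TOLS2 lateral inhibition,
symmetry breaking (10 % AUX1 reduction on one side plus Km 75→85), reduced
auxin content (all production and boundary auxin x 0.9), *potent/arf7*
(maximum ARF x 0.5, boundary influx x 1.4), auxin homeostasis (influx x 1.4
plus ARF-dependent extra auxin degradation, rate multiplied by
1 + k·ARFtotal/ARFmax with k = 0.004), apolar-equal DZ PIN (endodermis and
cortex DZ placement identical to EZ), and a no-growth pulse experiment
(growth off, chromatin opening blocked across the persistent auxin-loading
domain — the first 200 um of the EZ before zone scaling — and a
250 a.u. / 3 h auxin level imposed on a shootward EZ band).  In that
experiment the imposed level must exceed both the chromatin-opening
threshold and, at this tissue scale, a carrier-retention bistability of
the non-growing field: 250 a.u. for 3 h triggers a persistent secondary
elevation while 80 a.u. for 3 h, or 250 a.u. for 20 minutes, relax back to
the fixed point.  The
"10 % reduction in root tip auxin content" is implemented as scaling all
production rates and the boundary auxin level by 0.9; the *potent/arf7*
"40 % more auxin" enters through the boundary inflow.  Both are
interpretations of summary statements and are exposed as plain config
fields.

## Observables

Kymographs sample a one-point-wide line through the middle of the left
pericycle file every 100 s.  The "experimental" style skews the matrix by
the cumulative number of rows inserted below, anchoring differentiated
cells at fixed positions, and pads culled tissue forward in time.  Cell
traces follow pericycle cells from the moment they pass a reference
distance (500 um at full scale, scaled with the zones).  Priming events are
groups of consecutive cells whose EZ peak signalling stands out from the
inter-event minima by a prominence criterion.  A stable PBS is a cell
whose median-smoothed signalling re-rises after its post-priming trough —
the trailing-window mean reaching at least 1.8 times that trough — and
whose elevation persists to the end of its trace rather than passing as a
travelling crest; `far_dz_signalling` complements this with the mean
signalling a cell carries beyond a reference depth of the DZ, which
separates secondary responders from passively dissipating cells by a
factor of ~3 on the miniature tissue.  All of these criteria are
operationalizations — the underlying studies show but do not numerically
define these features — and every threshold is exposed as an argument.

## What the miniature tissue does and does not show

The test tissue (45 x 200 points, quarter-scale zones, dt = 2 s) exhibits
the full mechanism chain: reflux-driven auxin loading at the EZ onset,
growth-driven oscillation of that loading, shootward dissipation,
time-integrated discrimination of the most-strongly primed cells, their
ignition into stably rising signalling, and the dosage/lateral-inhibition
perturbations thereof.  Because it hosts fewer and relatively larger cells,
its priming events comprise fewer cells and a shorter period than the
full-scale root's (~10 cells at ~6 h), and quantitative figures (per-cell
normalized differences, exact narrowing counts) are expected to match the
full-scale model only qualitatively.  Full-scale runs (141 x 1516, days of
simulated time) reproduce the original geometry exactly but take hours to
days of CPU; they are run through the CLI, not the test suite.

## Known limitations

Cell walls are parallel across files (the staggered-wall robustness variant
is out of scope); there is no mechanical interaction, bending or tropism;
auxin metabolism is first-order decay plus the homeostasis variant; the
ARF-dependent degradation term and the composition of total signalling from
auxin and free ARF are deliberately minimal functional forms chosen for
their qualitative behaviour; and the lateral-inhibition pathway is a
single-species proxy for a multi-component peptide network.
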