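# Methods

## Respiration-curve model and parameter extraction

A PM well trace is a sequence of OmniLog-unit readings (instrument-arbitrary
absorbance; treated as dimensionless) over hours. The fitted model is a
cubic smoothing spline minimising `Σ(yᵢ − s(tᵢ))² + λ∫s″²`. λ is selected
by hold-out cross-validation: each candidate on a 13-point log grid
(10⁻⁶…10⁶, spanning near-interpolation to near-linear on hour/unit scales)
is fitted to the even-indexed observations and scored by squared prediction
error on the odd-indexed ones. When a whole plate is called at once, one
shared λ (the median over a deterministic sample of five wells) is used:
measurement noise is a property of the instrument run, not of individual
wells, and this keeps a 96-well plate to one spline solve per well. Series
shorter than five points fall back to an interpolating cubic spline; series
shorter than four are rejected.

Parameters, from the fitted curve over the observed interval:

* **A** — maximum of the fitted curve (on a 2001-point grid). For a curve
  still rising at the final read, this is the value at the window edge, not
  an extrapolated asymptote.
* **μ** — maximum of the fitted first derivative (units/h).
* **λ (lag)** — tangent-intercept convention: the tangent at the steepest
  point intersected with the baseline, where the baseline is the fitted
  value at the first observation. Flat or falling traces (μ ≈ 0) have no
  rising phase and report NaN.
* **AUC** — trapezoidal integral of the fitted curve evaluated at the
  observed times; no resampling is imposed, so missing reads are simply
  absent panels of the trapezoid sum.

## Positive calling

`ΔA = A_test − A_negcontrol − A_blank`, positive iff `ΔA > θ` (strict; ties
are negative; θ defaults to 0 and is configurable). Subtracting *both*
references treats the abiotic dye–medium reaction as the sum of the
negative-control and blank signals; the published description of this
arithmetic is ambiguous between that sum and a control-only subtraction, so
a `subtract_mode` switch (`both` | `control_only`) exposes the alternative
rather than silently resolving it. For replicate designs, the conservative
aggregation — positive only if positive in every replicate — is the default
stance; replicate agreement itself is quantified by pairing per-well maxima
and counting deviations above a cutoff (50 units by default, the scale at
which real replicate scatter becomes noteworthy).

## Evidence ledger

BLAST tabular rows (12-column outfmt-6) are retained strictly below the
E-value cutoff. The default cutoff is 0.005: the study's analysis applied
"below 0.005" while its screening step mentions a looser ≤0.05; the
stricter value governs and the parameter is exposed so either convention can
be applied deliberately. A retained hit is only *provisionally* passed —
a curator file (compound, EC, gene, status) can downgrade it to
`failed_manual_qc`; the tool never finalises a bare BLAST hit without either
an annotation-database source or explicit curation, mirroring the manual QC
step of the workflow. The ledger keeps one row per (compound, EC) with the
best evidence (pass > failed > insignificant; ties by E-value then gene id),
and a compound is included in the model expansion iff it has ≥ 1 QC-passed
record. Filtering is idempotent, monotone in the cutoff, and order-free.

The bundled `curated_evidence.tsv` encodes the published curation summary
for the *C. reinhardtii* study: 16 compounds, 48 distinct EC numbers, with
pass/failed-QC/insignificant-E-value outcomes and the annotated gene ids.
The study's complete supplementary curation (49 ECs, plus every dipeptide
identity) is not redistributable here; quantities that depend on it are
computed from the bundled table and reported as such.

## Network model and the expansion manifest

Metabolite ids carry COBRA-style compartment suffixes (`pyr[c]`, tolerant of
`pyr_c` on input); coefficients are negative for substrates; bounds are in
mmol/gDW/h; gene associations are opaque-id boolean strings (annotation
dialects — Phytozome, JGI, AUGUSTUS, NCBI — differ, so identity is exact
string match). SBML I/O targets the Level 2 COBRA dialect (bounds as
kinetic-law parameters, `GENE_ASSOCIATION:` notes, `boundaryCondition`
species, `FORMULA:`/`CHARGE:` species notes); write∘read is the identity on
metabolites, reactions, bounds, associations and objective.

**Uptake via boundary species.** New transports create the extracellular
species as a *boundary* species (mass balance not enforced), making the
passive transport itself the uptake route. An explicit exchange reaction is
available as an option but is off by default: with mandatory exchanges the
published arithmetic (254 added reactions, of which 120 transports, summing
with the base's 2,191 to exactly 2,445) could not hold, and the
no-new-root-gaps outcome requires every transported compound to be
suppliable. Boundary species carry no balance row, no shadow price, and are
never gap candidates.

All constructed enzymatic reactions are cytosolic (the localisation
predicted for the new gene products). Protonation states are chosen so each
template balances atoms and charge exactly: amino acids as neutral/zwitterionic
formulas with 2-oxo acids as monoanions, ammonium as NH₄⁺, phosphate as
HPO₄²⁻, cysteamine-S-phosphate as the monoanion with cysteamine in its
ammonium form. Peptide formulas are computed as the residue sum minus one
water per bond, so hydrolysis is element-balanced by construction; repeated
residues accumulate product multiplicity (Gly-Gly → 2 glycine). The
element-balance checker skips (with a warning) any reaction touching a
formula-less species rather than guessing.

The study manifest rebuilds the 254-reaction refinement programmatically:

* 20 amino-acid reactions: 8 d-amino-acid oxidations (Ala, Asn, Asp, Glu,
  Lys, Ser, Val, 2-aminobutyrate, each with its packaged 2-oxo product), the
  reversible d-alanine transaminase, 8 d/l racemases, the d-serine kinase
  (ATP + d-Ser → ADP + O-phospho-d-serine), a d-serine ammonia-lyase and an
  ethanolamine ammonia-lyase;
* 108 dipeptide and 5 tripeptide hydrolyses — eight dipeptide identities are
  published (Leu-Pro, Ala-His, Asp-Leu, Asp-Phe, Pro-Asp, Asp-Ala, Asp-Gln,
  Asp-Gly); the remainder and the tripeptides are synthetic stand-ins filled
  deterministically from the 20-residue enumeration, since the full positive
  list was not redistributable;
* the cysteamine-S-phosphate phosphatase — a phosphorus-assimilation
  reaction fitting none of the four headline classes, which is exactly why
  those classes sum to 253 while 254 reactions are added; the expansion
  delta carries this note instead of reconciling it;
* 120 passive transports: the 113 peptides, cysteamine-S-phosphate, and six
  of the eight d-amino acids. The published transport count (120) is fewer
  than the transported compounds (~122), implying some carriers pre-exist in
  the base network without saying which; this package designates the
  d-alanine and d-serine carriers (and the ethanolamine carrier used by the
  lyase) as pre-existing, seeded in the synthetic base model.

The 20 new genes comprise the 15 published ids (9 annotation-database, 6
PSI-BLAST transcripts) plus five placeholder racemase gene ids
(`racg1`–`racg5`), synthetic stand-ins for curation entries whose published
identities were in the non-redistributable supplement; they preserve the
1,086 + 20 = 1,106 gene arithmetic and are labelled as such in the manifest
docstring.

`expand_model` copies the base (never mutating it), rejects duplicate
reaction ids, and reports added reactions by class, added species and added
genes; expansion is associative over disjoint manifests and never shrinks
any count.

## Flux balance analysis and shadow prices

Maximise the objective flux subject to `S·v = 0` (rows for non-boundary
metabolites) and bounds, solved with HiGHS (`scipy.optimize.linprog`;
feasibility tolerance 10⁻⁹, dual tolerance 10⁻⁷; deterministic by
construction). Infeasible/unbounded outcomes are reported as a status, never
raised. The shadow price of metabolite *m* is defined as the marginal change
of the maximal objective per unit of extra availability of *m* (one free
unit supplied); solver duals are normalised to this convention, and the test
suite verifies it against finite-difference re-solves (ε = 10⁻³) on
non-degenerate instances. Strong duality (primal = dual objective within
10⁻⁶ relative) is audited on every reported optimum.

LP duals are non-unique under degeneracy. Each solution carries a
`degenerate_flag` from a primal-degeneracy probe — more variables at their
bounds than the vertex dimension `n − rank(S)` requires (rank is replaced by
the row count on problems too large to decompose). This is a heuristic:
it may flag benign cases, so dual comparisons always use a tolerance τ
(default 10⁻³) and absent metabolites are treated as absent, not zero.
On the sign semantics: a positive shadow price is reported as the metabolite
being in *excess* supply capacity for the objective (more would raise it)
and a negative one as *limiting*, matching the usage conventions of the
study this pipeline reproduces; some texts attach the labels the other way
around, so the classifier's mapping is explicit and documented here.

Condition presets identify exchanges by configurable id patterns (defaults:
`photon|hnu` and `EX_ac...`), since medium composition lives in the model
encoding rather than the pipeline: `light` closes acetate uptake and leaves
photon exchange at its encoded bounds; `dark` closes photons and opens
acetate at its encoded bound.

## Root gaps

A root gap is a metabolite with no production route. The structural
(default) detector counts as producers: positive stoichiometry in any
reaction, negative stoichiometry in a *reversible* reaction (bounds
ignored — reversibility is treated as intrinsic), and uptake-admitting
exchanges. The LP detector respects bounds: *m* is unproducible iff the
maximal flux through a temporary drain of *m*, with all exchanges opened, is
≤ 10⁻⁹. Every structural gap is also LP-unproducible (bounds only remove
routes); where the two disagree, both reports are emitted so the discrepancy
is visible. Boundary species are excluded as candidates.

## Synthetic data: what it emulates, what it does not

* **Plates** — logistic respiration curves (amplitude 150–250 units,
  steepness 0.08/h, midpoints 40–90 h) over a linear abiotic drift
  (0.05 units/h, present in every well including blanks and the A1
  negative-control water well) with Gaussian noise (σ = 2 units), read
  hourly for 168 h. This is the simplest family matching observed sigmoid PM
  kinetics; it makes no claim about tetrazolium dye chemistry,
  compound-specific kinetics, or plate-position effects. Planted positives
  sit ≥ 10σ above background, so perfect recall on synthetic plates shows
  the pipeline's arithmetic and thresholding are right — not that real,
  marginal wells are this easy.
* **Toy networks** — parallel substrate chains feeding one biomass
  precursor, with distinct uptake caps (one chain optionally carrying a
  strictly tighter interior bottleneck). The optimum is the analytic sum of
  chain capacities; shadow prices are 0/1 by position relative to each
  chain's binding constraint; planted orphan metabolites are root gaps by
  construction. Binding constraints are kept unique so duals are
  non-degenerate.
* **Printed-size base network** — reproduces a curated base model's *size*
  (2,191 reactions, 1,706 metabolites, 1,086 genes) around a functional
  core: capped medium exchanges (photons 60, acetate 30, ammonium 25
  mmol/gDW/h — nitrogen-limited under light so that new nitrogen routes are
  economically meaningful), photon- or acetate-driven carbon fixation,
  amino-acid synthesis, ATP synthesis, biomass, and a deterministic
  reversible filler network disconnected from biomass. It supports count
  arithmetic, expansion, preset and gap-delta demonstrations; it does not
  reproduce any real network's gap set or dual structure, and quantities
  that require the real expanded model (its 91 root gaps, its
  per-metabolite dual values) are only computed when that model file is
  supplied externally.

A known consequence of the stand-in's sparse core: most newly added
reactions carry zero flux at optimum because their products (e.g. the 2-oxo
acids) have no downstream consumers there, so expansion changes the
objective and duals far less than in a full reconstruction. This is a
property of the stand-in, not of the expansion machinery.

## Problem sizes and tolerances in the checks

The test suite and the acceptance script use 50 seeded toy models for
optimum/duality checks (tolerance 10⁻⁶), 20 seeded plates for
recall/false-positive measurement, a 27-point noiseless logistic grid for
parameter recovery (2% closed-form agreement, using the exact
tangent-intercept lag including its finite-baseline correction and the
window-edge maximum for slow curves), and the full 254-reaction manifest for
count audits and gap deltas. The whole suite runs in well under five
minutes on one CPU.

## Known limitations

* The E-value cutoff discrepancy (0.005 vs 0.05) and the 253-vs-254 class
  sum are surfaced, not resolved; both are inherent to the source material.
* Dipeptide/tripeptide identities beyond the eight published ones, and the
  racemase gene ids, are synthetic stand-ins.
* The degeneracy probe is conservative-heuristic; exact dual-uniqueness
  certification (e.g. optimal-face enumeration) is out of scope.
* SBML support is the Level 2 COBRA dialect only (no L3/FBC), matching the
  models this pipeline targets.
* Shadow-price values on the real expanded network are solver- and
  basis-dependent wherever the LP is degenerate; agreement on printed dual
  values is therefore checked to an absolute 0.01 and flagged.
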