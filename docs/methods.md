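# Methods

## Model overview and assumptions

`hepsim` implements two synchronous discrete-cycle agent-based analogs of
hepatic drug handling under inflammation.  Solutes (endotoxin, a single
pooled proinflammatory cytokine type, three drugs, their metabolites) are
discrete objects; enzymes are intracellular objects that map to a cell's
metabolizing capacity per cycle, not to individual P450 molecules; cells
(hepatocytes, endothelial cells, Kupffer cells) are agents executing five
probabilistic mechanism handlers once per cycle.  Every stochastic event
compares one uniform draw on [0, 1) against an event probability; all
draws in a trial come from one seeded stream (trial *i* of a protocol uses
`base_seed + i`), so trials are bit-reproducible.

Key simplifying assumptions inherited from the design: a single cytokine
type stands for all P450-down-regulating cytokines; one enzyme type per
drug (plus a non-metabolizing "nonspecific" binder on endothelial cells);
no P450 induction, no drug–drug interaction mechanisms, no leukocyte
recruitment or hepatotoxicity events.

## Per-cycle order of execution

Each cycle runs: (1) due scheduled events (bound-solute releases, queued
enzyme removals); (2) dosing and the body↔lobule exchange (liver analog);
(3) solute movement; (4) cell handlers in a freshly shuffled order.  The
paper-facing contract shuffles handler order per cell; the pooled
production path draws one handler order per cycle shared by all cells —
cells do not interact within a cycle, so per-cell marginal distributions
are unchanged and only (negligible) same-cycle cross-cell correlations
differ.  The agent-per-object culture mode shuffles per cell.

## Pooled-count representation

Production runs advance pools of identical unbound solutes per
compartment with binomial/multinomial draws, which is distributionally
identical to per-object Bernoulli stepping; the test suite verifies this
equivalence against an agent-per-object culture mode on small populations
(movement occupancy and cytokine-production distributions).  Bound
solute/enzyme pairs sit in a ring buffer indexed by cycles-until-release.
Within-cell binding attempts are still evaluated sequentially per solute
(the variable-mode probability changes after every success).

## Culture analog (ISHC)

Two stacked 25×25 grids.  Cell space holds at most one cell per point;
solutes at an occupied point are inside that cell.  Movement: each
unbound solute first attempts a vertical hop (`pExitCell` up,
`pExitMedia` down — the asymmetry encodes the large media volume) and
otherwise steps to a uniform von Neumann neighbor with toroidal wrap
(whole-system counts are the only measurements, so boundary artifacts are
irrelevant, while local stepping preserves the per-cell endotoxin
clustering that drives the threshold mechanism).  One cycle = one minute.

## Liver analog (ISL)

Body holds solute pools; each cycle a `sampleRatio × sampleRatioFactor`
binomial fraction of each type transfers into first-layer segment cores;
central-vein arrivals return to body the next cycle.  The lobule is a
layered random DAG (each segment wired to 1–3 next-layer segments; every
segment is reachable from the portal vein and reaches the central vein by
construction).  One cycle = one second.

**Geometry (declared assumption).**  The lobule dimensions are not data:
defaults are 5 layers × 9 segments (full) or 5 × 1 (compact desk scale),
each segment with a 10-point core and 2×10 endothelial and hepatocyte
lattices populated at the configured densities (0.66/0.33 endothelial/
Kupffer; 0.9 hepatocyte).  The compact lobule is ≈1/9 of the full tissue
and is paired with doses ÷ 10, keeping per-cell exposure near full scale.
Relative (LPS/control) readouts are the meaningful quantities under this
choice; absolute transit behavior depends on it.

**Movement kernel.**  Within non-core spaces a solute moves by a
categorical kernel: forward 0.2, lateral 0.6, and the remaining 0.2 split
equally (0.05) among backward, radial-in, radial-out, and stay.  The
pooled treatment is position-free inside a space: forward (backward)
moves cross to a successor (predecessor) segment with probability
1/length; all other in-space moves re-scatter over the lattice, re-drawing
cell occupancy, so a solute inside a cell stays put only on "stay".  The
core is positional: plug flow advances `flowRate` points per cycle, with
the kernel's radial-out weight (0.05) as the core→interface exit
probability.  Radial order: core ↔ interface ↔ endothelial space ↔ Disse
↔ hepatocyte space ↔ bile.

**Elimination channels.**  The bile canal is a terminal sink reachable by
radial-out moves from hepatocyte space — but only for metabolite types.
The modeled drugs are essentially fully metabolized in rats (a criterion
of their selection), so parent-drug biliary excretion would add a large
enzyme-independent clearance channel that contradicts the referent;
endotoxin and cytokine are proteins/lipopolysaccharide cleared by cellular
uptake and proteolysis, represented by `pDegrade` inside cells.  For the
same reason degradation applies only to solutes resident inside cells;
extracellular and body pools do not degrade.  Consequence: body endotoxin
persists for hours (half-life roughly 15–20 h in the analog), sustaining
Kupffer-cell stimulation across the 24 h pretreatment, as in the
referent experiments.  `sampleRatioFactor` for endotoxin is set to 1.0 —
a value is required for the LPS arm to function at all; types without a
factor (metabolites, cytokine) never transfer from body to lobule.

**Volume-of-distribution rule.**  In LPS arms, any drug defining
`Vd_change` (chlorzoxazone, 1.69) has its injected dose and its
`sampleRatioFactor` divided by that fold change.

## Down-regulation bookkeeping

Per hepatocyte and per down-regulatable enzyme type: at most one removal
is queued per cycle (first Bernoulli success among the resident
cytokines); a queued removal fires `delay` cycles after
`max(now, queue tail)`, so fire cycles strictly increase; a firing with
every enzyme bound defers and executes at the next release (bound enzymes
are never removed); a firing with no enzymes left evaporates.  Queued and
deferred removals both block replenishment, and totals never exceed the
basal (initial) draw.

## Metrics

Half-life: ln 2 / k with k the negative slope of an ordinary
least-squares fit of ln(count) vs time over all post-dose points
(non-positive counts excluded with a warning; ≥3 usable points required).
AUC: trapezoid over observed points plus a `last/k` tail when the
terminal slope is negative.  Systemic clearance ≡ dose/AUC∞; the
intrinsic-clearance analog uses the volume-of-distribution-adjusted dose.
These estimators are declared operationalizations; validation uses
LPS/control ratios, which are invariant to the count→concentration
normalization.  Similarity criteria: ±k SD bands, ±percentage bands, and
the ≥50%-of-points rule for multi-point targets.

## Problem sizes used by the shipped checks

The acceptance computation runs the chlorzoxazone arms at desk scale —
doses ÷ 10 (12,500 endotoxin / 12,500 drug objects; 7,396 for the
volume-adjusted LPS-arm dose), 4 Monte Carlo trials per arm, compact
lobule — and the culture checks use the full dose ladder with 16 trials
and the 2,000-cytokine time course with 4 trials plus a 48,000-cycle
extension for the recovery property.

## Known limitations

- The lobule geometry, per-space transition structure, and the
  position-free pooled treatment within spaces are this package's own
  reconstructions; the absolute depth of enzyme suppression is sensitive
  to them.  At the shipped desk-scale geometry the LPS arm sits in a
  stronger-suppression operating point than the referent wet-lab data
  (enzyme totals fall well below the wet-lab ~58%-of-control level while
  the clearance ratio lands near the wet-lab ~29%), so absolute
  suppression percentages should be read as regime-dependent; the
  qualitative pathway (sustained suppression, clearance drop exceeding
  what the volume-of-distribution change alone produces) is robust.
- The cytokine-production equation and the variable-binding formula are
  property-faithful reconstructions (zero above/below the stated
  thresholds, correct limits and monotonicity); an alternative
  cytokine-probability form is selectable for sensitivity analysis.
- Culture validating protocols exercise no binding/metabolism (no drug is
  dosed in vitro); the pooled culture path therefore rejects bindable
  doses, which the agent mode accepts.
- Wet-lab disappearance-curve ordinates are not shipped: only the printed
  constants (57.8%, 29.2%, 1.69-fold) are built in; other reference
  values must be user-supplied to the similarity checker.
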