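# Methods

## Model and procedure

The data are a set of linear SC stretches, each a segment `[0, L]` in
micrometres carrying closed intervals: Zip3 marker foci, Zip1-GFP
incorporation foci, and optionally a centromere point. All geometry is
continuous 1D; boundary coincidences (measure zero under continuous
placement) are resolved inclusively.

A GFP focus of length *g* with centre *c* occupies `[c − g/2, c + g/2]`.
For each Zip3 focus `[z₁, z₂]` the centre positions scoring a hit are:

* adjacency: `[z₁ − g/2, z₂ + g/2]` — equivalent to the focus touching,
  partially overlapping, or being encompassed by the Zip3 focus;
* encompassment: `[z₁ + g/2, z₂ − g/2]`, empty when `g > z₂ − z₁`.

Per-stretch domains are the union of these intervals (overlaps merged and
counted once), intersected with the legal centre range.

**Null model.** The test conditions on everything except the GFP centre
positions: stretch lengths, Zip3 coordinates, the per-stretch GFP focus
counts, and the bag of GFP focus lengths. An outer loop draws one length
from the bag per iteration block (that size is shared by every focus in
the block); the inner loop redistributes each stretch's foci uniformly
over its legal centre range and counts centres falling in the domain
union. Defaults are 1000 size draws × 1000 placements = 10⁶ iterations.
The p-value is the fraction of iterations with count ≥ observed ("plain"
rule; a `plus_one` (r+1)/(N+1) rule is available because the plain rule
can return 0).

**Exact oracle.** For fixed size the count is Poisson-binomial — the
convolution over stretches of Binomial(nᵢ, p_hitᵢ) with
`p_hitᵢ = domain measure / legal-centre measure` — computed exactly (no
normal approximation; totals of a few hundred foci are cheap). The outer
loop is marginalized by averaging tails over the empirical size atoms
(multiplicity-weighted) or over a 256-node midpoint quadrature for
parametric size laws. The oracle also supplies the *correct* standard
error of the shared-size MC p-value: iterations within a block share the
size draw, so `Var(p̂) = Var_g(tail(g))/n_outer + E_g[tail(1−tail)]/N`,
which can far exceed the naive binomial term.

## Size handling and calibration

The shared-size scheme is the faithful reading of the study design and is
the default. It has a consequence worth stating precisely: the hit
probability increases with *g* (the adjacency domain grows by *g*, and
the contained legal range shrinks by *g*), so sharing one *g* across all
~117 foci adds a between-block variance term `Var_g(Σᵢ pᵢ(g))` to the
null count. Data whose foci carry independent sizes (as the generator
produces, and as real nuclei presumably do) have a narrower count
distribution; p-values computed against the shared-size null therefore
concentrate toward the centre and the test is **conservative** — it
under-rejects at any nominal level, and observed significance survives.
Exact uniform calibration holds for the `per_focus` size mode (each focus
independently resamples its size per block), which matches the
generator's process; an `observed` mode (each focus keeps its own size;
placement-only conditional null) is also provided. The calibration
acceptance test uses `per_focus`; a companion test asserts the default's
conservatism.

## Boundary policy and edge cases

* `contained` (default): legal centres are `[g/2, L − g/2]`, so placed
  foci lie wholly on the stretch — the conservative reading, since the
  edge handling of the original analysis is not stated. `unconstrained`
  (`[0, L]`) is available; the policy is echoed in every result.
* A focus longer than a stretch leaves an empty legal range: the domain
  constructors warn; the MC engine raises an error naming the stretch
  when that stretch has a placement constraint.
* `touch_tolerance` defaults to 0 µm (exact boundary contact counts as
  touching); "touching" on rendered images has no stated tolerance, so it
  is configurable.
* Null foci may overlap each other (no exclusion rule is stated).
* Domain measures obey closed forms before clipping — adjacency
  `= zip3 length + g`, encompassment `= max(0, zip3 length − g)` — and
  encompassment domains are always subsets of adjacency domains; both are
  asserted in the test suite to 10⁻¹².

## Synthetic generator: the stated world

Defaults emulate the scored dataset: 69 stretches, 117 GFP foci, focus
lengths with mean 0.31 µm and hard maximum 0.58 µm. Values the source
does not state were fixed once at cytologically plausible levels:

| parameter | default | rationale |
|---|---|---|
| stretch length | Normal(3.0, 1.0) µm, min 1.0 | individual well-spread SC stretches are a few µm |
| Zip3 count / stretch | 1 + Poisson(1.0) | every scored stretch carries markers; mean 2 |
| Zip3 length | Exp(0.45 µm) truncated to [0.1, 0.8] | same optical scale as GFP foci, skewed |
| focus length law | lognormal, CV 0.4, right-truncated at 0.58 µm, µ solved so the truncated mean is 0.31 µm | positive, skewed, hard max; only mean and max are stated |
| GFP allocation | multinomial ∝ stretch length | longer SCs carry more events |

Zip3 foci are placed uniformly without mutual overlap by the exact
spacings construction (subtract the total focus length, drop k uniform
points, re-inflate) rather than rejection sampling — the same
distribution with deterministic cost and no pathological loops on crowded
stretches; foci that cannot fit are dropped from the count rather than
silently squeezed.

Enrichment: with probability θ a focus centre is drawn uniformly from the
stretch's Zip3 adjacency-domain union for its own length (falling back to
uniform if the union is empty). The rng call pattern per focus is fixed
(one selection uniform + one position uniform), so datasets generated at
different θ from the same seed are coupled by common random numbers and
hit counts are monotone in θ realization by realization.

What the generator does **not** emulate: optical point-spread, chromatin
texture, spreading artifacts, nucleus-level grouping of stretches, or
temporal dynamics of incorporation. A green calibration or power test
therefore establishes properties of the statistical machinery on the
stated geometry, not fidelity to any particular microscope.

## Descriptive tallies

GFP elements are classified ENCOMPASSED / PARTIAL_OVERLAP / TOUCHING /
NONE (strongest category wins across Zip3 foci) and split into size
classes: focus < 0.35 µm, short stretch [0.35, 0.5) µm, long stretch
≥ 0.5 µm (half-open bounds make the classes a partition). Centromere
association uses a `cen_window` of 0.35 µm by default (one short-stretch
unit; the original "at or adjacent to a centromere" is visual and
unquantified — the window is echoed in the report). When a centromere is
near both a focus-class and a stretch-class element, stretch takes
precedence by default (flag `stretch_over_focus`). The data model has no
nucleus grouping, so the per-nucleus fraction of early events at
centromeres is reported per stretch with its mean.

## ROI quantitation

Z-stacks are 7 sections of 0.2 µm; the summed-intensity projection uses
the middle 5 by default ("best-resolved" has no algorithmic definition in
the source; a variance-of-Laplacian best-focus window is available behind
a flag and the choice is echoed). Measurements are totals of three
edge-adjacent 4×4-pixel boxes (pixel 0.0643 µm, box side 0.2572 µm, box
volume 0.2572² × 5 × 0.2 ≈ 0.066 µm³) laid along a direction quantized to
the 8 pixel-grid orientations; sub-pixel placement is not attempted.
Integer stacks are accumulated in int64 so projection totals equal the
exact sum of the selected sections. Group comparison is the standard
two-tailed Mann–Whitney U test (SciPy; exact for small tie-free samples).
Exposure-time normalization across experiments is out of scope.

## Numerical choices

* Interval unions: sort by start, cumulative-max merge; hit testing by
  `searchsorted` parity on the flat boundary array. Zero-length intervals
  are dropped from unions (measure zero under continuous placement).
* Domain unions are memoized per (stretch, size, mode); empirical size
  atoms repeat heavily across blocks, so a full 10⁶-iteration study-scale
  run takes seconds.
* Poisson-binomial pmfs are convolved in float64 and tails clipped to
  [0, 1] against accumulated round-off (≤ a few ×10⁻¹⁶).
* The truncated-lognormal µ is solved by Brent's method on the analytic
  partial-expectation formula; sampling is by inverse CDF restricted to
  `[0, F(max)]`, so draws never exceed the truncation point.
* All randomness flows through one `numpy.random.Generator` per
  operation, seeded explicitly; reports contain no timestamps, making
  byte-identical reruns a tested contract.

## Known limitations

* The original coordinate sets are not deposited, so the study's headline
  p-values cannot be recomputed; all quantitative guarantees here are
  property-based on synthetic data.
* The shared-size default is conservative on independently-sized data
  (see above) — a property of the procedure it reproduces, not a bug.
* The empirical p-value resolves only to 1/N; heavily enriched datasets
  return 0 (or 1/(N+1) under `plus_one`).
* Qualitative image-derived classifications with no stated quantitative
  definition (Zip1 intensity "peaks"/"valleys") are deliberately out of
  scope, as are segmentation, deconvolution and 2D/3D colocalization.
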