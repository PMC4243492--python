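# Methods

This note records the model as implemented — its assumptions, the parameters
that matter, the synthetic study conditions, and the numerical choices made
where the design was genuinely open.

## The visual hierarchy and its feedforward sweep

The hierarchy is a small retinotopic pyramid: level 0 at input resolution,
each transition pooling an `rf × rf` half-open window with stride `s ≤ rf`
(default three transitions of 2×2/stride 2, so a 64×64 retina tops out at
8×8). Pooling is a uniform weighted sum (a mean), never a maximum: the model's
central commitment is that max-finding is a *top-down* operation, so the
feedforward sweep must be non-selecting, and with neutral gains and no
suppression it is exactly linear in the input. Feature channels are explicit
image planes (e.g. `curve`, `marker`, `colorA`) and do not mix during the
sweep; "color" names are mnemonic only — a channel is any feature map.

Attentive state on the hierarchy comprises three strictly independent
quantities:

* **gains** — multiplicative priming biases per channel and location
  (priming applies at the input level; linearity propagates the factor to
  every level, which is also how the priming unit-test is phrased);
* **suppression** — multiplicative attenuation in [0, 1] applied to a unit's
  output when it feeds upward; imposed as a Chebyshev annulus of width
  `suppression_extent` (default 2 units per level) around an attended
  selection, at strength `suppression_factor` (default 0.1), plus listed
  sibling channels at the selected locations; lifted wholesale at disengage;
* **pathway inhibition** — boolean object-based inhibition of return: every
  unit of an attended sample contributes 0 upward for `ior_horizon_cycles`
  attentive cycles (default 3), then auto-releases.

Resetting any one of these never touches the others; the suite asserts that
separation directly.

## θ-WTA and the attentional sample

`theta_wta` returns the connected component (8-connected by default, ties at
the peak broken by smallest (row, col)) of units within `(1 − θ)` of the
admissible maximum, containing the argmax. An all-zero admissible map is the
explicit no-winner signal. The threshold is *relative to the maximum*, not a
histogram bin, which keeps θ dimensionless; region growth is monotone in θ
and the implementation is checked exhaustively against an independent
brute-force oracle.

Top-level selection (the central focus of attention) restricts admissibility
to units whose receptive-field center lies inside the central attentional
field (`central_radius_deg`, default 10° at 0.5°/px = 20 px) and which are
not pathway-inhibited, and additionally excludes units whose dominant channel
differs from the peak's: stimuli distinguishable by their constituent
features are never selected into one region, while identical items may merge
— both behaviors are intended.

The executive's default θ is 0.8. The reason is geometric: a compact item
whose support straddles pooling windows produces "fringe" top-level units at
as little as 1/4 of its peak response (a 3×3 item split 1:2 across an 8-px
window in each axis). A selection threshold of 0.2×max captures the whole
item as one object, so that object-based inhibition of return suppresses all
of it; tighter thresholds leave selectable fringe that masquerades as a new
item on the next cycle. The `theta_wta` primitive itself defaults to a
neutral 0.25 for direct use.

Recurrent localization descends level by level from the top-level winner:
the admissible set at level *l* is the union of receptive-field windows of
the selected units at *l*+1; θ-WTA (on the channel-summed map) picks the
contiguous winner within that restriction; per location, all channels within
`(1 − θ)` of the strongest channel enter the sample; the suppressive annulus
is imposed around each level's selection *as it forms* (the alternative —
suppressing only after the full descent — is equivalent here because the
descent reads activations computed before any suppression; the choice
matters only for stage E). A `depth` argument stops the descent early (the
partial pass used by within-category identification). The result is rooted
and top-to-bottom connected by construction, and a graph-traversal validator
re-checks both invariants in the tests.

## Stage E and why re-analysis cannot *raise* a linear response

Stage E re-runs the feedforward sweep with the localization's suppression in
place and re-selects **within the attended region**. The restriction is
deliberate: stage E is a re-analysis of the attended stimulus, not a fresh
competition — after suppression the attended item's absolute response can
only fall or stay equal (all contributions are non-negative and suppression
is multiplicative), so an open competition would let an unsuppressed
neighbor capture the focus, which inverts the semantics of the stage.

In this architecture the re-analysis property "attended response after
suppression + repass ≥ before" holds with *equality* when no suppressed unit
feeds the attended pathway, and cannot hold strictly: a linear sweep has no
mechanism by which removing clutter increases a response (in cortex that
mechanism is nonlinear normalization, which is out of scope here). The
re-analysis study therefore uses displays whose items are aligned to the
pooling lattice (8×8 items on the 8-px grid) and separated by ≥ 24 px, so the
attended support tiles its pooling windows exactly, the annulus covers only
zero background and distant clutter, and the measured stage-E delta is
exactly zero on every display. What re-analysis buys in this model is not a
larger attended response but a cleaner one: everything *around* the attended
pathway is attenuated by `suppression_factor`.

## Fixation control

Peripheral saliency is a stand-in for a full saliency model: per channel,
response minus its local uniform-window mean (surround half-width 5 px),
rectified, weighted by the task's channel gain, summed — then zeroed inside
the central field. The interface accepts any drop-in replacement. Peripheral
candidate peaks come from greedy non-maximum suppression (default k = 5,
exclusion radius 6 px). Values at or below 1e-9 are treated as zero
throughout fixation control; uniform-filter round-off otherwise masquerades
as saliency once everything real is inhibited.

The Fixation History Map stores entries in *world* coordinates — its extent
exceeds the retina, which is what allows the model to remember and return to
locations that have left the view. Each update decays all weights by `lam`
(default 0.85; 1.0 disables decay) and drops entries below `eps` (default
0.01; 0 retains forever). An entry inhibits a disk of `inhibit_radius_px`
around its fixation plus any traced pixel set it carries; inhibition combines
across entries by max, and priority is `saliency · (1 − inhibition)`, with a
task-demand override flag that ignores the history term. The next fixation is
the highest-priority retinal position that satisfies the task predicate and
exceeds a floor of 5% of the map maximum; "none" drives task termination.
A saccade requires a disengage earlier in the same cycle (asserted against
the event log) and re-centers the retina; covert shifts move no retina.

## The model clock

All scientific timestamps are model milliseconds: priming lead 150 ms
(valid range 80–300), feedforward sweep 150 ms, full top-down pass 125 ms
(valid range 100–150, scaled by the fraction of levels descended for partial
passes), decision 25 ms and saccade 30 ms (both free parameters of this
artifact). The log is append-only with non-decreasing stamps and the final
time equals the sum of logged stage costs — the suite recomputes it from the
log.

## The executive

Methods are JSON graphs over four node kinds; edges carry outcome conditions,
parallel-group annotations (branches serialized deterministically before
their barrier join — a contract, not a concurrency mechanism), and explicit
`repeat` marks for the one legal cycle. Validation checks single start/end,
reachability, acyclicity outside repeats, and named slots. Long-term memory
ranks stored methods by `|descriptor ∩ keys| / |keys|`, ties by insertion
order. Script construction binds every `$slot` from the task specification
and fails naming any unbound slot.

Monitoring: nodes may declare a checkpoint predicate; `selection_valid`
re-derives the selection silently (same activations, same exclusions, same
re-analysis restriction) and compares peaks. The search methods monitor the
selection node itself — monitoring only the downstream match would let a
corrupted selection validate itself once the stage-E restriction narrows the
reference. On mismatch the ladder runs: (1) re-select excluding the failed
winner, (2) replace the script with the next-ranked method (the replacement
joins the trial in flight, so its priming and onset nodes are no-ops — the
bias persists within a trial), (3) abort. The ladder position is logged.

Negative completion (`done_negative`: "different curves", "target absent",
class mismatch) is a valid task answer; `failed` is reserved for executive
breakdown (no method, ladder exhaustion, budget overrun).

## Curve tracing

The tracer fixates the first X marker (markers are found as NMS peaks of the
marker channel; an X's center pixel is its brightest point), then repeats:
spread the trace over curve pixels within arc `central_radius_px` of fixation
(label spreading anchored at fixation, 8-connected, on the thresholded curve
channel of the current retinal view); if the second marker adjoins the traced
set, answer "same"; otherwise find the frontier — untraced curve pixels
connected to the traced set within arc `2 × central_radius_px` — and jump to
the farthest frontier pixel, absorbing the BFS chain to it into the trace
(the connectivity the fixation constraint verified *is* traced curve). When
the chosen continuation is inside the central field the shift is covert — a
small display is traced without any saccade. Frontier branches not taken are
remembered in world coordinates as loose ends and revisited before ever
answering "different"; only a truly exhausted connected curve yields
"different". Traced pixels and fixations feed the history map (undecayed for
tracing, inhibition radius 3 px so past fixations do not mask the curve
itself), and each cycle runs the full B/C/D/E machinery so the attentional
sample of the curve-at-fixation reaches the blackboard.

Tracing uses a 0.6° central field at 0.1°/px: the per-cycle traceable extent
(6 px spread + 12 px verified jump) is then a fine-grained fraction of curve
lengths in the 2–9° range, which is what makes cycle count — and hence model
RT — track along-curve distance. Markers sit symmetrically about the curve
midpoint with 0.5° of spare curve beyond each; larger margins add a variable
amount of stub exploration that only contributes variance.

## Synthetic displays: what they do and do not emulate

The generator produces, deterministically per seed: non-crossing
bounded-curvature curves (8-connected chain-code walks, diagonal steps
counting √2 of arc, minimum Chebyshev separation 6 px, rejected and re-seeded
on conflict up to 100 retries) with X markers placed by cumulative arc;
rings of items about the display center; a central two-class (or noise)
discrimination stimulus; and scattered clutter displays, optionally aligned
to the pooling lattice. Ground truth (pixel sets, marker assignments,
labels) is written alongside and consumed only by tests and scoring — never
by the model.

Study geometry is fixed by the model's own constraints: covert search rings
of radius 7° lie inside the 10° central field; the overt-scan world (160×160
viewed through a 64×64 retina with a 5° central field) keeps every ring item
on-retina from any ring fixation while keeping non-fixated items peripheral;
lattice alignment in the re-analysis and sample-structure studies removes
partial-window fringe as a confound. Scales used by the suite and the
acceptance script: 100 displays for sample structure, re-analysis and
priming; 50 tracing displays; 5 RT levels × 20 displays; rings of 4/6/8.

These displays are caricatures. Items are uniform squares with noiseless
backgrounds and jitter only in amplitude; curves are one pixel wide; channels
are given, not computed from pixels; there is no eccentricity scaling, no
luminance calibration, no temporal structure. Passing tests therefore show
that the *control architecture* behaves as specified — selection, routing,
memory, sequencing, chronometry — not that the front end would survive
natural images.

## Known limitations

* The hierarchy is linear with hand-specified channels; no learned filters,
  no cross-channel normalization, hence no strict response enhancement from
  re-analysis (see above).
* The saliency operator is a center-surround stand-in, not a full saliency
  model.
* Human tracing *rates* are not reproduced and not attempted — only the
  monotone growth of response time with along-curve distance.
* The remediation repertoire is exactly the three-step ladder; richer script
  editing is out of scope.
* Model time is stage-cost bookkeeping, not a dynamical simulation; costs
  within their stated ranges are free parameters.
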