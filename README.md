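# stcp — Selective Tuning with a Cognitive Programs executive

`stcp` is a runnable model of the *executive control of visual attention*: it
implements the Selective Tuning (ST) attentive cycle over a small retinotopic
feature hierarchy, and drives it with Cognitive Programs — method graphs that
an executive fetches from long-term memory, tunes into scripts, executes step
by step, and monitors. It is aimed at computational-neuroscience researchers
and students who want a concrete, testable executive for attention: every
stage, selection, memory access and decision is logged on a model clock, and
every display it runs on is generated with ground truth.

## The model in brief

**Visual hierarchy (VH).** Level 0 is the retinal image (named feature
channels); each higher level pools a window of the level below with a uniform
weighted sum. There is deliberately no feedforward max: selection is a
top-down operation. Attentive state lives on the hierarchy as three
independent quantities — multiplicative priming gains `g` (installed 80–300 ms
before stimulus onset), suppression factors `s ∈ [0, 1]` on unit outputs, and
boolean pathway-inhibition flags implementing object-based inhibition of
return (an inhibited unit contributes 0 upward for a fixed number of attentive
cycles).

**θ-WTA.** Selection on a response map `r` returns the spatially contiguous
near-maximal region: with peak `m = max r`, the winning region is the
connected component, containing the argmax, of units with
`r ≥ (1 − θ)·m`, `θ ∈ [0, 1)`. Units whose dominant feature channel differs
from the peak's are excluded — feature-distinguishable stimuli are not
selected together.

**The attentive cycle.** Stage B primes the hierarchy; stage C is a single
feedforward sweep followed by θ-WTA selection of the central focus of
attention (cFOA) at the top of the hierarchy; stage D is the recurrent
localization pass that descends the hierarchy, selecting at each level only
among units feeding the selection above and suppressing each level's spatial
surround as it goes — its union is the **attentional sample**, a rooted,
top-to-bottom connected subset of the hierarchy; stage E re-runs the sweep
with suppression in place and re-examines the attended region. Tasks map to
stages: discrimination-class tasks need B–C, within-category identification
adds a partial D, localization a full D plus E, search and tracing repeat the
full cycle.

**Fixation control.** Saliency is computed only peripherally (the Peripheral
Priority Map is zero inside the central attentional field by construction),
past fixations and traced structure decay in a world-coordinate Fixation
History Map, and the History-Biased Priority Map
`priority = saliency · (1 − inhibition)` drives the next overt fixation.
*Disengaging attention* is operationalized exactly as: lift all surround
suppression, and inhibit the pathways of the previously attended sample.

**Executive.** Methods (graphs of transfer / process / select /
set-parameter nodes) live in an associative long-term memory; the task
executive fetches by key overlap, binds open slots from the task
specification, executes with deterministic serialization of parallel groups,
and monitors declared checkpoints with a three-step remediation ladder
(re-select excluding the failed winner → swap in the next-ranked method →
abort). Five programs ship: discrimination, covert search, overt search,
localize/reinterpret, and curve tracing.

## Worked example

Generate a large two-curve display with two X markers on the same curve, then
ask the model whether the markers share a curve:

```bash
$ stcp gen --kind curve --out demo/curve --seed 4 --width 256 --height 256 \
      --deg-per-pixel 0.1 --n-curves 2 --curve-length 6.6 --same-curve
wrote curve display to demo/curve

$ stcp trace --world demo/curve --out demo/trace --seed 4
{"outcome": "same", "rt_ms": 1010.0, "seed": 4, "steps": 3, "traced_pixels": 48}
```

The model fixated the first X, traced the curve in three attentive cycles
(saccading along it, never touching the second curve), reached the second X,
and answered **same** with a model response time of 1010 ms — the summed cost
of the logged stages on the model clock, not wall time. `demo/trace/` holds
the event log (`events.jsonl`), the fixation trace (`fixations.csv`) and an
overlay PNG of the traced path. Longer along-curve separations take more
cycles, so model RT grows with arc distance, the signature of internal curve
tracing.

A discrimination run, and what its log shows:

```bash
$ stcp gen --kind discrimination --out demo/disp --class-id A
$ echo '{"task_type": "discriminate", "target": {"channel": "featA"}}' > demo/task.json
$ stcp run --task demo/task.json --display demo/disp --out demo/run
done_positive
$ stcp inspect --run-dir demo/run
stages: B,C
outcome: {"outcome": "done_positive", "reason": null, "seed": 0}
```

One priming stage and one feedforward sweep suffice: the stimulus is class A,
the selected focus matches the task goal, and the task completes positively —
no recurrent pass is deployed for plain discrimination.

The same machinery is available as a library:

```python
from stcp import TaskSpecification, vte_run
from stcp.stimuli import DisplaySpec, make_ring_display

spec = DisplaySpec(channels=("colorA", "colorB"), seed=3)
image, truth = make_ring_display(spec, n_items=4, target_index=2,
                                 ring_radius=7.0, jitter=0.2)
task = TaskSpecification(task_type="search_covert",
                         target={"channel": "colorA"},
                         overrides={"max_cycles": 8})
result = vte_run(task, image=image, seed=3)
print(result.outcome, result.script.cycles_done)   # done_positive 1
```

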