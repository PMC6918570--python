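# Methods

`hictad` calls hierarchically nested topologically associating domains
(TADs) from a single-chromosome Hi-C contact matrix. The method has
four stages: preprocessing, boundary detection, assembly of an optimal
nested domain forest, and penalty calibration against a permutation
null. This note defines each stage precisely, gives every parameter
with its unit, default and rationale, and records the numerical and
design choices that affect results.

## 1. Input model and preprocessing

The input is a symmetric `n x n` matrix of contact counts (raw or
balanced) at a fixed bin resolution, with an optional per-bin mask for
unmappable rows (all-zero rows are auto-masked on load). Two
transforms run before any statistic is computed:

1. **log2(1 + x)** (`--log2`, default on). The assembly margin
   `lambda` (below) is a difference of block means, and the shipped
   default `lambda = 0.1` is only meaningful on an O(1) scale: in log2
   units 0.1 is a ~7 % fold change in contact frequency. On raw count
   scales the same threshold would be dwarfed by the sampling noise of
   block means at deep-sequencing depths and by the decay amplitude at
   shallow ones. Data that is already log-like or signed should be
   loaded with `--no-log2`.
2. **Distance centering.** From each entry the mean of its diagonal
   (its genomic-distance stratum, masked bins excluded) is subtracted,
   so every off-diagonal offset has exactly zero mean. All later
   statistics — insulation dips, block means, flank means — are
   therefore deviations from the distance expectation, and the strong
   power-law decay cannot masquerade as domain structure. Centering a
   matrix twice is an error, which the container's `norm_state` field
   enforces.

## 2. Boundary detection

For a window size `W`, the **diamond statistic** at junction `i`
(junctions live *between* bins: `i` separates bin `i-1` from bin `i`)
is the mean of the `W x W` block with rows `[i-W, i)` and columns
`[i, i+W)` — the contacts that straddle the junction. Windows are
truncated at the matrix edges; a junction whose window is empty is
undefined (NaN). Masked bins are excluded from the mean. A deep local
minimum of this track is an insulation valley: a point that contacts
both its sides unusually weakly.

A junction is a **candidate boundary at window `W`** when

* its statistic equals the minimum of the track over the neighborhood
  `i - Lsize .. i + Lsize` (plateau ties are kept; equality uses a
  1e-9 relative tolerance so exact plateaus from noiseless data are
  not lost to float jitter in the summed-area tables), and
* its depth below the larger of the two neighborhood edges is at least
  `z * S`, where `S` is the standard deviation of the (defined part
  of the) whole track at this `W`.

The final candidate set is the union over `W = 1 .. K` plus the two
chromosome ends, with per-candidate provenance recording which window
sizes proposed it. Small sharp domains surface at small `W`, broad
domains at large `W`; the union feeds one joint assembly rather than
per-`W` calls.

Because `S` is a *global* track property, detection is sensitive to
the composition of the whole chromosome arm: long domain-free
stretches contribute deep decay-driven dips at many junctions, inflate
`S`, and can push genuinely periodic but shallower sub-domain dips
under the `z * S` bar. The effect is scale-free — both the dip depth
of a nested sub-boundary and `S` grow with the log of the enrichment —
so it cannot be bought back with deeper sequencing. This is a real
sensitivity cliff of the method on sparse, partially covered inputs,
and it is why the simulator's default geometry tiles the chromosome
(section 6).

## 3. Assembly of the nested domain forest

Let `D(a, b)` be the candidate-junction pair delimiting bins
`[a, b)`. Its **margin** is

```
delta(a, b) = deconv_mean(a, b) - max(up_flank, down_flank) - lambda
```

* `deconv_mean` is the mean of the block `[a,b) x [a,b)` *excluding*
  entries covered by the pair's direct children in the forest — the
  de-convolution step, so a parent is scored on its own territory
  only, not on the signal its children explain.
* The flanks are the two `size x size` rectangles upstream
  (`rows [a-size, a) x cols [a, b)`) and downstream
  (`rows [a, b) x cols [b, b+size)`), truncated at the chromosome
  ends; a fully truncated flank is dropped, and if both are empty the
  margin is `-inf` (a domain spanning the whole matrix has nothing to
  beat).
* `lambda` is the penalty: the margin by which the domain must beat
  its better flank.

The score of an interval between candidates is defined recursively:
`g(a, b)` maximizes over partition points the sum of the two parts'
scores, `h(a, b) = g(a, b) + delta(a, b | children = maximal called
domains under g)`, and the interval's score is `max(g, h)`; the pair
is **called if and only if its margin is positive** (`h > g`). The
production implementation is an equivalent left-to-right prefix DP
with memoized interval solutions; `forest.work` counts its inner-loop
iterations.

Two documented consequences of this objective:

* **Greedy-child property.** The recursion fixes a parent's children
  to the argmax of `g` before scoring the parent. It can therefore
  never *decline* a positive-margin child, even when skipping that
  child would raise the parent's de-convoluted margin by more than the
  child contributes. A global search over all laminar families of
  positive-margin domains (maximizing the sum of margins) can strictly
  exceed the recursion's optimum on adversarial random inputs; on
  clean block-structured inputs the two coincide. The recursion is
  the definition of the method's optimum, and the test suite pins the
  implementation to an unmemoized transliteration of it (plus full
  laminar-family enumeration on clean planted inputs where they
  agree).
* **Envelope domains.** When a parent has three or more strong
  siblings, the union of two adjacent siblings is itself a block whose
  de-convoluted mean genuinely beats its flanks, so the objective
  rewards calling the envelope as an intermediate level. This is not
  a bug; it does mean "the called nesting equals the planted nesting"
  is only guaranteed for two-children-per-parent hierarchies, which is
  how the simulator builds its default truth.

Constraints: `minsz <= b - a <= maxsz` (bins), and a called pair's two
ends may be at most `max_neighbor_span` candidates apart (partition
points in `g` are unrestricted). Exact score ties between calling and
not calling resolve to *not calling* (the margin must be strictly
positive); ties are measure-zero on continuous data.

**Levels.** A domain's level is 1 + its number of strict ancestors,
capped at `max_level_cap`; a root with no children is flagged a
singleton. A *boundary's* level is the larger of (number of domains
ending at it, number of domains starting at it), capped; a boundary
reaching the cap on one side is flagged a hub.

## 4. Penalty calibration

`select_penalty` sweeps an ascending `lambda` grid. For each value it
assembles domains on the real matrix and on `null_reps` within-distance
permutations of it (each permutation shuffles every diagonal
independently, preserving the per-distance multiset of values and
symmetry; masked rows are left in place; candidates are re-detected on
each permuted matrix, never shared). Real calls are binned into an
`n_quantiles x n_quantiles` grid of size- and score-quantiles (edges
from the real calls; out-of-range null calls clamp into edge cells).
Each real call in stratum `i` gets the local false-discovery
probability `p = min(V_i / R_i, 1)`; the aggregate FDR is the mean
`p`, and the smallest grid `lambda` with FDR at or below the target
(default 0.05) is selected (largest, with a warning, when none
qualifies).

Granularity matters: 25 x 25 strata suit genome-scale call counts
(thousands of domains). On a 200-bin toy map with a few dozen calls,
625 strata are never jointly occupied, real and null calls almost
never collide, and the estimate collapses toward zero; the examples
and acceptance runs use 5 x 5 strata there. Note the permutation of a
*structured* map retains the per-distance mixture of in-domain and
background levels, so its per-distance variance exceeds a true
structure-free null's: the resulting FDR is deliberately conservative,
and the stratification on size and score exists to keep those weak,
small null calls from penalizing strong large real calls. The clamp
`min(V/R, 1)` also biases the estimate below 1 on a pure-null input at
small call counts.

## 5. Parameters

| Parameter | Unit | Default | Why |
|---|---|---|---|
| `penalty` (lambda) | log2 contact units | 0.1 | ~7 % fold-change margin a domain must clear; calibratable by section 4 |
| `lsize` | junctions (bins) | 5 | local-minimum neighborhood half-width; smaller finds denser boundaries, noisier |
| `z` | track SDs | 1.96 | ~95 % normal band: a dip must be deep relative to the whole track |
| `minsz` | bins | 3 | smallest callable domain; below this the diamond/flank geometry degenerates |
| `maxsz` | bins | 200 | 2 Mb at 10 kb (`--max-span 2000000` / resolution); TADs are sub-megabase-scale objects |
| `max_neighbor_span` | candidate ranks | 5 | a domain's ends must be near-adjacent candidates; bounds DP work and span hallucination |
| `K` | bins | `min(maxsz, n)` | largest diamond window; matched to the largest callable domain |
| `max_level_cap` | levels | 5 | reporting cap for levels and the hub flag |
| `n_quantiles` | strata per axis | 25 | FDR stratification at genome scale; reduce for small maps (see §4) |
| `target` | FDR | 0.05 | conventional discovery-rate target |

## 6. The simulator: model, realism, limitations

**Model.** The expected matrix is a power-law decay
`mu(k) = c (1 + k)^(-alpha)` times, for every planted interval
containing both bins, that interval's enrichment multiplier — nested
intervals stack multiplicatively, matching the de-convolution
assumption. Noise is Poisson or negative-binomial (gamma-Poisson,
`dispersion` = gamma shape), one draw per unordered pair mirrored for
exact symmetry; `noise="none"` returns the expectation.

**Default study conditions** (chosen once, as a realistic regime, not
fitted to any test): 200 bins at 10 kb; `c = 2000`, `alpha = 1`
(a deeply sequenced in-situ map has on the order of a thousand
contacts between adjacent 10-kb bins; `alpha = 1` is the canonical
decay exponent); `sample_hierarchy` tiles the chromosome with
top-level domains of 40–70 bins (400–700 kb) that share boundaries
except for rare (p = 0.2) one-bin gaps, each split at a uniform point
into exactly two children of at least 15 bins; enrichment multiplies
by 2 per level. The tiling mirrors the observations that TADs cover
most of the genome and that most TADs are internally structured; full
coverage is also load-bearing for detection, per the `z * S`
sensitivity discussed in section 2 — an uncovered tail of a few dozen
bins measurably inflates `S` and suppresses sub-boundary detection at
any enrichment. Exactly two children per parent makes "called nesting
equals planted nesting" well-posed (no envelope domains, section 3).

**Limitations.** No A/B compartment plaid, no corner-peak loops, no
mappability texture or copy-number steps, a single global multiplier
per level rather than a per-domain distribution, and hierarchies of
fixed depth. The generator is a test harness for the caller's own
modeling assumptions, not a Hi-C emulator: results on it bound what
the caller can do when its assumptions hold exactly.

## 7. Numerical choices

* Diamond and block means use summed-area tables (O(1) per query after
  O(n^2) setup) with NaN-aware counting for masks; oracles in the test
  suite recompute them with literal double loops.
* Local-minimum equality uses a 1e-9 relative tolerance (section 2);
  DP score comparisons use a 1e-12 absolute guard so float jitter
  cannot flip a partition choice; domain calls require strictly
  positive margins.
* All stochastic procedures (permutations, simulations, calibration)
  take explicit integer seeds; internal child seeds derive from
  `numpy.random.SeedSequence` reduced mod 2^31 so they stay portable.
* Assembly, detection and evaluation are deterministic functions of
  their inputs; repeated runs are bit-identical.
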