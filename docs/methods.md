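# Methods

## Model

The null model treats every candidate slot for a target entity as an
independent Bernoulli trial with success probability p. In k-mer mode
a slot is one of the (L_s − k + 1) k-mer windows of the N-free portion
of a sequence; because copies are detected non-overlapping, the k−1
positions consumed by each of the N copies are removed from the
denominator:

    p = N / ((L_s − k + 1) − N·(k − 1))

L_s is the sum of contig lengths (Ns excluded), and the window count is
accumulated per contig as Σ max(0, len − k + 1): ambiguous positions
are never candidate slots, and counting them would bias p downward. In
element mode a slot is an abstract stretch of the mean element length,
p = N·L_mean/L_s, with L_s the full declared sequence length (element
annotations refer to complete assemblies, so no N-exclusion is applied
there).

Under this null the distance between consecutive copies is geometric,
P(d) = p(1−p)^(d−1), d ≥ 1 — the unique memoryless inter-arrival law
consistent with a Bernoulli process. The distance convention is
"start of downstream minus end of upstream" in 1-based inclusive
arithmetic (abutting copies ⇒ d = 1); internally all coordinates are
0-based half-open and the convention reduces to start − end + 1.
Overlapping input elements (possible in real annotations) are clamped
to the minimum distance 1, so they always co-cluster.

A cluster is a maximal run of copies with all consecutive distances
≤ d_max, never crossing a contig boundary, with ties at d_max inside.
Its significance is the negative-binomial CDF P(X ≤ n_f) with
r = n − 1 successes: the first copy anchors the cluster and carries no
evidence, so only the n − 1 subsequent arrivals are scored. Runs of a
single copy are never reported — with r = 0 the statistic is
degenerate.

## Maximum-distance models

* **percentile** — nearest-rank percentile of the observed distance
  distribution (smallest d whose cumulative frequency reaches q/100;
  no interpolation on the discrete data). q = 50 gives the classical
  median threshold.
* **chrom_intersection** (default, as in the original web tool) — the
  crossing point between the normalized observed histogram and the
  geometric pmf, per sequence. Scanning d = 1, 2, …, the crossing is
  the first d where observed < expected after some occupied d where
  observed lay strictly above expected. Exact equality does not count
  as enrichment: for a normalized finite histogram some occupied
  distance always satisfies observed ≥ expected (the expected mass over
  any finite support is < 1), so arming on ties would make the
  detector's fallback unreachable and would flag coinciding curves as
  structure. If no strict exceedance ever occurs the median is used
  with a logged warning. No smoothing is applied before the scan;
  smoothing would add a parameter the method does not define.
* **genome_intersection** — same crossing rule on the union (summed
  counts) of all per-sequence distance multisets, paired with a single
  genome-wide p computed from summed N and summed slot counts. With one
  input sequence this coincides with chrom_intersection.
* **fixed** — a user-supplied d_max, with per-sequence p.

In element mode the intersection models operate in failure units:
distances are mapped to ⌈d/L_mean⌉, the crossing u is found on the
unit histogram against the geometric law in units, and the bp threshold
is ⌊u·L_mean⌋ — the largest distance whose unit count is ≤ u.

## Parameters

| parameter | default | meaning |
|---|---|---|
| distance model | chrom_intersection | how d_max is derived |
| percentile q | 50 | percentile model only; median |
| α | 1e-5 | raw p-value cutoff for reporting |
| words / pattern | — | equal-length word set; IUPAC patterns expanded (CWG → {CAG, CTG}) |

No multiple-testing correction is applied — the method thresholds the
raw p-value — but the report header carries the number of clusters
tested so a Bonferroni factor can be applied externally. Words are
searched literally with no automatic reverse complement; users wanting
both strands list both words (as with CAG/CTG). Word sets of unequal
lengths are rejected: n_f = L_c − n·k and the slot arithmetic are only
defined for a single k. p-values are computed in log space
(log-gamma + logsumexp); values below the smallest positive double are
floored at 5e-324. Degenerate inputs — saturated tiny sequences where
the slot denominator is ≤ 0 or p ≥ 1 — abort with a diagnostic rather
than produce an invalid null.

## Synthetic data

`fixtures.make_sequence` emulates the one feature of real data the
method keys on: an excess of short inter-copy distances inside bounded
windows over a memoryless background. Planted windows receive a fixed
number of copies with uniform gaps of at most `max_gap` (default 5)
intervening bases; outside them, copies arise from a Bernoulli process
at `background_rate` per kb (default 0.5); accidental background
matches are removed by an iterative repair pass and the recorded truth
is the realized post-repair occurrence set. It does not emulate base
composition heterogeneity (isochores), repeats, or strand structure —
so passing recovery tests demonstrate correctness of the detection
machinery under the stated null, not calibration on real genomes,
where the Bernoulli assumption is only an approximation.
`make_elements` lays out fixed-length elements in blocks with exact
gaps (a block of 5 × 300 bp elements with 250 bp gaps spans 2500 bp)
plus well-separated background elements. All generators take one
explicit seed and are byte-reproducible.

Test problem sizes: sequences of 40–100 kb, 3–4 planted windows of
8–12 copies, 20 seeds for the recovery property — large enough that
the intersection threshold is stable (dozens of intra-cluster
distances) and the planted p-values sit far below α.

## Numerical and design choices

* Coordinates are 0-based half-open everywhere; BED I/O is native.
* Ambiguity codes other than N also break contigs; only A/C/G/T is
  guaranteed inside a contig. Soft-masked (lowercase) bases are
  uppercased and searched.
* The promoter window R13 spans [TSS−1500 bp, TSS+500 bp] inclusive in
  transcription orientation (2001 bp on the genome); the TSS region is
  the 1-bp transcript start, with a separate 201-bp TSS±100 window.
  A cluster is counted once per region label regardless of how many
  genes or intervals it touches.
* Cluster GC and CpG O/E are the standard island quantities,
  GC = (C+G)/L_c and O/E = #CpG·L_c/(#C·#G).

## Known limitations

* The intersection detector reads the raw histogram; on sparse data
  (few dozen distances) holes in the observed support can trigger the
  crossing early and fragment clusters. Percentile or fixed models are
  preferable for very small inputs.
* The null is a 0-order (single-base-independent) Bernoulli model;
  compositional heterogeneity of real chromosomes inflates significance
  at GC-atypical loci, and no order-≥1 Markov null is provided.
* Element-mode failures ⌈L_no/L_mean⌉ are an approximation whenever
  element lengths vary widely around their mean.
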