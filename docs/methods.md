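# Methods

## Data model

A *report* is one spontaneous submission: an opaque identifier, the calendar
year the report was received, sex (F/M/U), age in years (possibly missing),
and deduplicated sets of administered vaccine-type codes and MedDRA-style
symptom terms.  Raw input follows the VAERS three-table CSV layout (DATA,
VACCINE, SYMPTOMS joined on VAERS_ID); the join is lossless with respect to
DATA-table IDs, so reports without any vaccine or symptom rows are retained
— they carry no pairs but still belong in every report-total denominator.
Sex codes are accepted case-insensitively as F/M, with anything else
(including blank) mapped to U; dates are parsed as MM/DD/YYYY with
unparseable values leaving the year missing (tallied in the log); files are
decoded permissively as 8-bit text with replacement.  Terms are matched
exactly after whitespace trimming — no case folding or MedDRA normalisation.

## Disproportionality

Within a stratum (overall corpus, one year, or one sex), with a = reports
for vaccine V containing symptom S, b = reports for V, c = reports
containing S, d = all reports:

    PRR = (a/b) / (c/d)

Two conventions are deliberate:

* **All-reports comparator.** The denominator proportion c/d is taken over
  *all* reports in the stratum, including V's own — not the classic
  "all other vaccines" 2×2-table variant.  With the comparator fixed this
  way, a vaccine present in every report has PRR exactly 1 for every
  symptom, a property the tests assert.
* **PRR > 1, strictly, and nothing else.** No minimum-count threshold and
  no companion chi-square statistic: significance is the single strict
  inequality.  Under null data roughly half of well-supported pairs land on
  each side of 1, so the filter is a structural device for network
  construction, not a calibrated alarm.

Undefined PRRs (b, c or d zero in the stratum) propagate as explicit missing
values (`None`/NaN), never as 0 or infinity, and never pass the filter.
Sex strata use F and M reports only; unknown-sex reports count in overall
and yearly strata.  Reports without a parseable year count in overall and
sex strata only.  Demographic distributions use age bands <2, 2–17, 18–64,
≥65 and unknown (configurable) — standard vaccine-surveillance bins.

## Networks

Significant pairs are edges of an undirected bipartite graph; node sets are
the unions of edge endpoints, so no isolated nodes exist, and construction
verifies that no label serves as both vaccine and AE.  Metrics per stratum:
average degree 2E/N; average shortest-path length as the mean unweighted
BFS distance over reachable unordered node pairs (self-pairs excluded,
unreachable pairs excluded — i.e., averaging within components, the common
network-analyzer convention; the equivalent ordered-pair average is
identical on an undirected graph); diameter as the largest finite distance.
The path-length total is accumulated as an integer before the single
division, making the float mean bit-reproducible against the test suite's
Floyd–Warshall oracle.  Tabular output rounds half-up to 2 decimals; full
precision is kept internally.

## Similarity, clustering, sex comparison

The PCC association index of two same-type nodes is algebraically the
Pearson correlation of their binary incidence vectors over the n_y
opposite-type nodes; it is undefined for a node of degree 0 or n_y (zero
variance).  The implementation computes it from integer degree/overlap
counts, so results are exact and symmetric.

Clustering uses average linkage on distance 1 − PCC (configurable).  The
linkage and distance are a design choice — a standard one for
correlation-profile clustering — since the index itself does not dictate
them.  Undefined entries are imputed as 0 (the index's chance reference
point) with a logged warning; labels are sorted lexicographically before
linkage so ties resolve deterministically and permuted inputs give
isomorphic trees.  Dendrograms export as Newick with branch lengths equal
to merge-height differences.

Female and male networks are built from sex-specific PRR > 1 edges — *not*
by subsetting the overall network — then projected and compared over the
vaccines present in both: paired off-diagonal PCC values (pairs undefined in
either stratum dropped), fixed-width 0.05 density bins over [−1, 1] so the
two histograms align, and a two-sample Kolmogorov–Smirnov distance reported
as a purely descriptive summary.

## RDF meta-model

One association resource per distinct pair, identified deterministically
(percent-encoded vaccine code + 16-hex-character SHA-1 prefix of the symptom
term) under the project namespace `http://vaersnet.example.org/ns#`.  Each
resource carries `hasVaccine`, `hasSymptom`, `reportCount` and either a
`hasPRR` literal or an explicit `prrUndefined` marker; yearly and
sex-specific values live on stratum nodes (`hasStratum` → `forYear`/`forSex`
+ count + PRR-or-marker, 4 triples each), and demographic cells on
`hasDemographic` nodes.  PRR literals are positional `xsd:decimal` built
from the float's shortest exact decimal form, because Turtle's plain-literal
shorthand preserves a decimal lexical verbatim while reformatting doubles;
this makes write-Turtle → parse → canonical-N-Triples an identity and the
query round-trip numerically exact.  No blank nodes are used, so sorted
N-Triples is a canonical form.  The vocabulary is a project-local stand-in;
no external IRIs (MedDRA, vaccine ontologies) are minted.

## Synthetic generator

The generator emulates the *structure* of a passive-surveillance corpus at
desk scale, with defaults chosen once as study conditions: 50,000 reports
over 2010–2013; 14 vaccine types with skewed marginal usage (seasonal
influenza 0.22 down to a 0.02 tail) and 1–3 vaccines per report
(probabilities 0.80/0.15/0.05) drawn without replacement via the Gumbel
top-k trick; 30 MedDRA-style symptom terms with background per-report
probabilities from 0.08 (pyrexia, injection-site reactions) down to 0.002
(rare serious events); sex mix F 0.56 / M 0.38 / U 0.06 reflecting the
female skew of spontaneous reporting; ages from a mixture of infant, child,
adult and elderly blocks with 2 % missing.  Symptoms are drawn independently
given the report's vaccines and sex, with each planted (vaccine, symptom,
stratum, multiplier) signal multiplying the background probability in
matching reports, capped at 1; "both" targets F and M but not U.  Everything
derives from one `numpy` generator seed, so output is byte-reproducible.

What the generator does **not** emulate — and hence what passing tests do
not show about real data: symptom–symptom correlation (syndromes),
duplicate and batch reporting, temporal reporting trends, age-dependent
vaccine schedules or risks, term-coding variability, and underreporting
biases.  Recovery results here demonstrate correctness of the computation,
not field performance of PRR screening.

## Problem sizes and numerical choices

The test suite and the acceptance script run at the sizes the analyses need
for stable behaviour, chosen as part of the study design: 50,000-report
corpora for signal recovery (20 seeds) and null calibration (pairs with
≥ 100 co-reports), a 3,000-report corpus for RDF round-trips, 5,000-report
runs for end-to-end determinism, random bipartite graphs up to 300 nodes
against the Floyd–Warshall oracle, and 1,000 random configurations for the
PCC–Pearson equivalence (tolerance 1e-12; degree/overlap draws respect
|N(A)∪N(B)| ≤ n_y).  Closed-form anchors: the 100-report fixture with
a=4, b=10, c=20, d=100 giving PRR exactly 2.0; PCC anchors 1, 0, −1.

Known limitations: the PRR here intentionally reproduces the all-reports
comparator convention described above, so values differ slightly from
classic PRR implementations on the same data; the pipe character is reserved
as the in-cell delimiter of the normalised flat CSV and may not occur in a
term; clustering of very small networks (2–3 vaccines) is computed but
rarely meaningful; and the KS distance is reported without any resampling
inference.
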