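# Methods

This note documents the models and procedures implemented in rnaloom, the
parameters that matter, the numerical and design choices made where the
design was genuinely open, and what the bundled simulator does and does not
emulate.

## Graph model

The assembly graph is a condensed bidirected de Bruijn graph. k must be odd,
which forbids reverse-complement-palindromic k-mers: every k-mer and its
reverse complement are distinct, and each oriented k-mer belongs to exactly
one edge. Canonical form of a k-mer is the lexicographic minimum of the two
orientations. Edges carry their full nucleotide sequence, the summed count
("mass") of their constituent k-mers — mean k-mer coverage is
`mass / (len(seq) − k + 1)` — and the id of their reverse-complement twin.
An edge whose sequence is its own reverse complement is stored once and
flagged `self_rc`; all removal operations treat twin pairs atomically, so
twin symmetry is an invariant of every operation, checked extensively in the
test suite. Coordinates are 0-based and half-open throughout.

Construction expands canonical counts into both orientations and walks
maximal non-branching paths; the twin of each walked unitig is emitted as
its exact reverse complement. Isolated cycles are walked from their
lexicographically smallest k-mer, and twin cycles are derived rather than
re-walked, which keeps the pairing exact. Re-condensation after edge removal
works at the edge level: chains through vertices of in- and out-degree 1 are
merged, attributes concatenated, twin chains mirrored. A brute-force oracle
(naive (k−1)-overlap graph, condensed by walking) verifies equivalence on
random inputs up to 300 bp at k ∈ {15, 21}.

## Two k-mer sizes

`k_high` is the largest odd number ≤ read_length/2 − 1; `k_low` the largest
odd number ≤ read_length/3, floored at 29 (for 100-bp reads: 33 and 49; for
150-bp: 49 and 73). If the floor reaches `k_high`, a single iteration is
run. The k_low graph is built and cleaned first; its edge sequences then
join the k_high build as *protected* k-mers: absent ones enter the table
with a pseudo-count of 1, and edges more than half made of protected k-mers
are exempt from the coverage-based removals (tip condition 1 and the
isolated-edge rule). Coverage values themselves always come from the reads.
This choice — protection as removal-exemption plus unit pseudo-counts — is
ours; the alternative (copying k_low coverage across) would double-count.

## Cleaning rules

All five procedures iterate to a fixed point (each productive round strictly
shrinks the graph's k-mer content, so termination is guaranteed), with
re-condensation inside each step, in the order tips → bulges → chimeric
loops → hairpins → isolated edges.

**Tips** (edges with a free end, in k-mer length l, coverage c_T, best
alternative coverage c_A): removed iff (1) l < 2k and c_T ≤ 1; or (2)
l < 4k, c_T < c_A/2 and Hamming distance to the alternative ≤ 3; or (3)
more than 80% A/T. The tip and its alternative are anchored at the shared
vertex and compared over the min of their lengths; with several
alternatives, the highest-coverage one is used. Tips that are genuine
alternative first/last exons fail all three tests and survive.

**Bulges**: only simple bulges — exactly two parallel edges sharing both
endpoints — with relative length difference < 10% are collapsed
(`|l1 − l2| / max(l1, l2)`; the denominator is our choice). No coverage
threshold is applied, because isoform expression levels legitimately
differ. The higher-coverage edge is kept (ties: lexicographically smaller
sequence), and the removed edge's k-mer mass is projected onto it, so
total mass is conserved. Exon-skipping bulges differ in length by the exon
and are preserved.

**Chimeric loops**: a self-loop at a vertex whose only other adjacency is a
single long edge (> 2k) is removed — purely topological. We additionally
require the loop itself to be shorter than 2k: the condensed loop contains
the genuine transcript 3' tail together with the chimeric junction (the
tail's k-mers exist nowhere else in the graph), so removing arbitrarily
long loops amputates real sequence. Long loops are left in place and
neutralised during path extension instead (below).

**Hairpins**: an edge joining a vertex v to its twin — gluing sequence onto
its own reverse complement — is removed when an anchoring edge is incident
to v. A reverse-complement repeat *between* transcripts does not join twin
vertices and is untouched.

**Isolated edges** (no adjacency at either end) are dropped when both
weakly covered (cov < 2, strict) and short (≤ read length, in
nucleotides — the read-length comparison is inherently in base units).

**Strand splitting** (stranded libraries only): per-position strand
coverage cov⁺/cov⁻ is annotated by mapping protocol-oriented k-mers; an
edge is split at the position where one strand dominates the prefix and the
other the suffix. "Much greater" is concretised as a ratio ≥ 10 with
dominant coverage ≥ 1 — the threshold is not published anywhere we know of
and is exposed in `AssemblyParams.strand_split_ratio`. The two pieces share
no vertex (the boundary-spanning k-mers are dropped) and the twin graph is
updated symmetrically.

## Read-pair mapping

No aligner is used: mates are anchored by exact k-mer lookup. Because
condensed edges are routinely shorter than a read, a mate records an anchor
on every edge it overlaps (vote-ordered, at most 4), with the top-vote edge
as its primary placement; ties go to the edge hit earliest in the read.
Pairs are stored fragment-forward (mate 1 upstream, mate 2
reverse-complemented), duplicated in the twin-mirrored orientation, and
deduplicated by fragment id wherever they are counted. The insert size
(outer fragment length) is estimated from pairs whose primary placements
share one edge. On stranded libraries pairs are first put in
transcript-sense order (RF: mate 2 leads) and each link record is tagged
sense/mirror; the extender then only counts the class matching the path's
strand (estimated from cov⁺ vs cov⁻), which is what lets stranded data
resolve reverse-complement repeats that unstranded data cannot.

## Gap closing

Dead-end and dead-start tips are glued when (a) they share an exact
suffix–prefix overlap ≥ L_ov = 8 bp and ≥ N_ov = 1 connecting pair, or (b)
≥ N_min = 5 pairs connect them. Under (b) the median pair-implied gap
decides the join: a negative gap retries the overlap search with the floor
relaxed to 4 bp (exact only), a non-negative gap concatenates directly —
no N runs are emitted. Overlaps are capped at k − 1 (anything longer would
already share k-mers). A tip with several eligible partners is left
unglued, and a tip is never glued to its own twin.

## Path extension

Seeding starts from the longest edge not yet in any path and repeats until
every edge (or its twin) is covered. Growth alternates between the forward
and the twin direction until neither extends — a path too short in one
direction may be unjudgeable by pairs until the other direction has given
it anchorage.

The score of a candidate edge is the number of distinct fragments whose
upstream mate lies on the path within one insert window
(mean + 3 sd) of the path end and whose downstream mate lands on the
candidate *or any edge reachable through it* within the window (the
"cone") — without the cone, short candidates would never collect support
because the downstream mate overshoots them. With several candidates, each
is scored on its exclusive cone (edges reachable only through it): shared
downstream evidence cannot distinguish branches that reconverge within an
insert, and counting it for every sibling would fork the path on every
residual error bubble. All candidates with score > max/C (C = 1.5) and
score > Θ are kept and extended independently; Θ defaults to 1.0 raw
pairs (its published value is not printed anywhere; it is exposed in
`AssemblyParams.theta`). The arg-max candidate is always among the
survivors.

Three guards keep pathological structures in check: a fragment whose
downstream mate sits on an edge the path already contains is not counted
(paths would otherwise orbit residual chimeric cycles); a path shorter than
one insert may take a topologically forced single fresh candidate without
pair support, but only when its mean coverage exceeds C_min (chimeric junk
edges must not bootstrap); and no edge is used more than
`max_edge_multiplicity` = 4 times per path, guaranteeing termination on
cyclic graphs.

When the pair extender fails on exactly two candidates, the coverage rule
runs: with e the higher-covered candidate, e′ the other, and (e2, e2′) the
on-path/off-path pair at the last two-way incoming vertex, e is chosen iff
cov(e) > Δ·cov(e′), cov(e2) > Δ·cov(e2′), Ω > cov(e2)/cov(e) > 1/Ω and
cov(e) > C_min (Δ = 2, Ω = 10, C_min = 2, all strict). On stranded
libraries the identical rule runs on library-forward strand coverage
instead, which resolves opposite-strand transcripts sharing a
reverse-complement region longer than the insert.

Deduplication removes exact duplicate paths and contiguous subpaths only
(twin-reversed lists count as duplicates on unstranded data); diamond forks
that later reconverge are kept as separate paths. Output orientation:
stranded — the orientation with the higher library-forward coverage;
unstranded or tied — the lexicographically smaller sequence, so runs are
byte-reproducible.

## Filtration

Three nested presets act on (length, mean coverage, isolated-edge
provenance): soft (no length/coverage floor; isolated contigs ≤ 0.5×
read length dropped), normal (cov ≥ 1; isolated ≤ 1× read length dropped),
hard (length ≥ 200, cov ≥ 2; isolated ≤ 2× read length dropped). The
thresholds are monotone field-wise, so hard ⊆ normal ⊆ soft holds for any
input — a property test checks this on randomized sets. The exact
published preset values are not available to us; these are our own,
clearly non-canonical, and fully configurable.

## Simulator

`rnaloom.simulate` generates multi-exon genes (5–7 exons of 180–350 bp,
realistic mRNA scale) with two isoforms per gene differing by one event —
by default a skipped internal exon of 60–160 bp, always longer than any
assembly k, so both isoforms are structurally distinguishable; alternative
first/last exons and diverged paralogs are available through the config.
Expression is log-normal (σ = 0.6), mean k-mer depth defaults to 20×,
fragments are uniform with normal insert lengths (300 ± 30), mates are
100 bp, substitution errors i.i.d. at 0.5%, and a 15-nt poly-A tail
exercises the low-complexity tip rule. Chimeras are injected at 1% of
pairs, half "loops" (the polymerase runs to the transcript end and jumps
back 10–35 bp, re-copying the terminal stretch — exactly the structure the
loop remover targets) and half "hairpins" (a fold-back onto the opposite
strand at the break point, producing the vertex-to-twin edge the hairpin
remover targets). Everything is deterministic given the seed.

What the simulator does **not** emulate: indels (the cleaning rules target
substitutions), empirical quality profiles, PCR duplicates, intron
retention, genomic DNA contamination, sequence-composition bias, and
shared sequence between genes other than explicit paralogs. Passing tests
therefore demonstrate the algorithms' behaviour under their own stated
assumptions, not performance on real libraries.

## Evaluation

Contigs are aligned to reference transcripts by exact 31-mer anchor
chaining (diagonal drift ≤ 30, anchor gaps ≤ 500 bp, chains ≥ 62 bp); a
spliced aligner is deliberately not reimplemented. A reference transcript
is X%-assembled when a single chain covers ≥ X of its length. Database
coverage is the fraction of reference bases covered by any chain;
duplication ratio is aligned contig bases over covered reference bases. A
contig is misassembled when its greedy non-redundant chain decomposition —
blocks are kept if they explain ≥ 100 bp (or ≥ 10%) of contig sequence not
covered by larger blocks, which matters for chimeras whose halves share a
repeat — contains blocks from different transcripts, different strands, or
positions > 1 kb apart on one transcript. These tolerances are our own
documented configuration.

## Known limitations

* Error bubbles parallel to multi-edge paths survive cleaning (only simple
  two-edge bulges are collapsed, by design); they are low-covered and
  rarely attract extension, but they inflate the contig count — the normal
  and hard filters remove most.
* Genes with more than two expressed isoforms are resolved only as far as
  pair evidence and pairwise coverage ratios allow.
* Isoforms below the coverage floors (junction coverage under ~C_min)
  fragment by design; the published rules are explicit that low-covered
  resolution risks misassembly.
* The loop remover trades a ≤ 2k nick of 3' tail for misassembly safety
  when a chimeric loop condensed over the tail is excised.
* Mapping is exact-k-mer anchoring; at substantially higher error rates
  than simulated (≳ 2%) anchors thin out and pair evidence degrades before
  graph quality does.
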