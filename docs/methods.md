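# Methods

## The dating model

A provirus is born with identical 5' and 3' LTRs; each then evolves
independently at the host's neutral substitution rate M. The package models
substitution as a per-site Markov jump process of the Kimura two-parameter
(K80) form: each site leaves its current base at total rate M, going to its
transition partner with probability κ/(κ+2) and to each transversion
partner with probability 1/(κ+2) (κ = transition/transversion rate ratio,
default 2). Rates are normalized so M is the expected number of
substitutions per site per Myr, which makes the K2P distance estimator
consistent for M·t by construction: the simulator and the estimator share
one model, so parameter-recovery tests probe the inference, not a model
mismatch.

LTR-pair divergence accrues along two branches of length t, so
`T = D/(2M)`. Gene-vs-consensus divergence treats the majority-rule
consensus of a recently expanded subgroup as a proxy for the ancestral
sequence; divergence then accrues along one branch and the default divisor
is c = 1 (`T = D/(cM)`, c = 2 selectable, and the divisor used is stamped
into every output row). Both conventions appear in the retroelement
literature; the choice matters exactly twofold, which is why it is an
explicit, recorded parameter rather than a silent default.

Mean, sample SD (ddof = 1, reported as 0 when n = 1) and median are
computed per (subgroup, method, gene); rendering as `~ mean (± sd)` with
two decimals happens only at the reporting layer — full precision is kept
internally.

## CpG masking: two conventions and a bias analysis

CpG sites hypermutate via 5-methylcytosine deamination, so dating excludes
them. The obvious convention — mask the two columns of every CpG observed
in either sequence ("union" mode) — turns out to be statistically biased:
a substitution that lands a C immediately before a G (or a G after a C)
*creates* a CpG and thereby masks its own site, so differing sites are
masked more often than matching ones. Under K80 at uniform base
composition the effect is exactly computable by enumerating (ancestral,
derived) base pairs with their K80 weights: P(masked | site differs) =
0.242 versus P(masked) = 0.125, shrinking the estimated distance by
(1−0.242)/(1−0.125) = 0.866 — a 13% downward bias in every age,
independent of whether CpG hypermutation is even present.

The package therefore defaults to "context" masking: a site is excluded
when its gap-stripped previous base is C or its next base is G, in either
row. This is a superset of the union mask (every member of every actual
CpG is covered, so all currently hypermutable sites are excluded), and its
masking status depends only on a site's *neighbors*, never on the site's
own base — it cannot correlate with whether the site differs, so the
retained sites give an unbiased divergence. The cost is fewer compared
sites (roughly 7/16 of sites masked at uniform composition, vs ~1/8), i.e.
somewhat higher variance. Both modes are available
(`mask_cpg(rows, mode=...)`); distances always report n_sites, the count
of CpG-masked sites, and gap/ambiguity exclusions separately. Residual
bias under hypermutation remains in either mode from sites whose CpG
context existed earlier in their history but has since decayed; the
masking-benefit test quantifies that the masked estimator is far closer to
truth than the unmasked one (which overestimates ages ~2-fold at a 10×
CpG rate multiplier).

Saturation (a non-positive log argument) is an explicit typed outcome, so
summaries can count exclusions instead of propagating NaN or infinity.

## LTR pair detection and boundary handling

Loci are self-compared with 12-mer anchors; anchor pairs at the same
offset (diagonal) at least 4 kb apart vote for a candidate direct-repeat
pair, which is then extended outward ungapped with an x-drop scheme (match
+1, mismatch −3 — the log-likelihood-ratio scoring for ~99%-identical
repeat vs unrelated sequence — argmax boundary, outermost on ties), and
finally trimmed so each boundary ends in four consecutive matched pairs.
The highest-scoring candidate wins; TSDs are recovered as an exact 4–10 bp
duplication immediately outside both LTRs. Boundary estimation from two
diverged copies is inherently uncertain by a few bp: a chance match just
outside the true boundary is statistically indistinguishable from repeat.
Two consequences are handled explicitly:

* Reported boundaries are maximum-likelihood coordinates, accurate to
  ±5 bp for insertions up to ~2 Myr old (verified against simulator
  truth).
* Dating does not trust the outermost bases: the divergence computation
  uses the detected LTR slices minus a fixed 10 bp margin at each end.
  An overshot boundary aligns unrelated flanking bases (~75% mismatch)
  into the pair, which would otherwise contaminate D; because the margin
  is content-blind it cannot bias the per-site divergence of what remains.
  The margin is sized from the overshoot-length distribution of the x-drop
  extension (overshoots beyond 10 bp containing a mismatch have
  probability ~10⁻⁵ per boundary).

## Reference-guided annotation

Gene intervals are projected from a reference provirus annotation through
a global pairwise alignment of internal regions. Two scoring regimes are
used deliberately. General pairwise alignment (consensus construction, LTR
dating, outlier screens) uses match 2 / mismatch −3 / gap open −5 /
extend −2. The reference-projection alignment instead uses open −12 /
extend −0.5: with cheap gap opening, the optimizer shaves bases off long
deletions wherever chance matches exist inside them (a planted 133-nt
deletion is measured as ~127 nt), whereas expensive-open/near-free-extend
keeps each real deletion one contiguous run whose length is measured
exactly — the property the deletion signatures (133/1487/2216 nt, matched
within a ±10 nt tolerance; unmatched runs ≥50 nt reported as "other")
depend on. Traceback is deterministic in both regimes.

Motif states (PRPPIY/PQPPVL, PPPY/TPPY, CETTG/altered/absent) are read
from the translated gag/env in the mapped frame within ±15 aa of the
reference-homologous position; CETTG is called "absent" rather than
"altered" when more than half of env is gone (the large env deletion
removes the motif region). ORF status requires zero internal stops and
≥90% of the reference gene length for "full_length". Subgroups are
assigned by nearest consensus (percent identity via global edit distance;
floor 70%, below which "unassigned"), with one consensus per subgroup —
mixing B1 and B2 into a single group-B consensus would let the majority
env deletion into the consensus and distort assignment for the
deletion-free half — and the env-deletion signature splitting group B into
B1 (present) versus B2 (absent).

## Consensus and clades

The built-in aligner is center-star progressive alignment (center chosen
by shared-k-mer similarity; pairwise alignments to the center merged with
per-position maximum insertion padding), adequate for the ≤300 × 12 kb
instances this pipeline produces; any external aligner can be substituted
via a command template (e.g. `mafft --quiet {input}`). Majority-rule
consensus counts the gap as a symbol; gap-winning columns are omitted from
the consensus but kept in the column map; ties break by fixed base order
A<C<G<T, a base beating a gap. Outlier exclusion iteratively removes the
member with the lowest identity to the current consensus (recomputed after
each removal; deterministic tie-break by id) until all members meet the
threshold (default 60%).

LTR clades are defined by indel fingerprints, not trees: gap blocks
(maximal runs of ≥3 gap-containing columns in the master LTR alignment,
terminal blocks excluded as boundary-placement artifacts) are scored
present/absent per LTR; identical vectors form clades, optionally merged
by Jaccard distance. The 5' and 3' LTRs of one provirus enter as separate
taxa so per-provirus concordance is checkable. The neighbor-joining tree
(deterministic lowest-index tie-break; negative branch lengths clamped to
zero with the deficit moved to the sibling; midpoint-rooted on the longest
leaf-to-leaf path) is a visual companion only.

## The simulator: what it emulates, and what it does not

The generator plants proviruses with the canonical structure into a
uniform-composition host, with: ages drawn uniformly from 0–7 Myr; LTRs
evolved independently and the internal region once; per-subgroup
diagnostic deletions (env 1487 nt with probability 1 in B1 — the defining
character of the B1/B2 split; pol 133 nt in ~72% of B1; pol 2216 nt in
~13% of B2); LTR indel combinations drawn from a per-subgroup menu (two
combinations in group A, five across B, none in C), planted in the
ancestral LTR so both copies share them; late-domain and CETTG variants at
the frequencies observed in each subgroup; premature stops planted at
known codon indices; TSDs of 4–6 bp duplicated from the insertion site.
Subgroup ancestors derive from one family ancestor evolved 12.5 Myr per
branch (~94.5% between-subgroup identity), then repaired to intact ORFs
with their subgroup's motif forms. Truth records carry coordinates
(0-based half-open), ages, planted features, and motif states *as scanned
from the final sequence* — so a motif destroyed by a post-planting
substitution is recorded as what it actually is, and recovery tests
compare annotation against sequence reality rather than against intent.

Deliberately not simulated: inter-LTR gene conversion (which biases real
LTR ages downward and is the main caveat on the clock), solo-LTR
formation, recombination, segregating insertions, indel mutations inside
genes (indels are planted, never stochastic, so length-recovery tests are
exact), host composition structure (GC heterogeneity, CpG islands), and
minus-strand insertions (mining normalizes orientation at extraction; the
simulator plants plus-strand). Passing recovery tests therefore
demonstrates correctness of the inference machinery under the stated
model, not robustness to every property of real genomes.

Default problem sizes were chosen to keep the full test suite and the
acceptance script desk-scale: recovery runs use a 2 Mb host with 50
proviruses spaced ≥25 kb apart (each provirus then occupies its own
±10 kb extraction locus), rate recovery uses 1,000 LTR pairs, and the
linearity check uses 200 pairs per true age.

## Known limitations

* Ungapped LTR-pair comparison: post-insertion indels *within* one LTR of
  a pair would break the shared-diagonal assumption; at the simulated
  divergences (≤7 Myr) substitution-only LTR pairs are realistic, but
  very old families would need a gapped pair aligner.
* One provirus per locus: a merged locus containing two proviruses yields
  only the highest-scoring pair (default spacing makes this a non-issue
  in simulations; tandem proviruses in real data would need iterative
  masking).
* The center-star aligner is built for near-identical families; deeply
  diverged inputs should use an external aligner via the command
  template.
* Gene-consensus ages inherit the consensus-quality of small subgroups; a
  singleton's gene age is undefined and skipped.
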