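# Methods

## Problem and model

`bismotif` discovers a single over-represented DNA motif of fixed width *k*
in a set of *N* co-regulated sequences *f₁ … f_N* (a ChIP-chip or ChIP-seq
sequence-set), optionally guided by any number ℓ of position-specific priors
(PSPs) *S₁ … S_ℓ*.  A PSP stores, per sequence *i* and per admissible start
*j*, the prior probability that a width-*k* motif starts there; such priors
are computed upstream from orthologous conservation, DNA duplex
destabilisation energy, nucleosome occupancy or ChIP-seq coverage.

The motif is an IUPAC string *m*; it induces a 4×*k* column-stochastic PSSM
under a smoothing parameter δ: in each column the bases in the symbol's set
share mass 1−δ uniformly, the remaining bases share δ uniformly (a full
{A,C,G,T} set is the uniform column).  δ defaults to 0.1 so that every
log-probability is finite; δ = 0 gives exact-match semantics.

The objective is the **balanced information score** (BIS).  Writing
*P_m(w)* for the PSSM probability of word *w* and λ ∈ (0,1] for the balance
constant, every sequence is annotated at the start *jᵢ* maximising its
balanced term, and

```
BIS(m, f, S) = Σᵢ max_j [ λ · log P_m(fᵢ[j … j+k−1])
                          + (1−λ) · Σ_p α_p · log S_p[i, j] ]
```

with convex prior weights α_p ≥ 0, Σ α_p = 1.  Both factors are
probabilities, so BIS ≤ 0 and BIS = 0 exactly when the motif occurs with
probability 1 at every annotated start (and, for λ < 1, the priors put
probability 1 there).  The score is minus a λ-weighted sum of
self-informations: maximising it minimises the combined surprise of
observing the motif and the priors at the annotated positions.  There are
no latent variables and no background model; over-representation enters
only through the annotated occurrence probabilities.

With ℓ = 0 the prior term vanishes and λ plays no role.  A uniform prior
adds a motif-independent constant per sequence, so at any λ it changes no
annotation, no greedy decision and no reported motif — the package treats
this invariance as a test contract (it is also why coverage-based priors on
short fragments add nothing over the uniform prior: their information is
already encoded in the over-representation term).

## Search

Discovery is seeded, then refined:

1. **Seeding.**  Width-*k* DNA words are enumerated by letter-by-letter
   extension over {A,C,G,T}.  A prefix is pruned when the number of
   sequences containing it within Hamming distance *e* (over the prefix's
   length) drops below a quorum; since prefix distance never exceeds
   full-word distance, no quorum-meeting word is lost.  Survivors are
   ranked by a z-score of their support against a uniform-background null:
   per sequence, P(≥1 hit) = 1 − (1 − V/4ᵏ)^W with neighbourhood size
   V = Σ_{d≤e} C(k,d)·3ᵈ and window count W; the null depends only on
   (k, e, sequence lengths), so equally supported words tie, and ties break
   by support then lexicographically.  If fewer than z_min words survive,
   the quorum relaxes in steps of ⌈0.05·N⌉ down to 1; the ranked list is
   truncated at z_max.  When the 4ᵏ×N presence table fits in memory and
   e ≤ 2 an equivalent dense counting path is used (identical output,
   verified against the extension search in tests).  This enumerator is a
   deliberately simple stand-in for suffix-tree consensus extractors; any
   external tool can replace it via a seeds file.  The null's
   independent-window assumption ignores overlap correlation between
   windows — it is a ranking device, not a calibrated p-value.

2. **Greedy IUPAC refinement.**  Each of the top *z* seeds is hill-climbed:
   positions are visited cyclically (0-based, modular), at each position all
   15 IUPAC symbols are tried, and a substitution is kept only if it
   strictly improves BIS; the search stops after *k* consecutive positions
   without an accepted move.  Every accepted move strictly increases a
   score bounded above by 0 over a finite motif space, so the procedure
   terminates and never revisits a motif.  The refined motif with the
   highest BIS is reported (first encountered wins ties); the running best
   is initialised with an empty-motif sentinel that loses every comparison
   and is never user-visible.

### Numerical choices

- **Tie guard.**  "Strictly improves" means beating the incumbent by more
  than a relative 1e-9 tolerance.  Mathematically tied motifs can differ by
  a few ulps depending on summation order (e.g. the identical objective
  shifted by a uniform-prior constant), and a bare `>` would let rounding
  noise choose different tie members across equivalent runs.  Genuine
  improvements in this objective are ≥ 1e-3; the guard is orders of
  magnitude below them.  Accepted moves are re-scored from scratch so
  incremental-update drift never enters the accepted chain.
- **Zeros.**  PSP entries are floored at `prob_floor` (default 1e-10) at
  load so logs stay finite; rows are not renormalised afterwards, since the
  score only compares entries within a sequence and flooring preserves that
  order.  Windows overlapping a masked base (N) are excluded from
  annotation and from seed-occurrence counting.
- **Tie-breaks.**  Annotation argmax: smallest start, then + strand.
  Inner-loop symbol order is the fixed canonical A,C,G,T,R,Y,S,W,K,M,B,D,
  H,V,N; the loop keeps scanning the remaining symbols after an acceptance,
  comparing against the updated motif.
- **Degeneracy cap.**  `max_degenerate` restricts how many positions may
  hold a non-{A,C,G,T} symbol (the ChIP-seq preset sets 2; unlimited by
  default).  On very large sequence-sets unconstrained refinement drifts
  toward highly degenerate strings.

## Default parameters

| parameter | default | meaning |
|---|---|---|
| k | 8 | motif width (the PSP convention: priors are computed for 8-mers) |
| λ | 1 if ℓ=0, else 1/2 | balance of sequence vs prior information |
| α_p | 1/ℓ | prior weights when no quality knowledge exists |
| δ | 0.1 | PSSM off-consensus smoothing |
| e | 2 | seeder mismatch budget (the classic (8,2) planted-motif regime) |
| quorum | ⌈0.8·N⌉ | sequences that must contain a seed word |
| z / z_min / z_max | 10 / 10 / 50 | seeds refined / returned bounds |
| prob_floor | 1e-10 | PSP log-safety floor |
| step / df | 25 bp / 3 | peak-prior step width and t density df |

## Peak-summit prior

For ChIP-seq data a coverage prior is built from per-sequence peak summits:
the prior over window starts is proportional to a Student t density (df = 3)
of the distance between the window centre (start + ⌊k/2⌋) and the summit,
discretised to 25-bp steps (the density is evaluated at each step's centre,
in step units, so all starts within a step share one value), then row-
normalised.  It is symmetric about the summit.  Window *centre* rather than
start is used because the biological statement — motifs pack near the
summit — is about motif location; centre distance is also symmetric for
both parities of k.

## Motif comparison

Reported motifs are compared to a reference by a scaled Euclidean PSSM
distance: the per-column Euclidean distance averaged over columns and
divided by √2, so identical matrices score 0 and disjoint point-mass
matrices score 1.  Unequal widths slide the shorter matrix over the longer
and take the minimum over full-overlap offsets (both strands optionally).
The recovery benchmark calls a report a success at distance ≤ 0.25.  This
metric and the IUPAC→PSSM smoothing rule are this package's own
formalisations of the standard practice; threshold and δ are configurable.

## Synthetic data

The generator emulates the yeast ChIP-chip regime: N = 200 sequences of
500 bp of i.i.d. background (uniform by default, GC bias available), each
with exactly one planted occurrence of a width-8 consensus (default
TCACGTGA, an E-box-like word of the kind bound by yeast Cbf1/Pho4) carrying
exactly 2 random substitutions, at a uniform random start — the classic
(8,2) one-occurrence-per-sequence planted-motif setting, matching the
scorer's one-annotation-per-sequence contract.  Synthetic PSPs place a
fraction `prior_concentration` of each row's mass on the planted start
(jittered by a rounded Gaussian of `prior_noise_sd` bp, clipped to range)
and spread the rest uniformly.

The benchmark's noisy-prior arms use concentration 0.5 with 2 bp jitter: a
realistic mis-registration scale for summit-derived priors.  Point-mass
priors displaced by tens of bp are *adversarial* for this score — they
reward degenerating the motif until annotations migrate to the false peaks
— and do not represent any real PSP, whose peaks are broad and roughly
correctly placed.

What the generator does **not** emulate: correlated, broadly peaked real
priors; compositional bias, repeats and masking patterns of real genomes;
sequences with zero or multiple occurrences.  Passing recovery benchmarks
demonstrates the machinery end to end, not field accuracy on real
ChIP data.

## Known limitations

- One motif, one fixed width, one occurrence per sequence; no quorum
  fraction (sequences without a site still get annotated somewhere).
- The seeder's significance is a ranking heuristic (independent-window
  binomial null), not a calibrated significance test.
- The greedy search finds a local optimum of BIS per seed; quality depends
  on seed coverage of the true motif's neighbourhood.
- Exact mathematical score ties are resolved deterministically but
  arbitrarily (first in canonical order); distinct tied optima exist on
  small or highly symmetric inputs.
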