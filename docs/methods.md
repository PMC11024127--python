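# Methods

This note documents the model implemented by `tcommit`, the numerical and
design choices that were genuinely open, and what the package's tests do
and do not establish.

## Model

### Transcriptional level

Six species per cell — Runx1 [R], Tcf7 [T], Gata3 [G], PU.1 [P], the
Bcl11b-opposing function X, and the Notch signal N — with Shea–Ackers
production terms and first-order decay:

```
d[R]/dt = (p1[R] + p2 N) / (1 + p1[R] + p2 N) − γ_R [R]
d[T]/dt = (p3[T] + p4[G] + p5 N/(p6+[P])) / (1 + p3[T] + p4[G] + p5 N + p7[P]) − γ_T [T]
d[G]/dt = (p8[T] + p9 N/(p10+[P])) / (1 + p8[T] + p9 N + p11[P]) − γ_G [G]
d[P]/dt = p12[P] / (1 + p12[P] + p13[R][G][T]) − γ_P [P]
d[X]/dt = 1 / (1 + p14[T] + p15[G]) − γ_X [X]
dN/dt   = p16 / (1 + N)
```

Stochastic simulation reads these rate laws at integer counts: each
production term is one reaction channel (+1), each decay term γ·count one
channel (−1); Notch has no decay channel and is monotone non-decreasing.
The exact Gillespie algorithm is used; a reaction at count 0 has zero
propensity, so counts stay non-negative.  Defaults: p1..p16 = 0.10, 1.00,
5.00, 1.00, 1.50, 0.01, 0.50, 0.70, 0.50, 1.00, 0.20, 2.50, 2.60, 2.00,
1.00, 0.01; γ_R = γ_T = 0.15, γ_G = 0.23, γ_P = 0.06, γ_X = 0.02 h⁻¹.

Two dynamical features drive everything downstream.  The p5·N/(p6+[P])
term with p6 = 0.01 makes Tcf7 production explode once PU.1 reaches zero,
so Tcf7/PU.1 form a stochastic toggle (the "preparatory switch"); and with
Tcf7 high, X production 1/(1+2[T]+[G]) collapses, after which X decays at
the slow rate γ_X = 0.02 h⁻¹ — X depletion is therefore late and variable,
which is where commitment heterogeneity comes from.

The deterministic mode (`integrate_ode`, LSODA, rtol 1e-8) treats counts
as reals.  It exists for validation and knockdown sanity checks only; at
these copy numbers (1–10 molecules) the SSA ensemble mean differs from the
mean-field ODE by a genuine Jensen bias of up to ~10 % over a few hours,
which the test suite documents rather than hides.

### Epigenetic level

The Bcl11b regulatory region is S = 500 exchangeable sites in states
closed (C), intermediate (I) or open (O); direct O↔C transitions do not
exist.  Nine channels with Table parameters k1 = 0.28, k2 = k3 = 0.20,
α = β = ε = 0.002, γ_m = δ = 0.0005 (γ renamed γ_m to avoid clashing with
the GRN decay rates):

| attempt rate      | transition | mediator |
|-------------------|------------|----------|
| k1·[X]            | O → I      | —        |
| k1·[X]            | I → C      | —        |
| k2·N + k3·[R]     | C → I      | —        |
| k2·N + k3·[R]     | I → O      | —        |
| α                 | O → I      | C        |
| β                 | I → C      | C        |
| γ_m               | I → O      | O        |
| δ                 | C → I      | O        |
| ε                 | I → C      | I        |

A channel fires at its attempt rate; the transitioning site is drawn
uniformly among all S sites and must match the source state, and mediated
channels additionally require a uniformly drawn mediator site to match.
Because sites are exchangeable this rejection scheme aggregates exactly to
propensities rate·(source/S)·[mediator/S], which is what the kernel
implements (verified against a literal per-site rejection sampler at
S = 10 by a chi-square test).  The mediator may coincide with the
transitioning site in the ε channel; at S = 500 the effect is negligible.

The consequence of the 1/S scaling is that spontaneous region dynamics are
slow — a few site transitions per hour against 500 sites — so between
divisions the open fraction only drifts, and the large opening steps come
from the division rule below.  The region is open, and the cell committed,
when O ≥ 75 % of S (inclusive threshold).

The epigenetic SSA is driven by the cell's own GRN trajectory: (X, R, N)
are piecewise constant between GRN events, and the waiting-time draw is
restarted at each GRN event time, which is exact for piecewise-constant
hazards by memorylessness.  Levels are simulated sequentially (GRN first)
because the region depends on the GRN but not vice versa.

### Proliferation level

A colony starts from one generation-0 cell with counts R=1, T=2, G=1, P=5,
X=8, N=7 and a fully closed region (C=500).  Division times are Gaussian
per generation — (μ, σ) = (34, 13), (15, 5), (13, 5), (12, 4) h for
generations 0–3 and (12, 3) h from generation 4 — resampled until
positive.  A cell divides if birth + T_div ≤ 120 h (a division at exactly
the horizon counts; its daughters are zero-lifetime censored leaves),
otherwise it is censored at 120 h and becomes a leaf.

At division the daughters copy the mother's gene counts.  The region is
copied verbatim when the mother's end-of-life X > 0.  When X = 0, each
daughter independently applies the opening rule **as a two-pass update**:
all closed sites become intermediate first, then every intermediate site
(old and new) opens with probability ½, i.e. O' = O + Binomial(C + I, ½),
C' = 0.  Under this rule the open fraction obeys o' ≥ (1 + o)/2, so a
lineage that has lost X crosses the 75 % threshold within at most two
further divisions — which is precisely the observed one-to-two-generation
delay between decision and commitment.  The one-pass alternative (only
pre-existing intermediate sites may open) needs exactly three X = 0
divisions from a closed region and produces a uniform three-generation
delay; the two-pass form is the one consistent with the reported
phenomenology and is the package's choice.

### Reproducibility

Every source of randomness derives from one root seed.  Cells get
structural ids (root 0, children 2i+1, 2i+2) and a per-cell stream from
SeedSequence(root seed, spawn_key=(cell id,)), consumed in a fixed order
(inheritance draw, division time, GRN kernel seed, region kernel seed), so
colony results are independent of traversal order and bit-reproducible.
Ensembles derive per-colony seeds the same way from a base seed.

## LCA classification

Statuses are evaluated at end of life ("before division"), matching the
tree colouring (white = open, black = closed & X > 0, red = closed &
X = 0).  A closed cell is an LCA iff each of its two daughter branches
contains an open descendant; its order is 1 + min over branches of the
subtree distance f (f = 0 for an open node, else 1 + min over children).
Closed non-LCA cells with an LCA ancestor are post-LCA of order equal to
the distance to the most recent LCA ancestor; the rest are pre-LCA.  Open
cells are never LCAs, and a closed cell below an open one (the model
permits reopening/closing, though it is rare) is classified by the same
unchanged rules.  The production classifier is a two-sweep dynamic program
and is required by the test suite to agree exactly with a brute-force
enumerator on 10⁴ random trees.

The commitment-delay statistic: for each open cell, its X-loss cell is the
earliest ancestor-or-self whose end-of-life X is 0 while its mother's was
positive (the root qualifies if it ends at 0); each loss cell counts once
per colony; the delay is the subtree distance f from the loss cell to the
first open cell at or below it.  Per-category expression tables pool the
end-of-life values of all cells over all colonies (SD with ddof = 1, NaN
for singleton categories).

"Number of divisions per colony" is the modal leaf generation — the number
of divisions a typical cell alive at the horizon has undergone.  Division
draws are per cell, so lineages reach different depths; the maximum
generation is an extreme-value statistic (biased upward by roughly three
generations in a ~500-leaf colony) and is exposed separately.

## Knockdown protocol

A knockdown multiplies one gene's production propensity by a factor
(default 0.2).  Onset 0 also multiplies the gene's initial count, rounded
to the nearest integer with ties away from zero (the SSA needs integers).
A later onset leaves the process untouched up to the onset time — the
pre-onset trajectory is statistically identical to wild type — and then
switches the factor for all live cells and their descendants; existing
counts are not rescaled at onset.  A factor of 1, or an onset equal to the
horizon, reproduces the wild-type ensemble bit for bit.

## Synthetic data and fixtures

The package generates all of its own data.  `tcommit.fixtures` builds
small hand-specified lineage trees whose per-cell values are synthetic
(chosen to realise a status, not simulated); they cover the category
system's corner cases — all-closed, all-open, order-1 LCA, the
order-5-vs-6 asymmetry, and a post-LCA lineage returning to LCA.  Random
status trees drive the classifier/oracle equivalence tests.  What passing
tests show is therefore internal consistency of the simulator and
analysis, plus agreement with the study conditions' reported statistics;
they do not validate the parameterisation against new experimental data,
and the model omits cell death, CD25, asymmetric division, spatial
signalling and alternative fates for escaping cells by construction.

## Numerical choices and problem sizes

* SSA kernels are numba-jitted; a wild-type colony simulates in well under
  a second, so the test suite runs 30-colony ensembles and the acceptance
  script a 300-colony ensemble (batched 25 at a time to bound memory).
* Knockdown ensembles: 20 colonies for Tcf7, 60 for Gata3, 30 for the
  trend and narrowing checks, 30 per onset for the delayed series.  The
  Tcf7 result "no open cells" is itself stochastic: the PU.1-collapse
  escape route survives the knockdown at a measured rate of roughly one
  colony in 300, so small nonzero counts can occur at some seeds.
* The division-count statistic straddles 7/8 because the cumulative mean
  division times reach 122 h ≈ the 120 h horizon at generation 8; over
  many colonies the mode can resolve to either value.
* Waiting times crossing an input change-point or knockdown onset are
  discarded and redrawn (exact by memorylessness).  Degenerate intervals
  (t0 = t1) return the initial state; zero total propensity censors at the
  horizon rather than erroring.
* Newick/NHX export writes floats with `repr` so export → parse → export
  is byte-identical; branch lengths are cell lifetimes in hours.

## Known limitations

* The mean-field ODE is not the SSA mean (documented Jensen bias); use the
  ODE only for qualitative sanity checks.
* Pre-LCA/post-LCA statistics pool cells whose colonies never commit with
  early cells of committing colonies; interpretation should follow the
  category definitions, not colony fate.
* The per-colony open fraction at 120 h is small in most wild-type
  colonies (median near zero over 30 colonies); commitment concentrates in
  colonies whose switch fired early.  Statements about "typical" colonies
  are therefore sensitive to ensemble size.
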