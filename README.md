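# tcommit

Agent-based multi-scale stochastic simulation of early T-cell lineage
commitment, with last-common-ancestor (LCA) lineage analysis and in silico
knockdown experiments.

## The scientific problem

Early thymic progenitors (ETP/DN1 cells) proliferate for several cell
cycles before committing to the T-cell fate; commitment is marked by
expression of *Bcl11b* as cells transition to the DN2b stage.  The timing
between the *decision* to commit and the *observed* commitment is hard to
access experimentally because colonies are heterogeneous in both division
number and commitment timing.  `tcommit` simulates clonal T-cell colonies
in which every cell is an individual agent, builds the resulting lineage
trees, and classifies cells by their relation to committed descendants,
making the decision-to-execution delay directly measurable.

The model has three coupled levels inside every cell:

1. **Transcriptional level** — a six-species stochastic gene regulatory
   network: Runx1 (R), Tcf7 (T), Gata3 (G), PU.1 (P), the Notch signal (N)
   and a hypothesized Bcl11b-opposing function X.  Production rates follow
   the Shea–Ackers thermodynamic form, e.g.

   d[T]/dt = (p3·[T] + p4·[G] + p5·N/(p6+[P])) /
             (1 + p3·[T] + p4·[G] + p5·N + p7·[P]) − γ_T·[T]

   and the system is simulated exactly with the Gillespie algorithm on
   integer molecule counts (an ODE mode over real counts exists for
   validation).  Tcf7 and PU.1 form a mutual-repression switch; Tcf7 and
   Gata3 repress X; Notch has no decay term.

2. **Epigenetic level** — the Bcl11b regulatory region as S = 500 sites,
   each closed (C), intermediate (I) or open (O), with no direct C↔O
   transitions.  X drives closing (attempt rate k1·[X]), Runx1 and Notch
   drive opening (k2·N + k3·[R]); five slow channels need a mediator site.
   A channel fires at its attempt rate and a uniformly chosen site (and
   mediator) must match, giving aggregated propensities
   rate·(source/S)·[mediator/S].  The region — and hence Bcl11b — counts
   as **open** when ≥ 75 % of sites are open; that cell is committed.

3. **Proliferation level** — cells divide with generation-dependent
   Gaussian cycle lengths T_div ~ N(μ_g, σ_g) (34±13 h at generation 0,
   shrinking to 12±3 h from generation 4) over a 120 h horizon.  Daughters
   copy the mother's gene counts.  Site counts are copied verbatim if the
   mother ends life with X > 0; if X = 0, closed sites become intermediate
   and every intermediate site opens with probability ½ — so losing X makes
   the region open within about two further divisions.

On top of the simulator, the **LCA classification** labels every cell of a
lineage tree as `open`, `LCA n` (a closed cell with open descendants in
both daughter branches, n generations from the nearest one), `closed
post-LCA m` (closed, m generations below its latest LCA ancestor) or
`closed pre-LCA` (closed, no LCA ancestor).  This yields a
generation-number-free coordinate system in which commitment decisions can
be located and compared across colonies.

## Worked example

```python
import tcommit as tc
from tcommit.experiments import wt_report, delay_statistics

cfg = tc.default_config()               # wild-type parameters and ETP state
report, cats, trees = wt_report(30, cfg, seed=1, return_trees=True)

print(dict(report.division_histogram()))
# {6: 2, 7: 8, 8: 10, 9: 7, 10: 3}

d = delay_statistics(trees, cfg.epigenetic)
print(len(d), d["delay"].mean(),
      int(d["lca_order"].dropna().astype(int).value_counts().idxmax()))
# 55 2.0 2
```

The division histogram says that among 30 simulated wild-type colonies the
most common colony size is 8 divisions (range 6–10 here).  The delay table
finds 55 X-loss events on committed paths: on average the first Bcl11b-open
cell appears 2.0 generations below the cell that lost X, and the X-loss
cells are most often `LCA 2` cells — the commitment decision precedes its
execution by about two generations.

The pooled per-category means show the same story as a population statistic
(`cats` from the call above, selected rows):

```
      category  count  mean_T  mean_P  mean_X  mean_open_site_fraction
closed pre-LCA  13117   13.93    7.23   14.70                     0.08
         LCA 5     10   32.70    0.30    3.10                     0.03
         LCA 2     29   40.62    0.00    0.00                     0.07
         LCA 1     84   39.73    0.00    0.00                     0.56
          open    404   40.57    0.00    0.16                     0.86
```

Reading upward: the Tcf7-high/PU.1-low preparatory switch is already thrown
by LCA 5, X is fully depleted at LCA 2, and the open-site fraction only
then rises through LCA 1 (0.56) to the open cells (0.86).

The same experiments are available from the shell:

```console
$ tcommit simulate --seed 11 --out run/
colony: 331 cells, 7 divisions, fraction open 0.084
$ tcommit ensemble --colonies 30 --seed 1 --out ens/
30 colonies; modal divisions 8; median fraction open 0.000
$ tcommit knockdown --gene Tcf7 --colonies 10 --seed 1 --onset 0 --onset 60 --out kd/
onset    0.0 h: median fraction open 0.000, median mean X 42.16
onset   60.0 h: median fraction open 0.000, median mean X 28.92
```

`simulate` writes the colony as an annotated Newick/NHX tree (`tree.nhx`,
re-parsable with `tcommit classify` or `tcommit.parse_tree`), a per-cell
CSV and a manifest from which the run can be re-created exactly.  The
knockdown output shows Tcf7's role: knocked down from t = 0 the colonies
keep X high (median colony-mean 42) and nothing commits; knocked down at
60 h, X is lower and commitment partially recovers.

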