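# Methods

## Scope and data model

`chiqspr` works entirely on hydrogen-suppressed heavy-atom graphs: atoms
carry an element (C, N, O), a formal charge (0 or +1), and an attached-
hydrogen count; bonds are unordered index pairs. Bond order is ignored
throughout — both connectivity degrees depend only on adjacency and
hydrogen counts — so aromatic rings enter as plain cycles, with the
hydrogen count of an aromatic atom inferred from its valence less the one
electron committed to the ring π system (an aromatic CH has h = 1).
Counterions are never part of the graph: the surfactants are modelled as
their covalent dications, and the packaged reference values are consistent
only under that convention. Graphs are validated on construction
(connected, simple, degree ≤ 4, degree + h equal to the standard valence:
C 4, N 3, N⁺ 4, O 2) and are immutable afterwards, which lets fragment
enumerations be memoized safely.

The electron parameters entering the valence degree
δᵛ = (Zᵛ − h)/(Z − Zᵛ − 1) are fixed per element: C (6, 4), N (7, 5),
O (8, 6). A quaternary or aromatic N⁺ keeps Zᵛ = 5 and Z = 7 — the charge
enters only through the hydrogen count and degree — giving δᵛ = 5 for a
quaternary nitrogen. This convention was validated by recomputing the full
packaged descriptor row of the 12-6-12 dication, which matches to better
than 3 × 10⁻⁶ per index.

## Index computation

Fragments of order m (= edge count, m ≤ 4) are enumerated as connected
edge-subsets by depth-first growth: each subset is grown from its
minimum-index seed edge, only edges adjacent to the current fragment and
with index above the seed are added, and a final edge-set dedup removes
residual duplicate orderings. The cost is O(Σ_f deg(f)) over generated
fragments — for surfactant-sized molecules (≤ ~45 heavy atoms) well under
a millisecond per order. Classification uses within-fragment degrees
only: a cyclic edge set (|V| ≤ |E|) is a *ring*; an acyclic one is a
*path* (max degree ≤ 2), a *cluster* (star), or a *path-cluster*
(branched, non-star; first possible at m = 4). Ring fragments are
enumerated and queryable but never contribute to path/cluster/
path-cluster indices — relevant only for the cyclic test compounds, since
the training set is acyclic. Order-2 fragments are always classified
path, including those centred on a branch vertex.

Index values accumulate in input order in 64-bit floats; fragment
enumeration order is made deterministic by sorting edge sets. An
exhaustive oracle (`brute_force_chi`) iterates over all C(E, m) edge
subsets with independent connectivity/classification checks; it refuses
graphs above 12 edges and exists purely as a test cross-check. The two
routes agree to ≤ 10⁻¹² on hundreds of random molecules; all ten indices
are invariant under atom relabelling.

Reference tables print indices to five decimals with occasional one-ulp
rounding oddities (and one visibly truncated entry, 22.77 for the
12-6-12 ²χ, where chain homology demands 22.777); all comparisons against
packaged values therefore use an absolute tolerance of 2 × 10⁻⁵, and the
truncated entry is stored as printed.

## Regression conventions

Models are ordinary least squares with intercept, solved by orthogonal
decomposition (`numpy.linalg.lstsq`), no regularization. The reported
statistics follow the conventions of this QSPR lineage rather than
standard multiple-regression output:

* r² = Σ(ŷ − ȳ)²/Σ(y − ȳ)², identical to 1 − SSE/SST for OLS with
  intercept (asserted numerically on every fit);
* r = +√r², not Pearson's signed coefficient;
* F = (n − 2)·r²/(1 − r²) with the n − 2 factor for **every** model,
  including the two-descriptor one — the published two-descriptor
  F = 585.4 only arises under this convention;
* s = √(SSE/(n − 2)).

Slope standard errors are the conventional s²(XᵀX)⁻¹ diagonal with the
same n − 2 based s. Descriptor cross-correlations are standard Pearson
coefficients reported as magnitudes.

## Stepwise selection

`run_selection` automates what can be automated and logs the rest:

1. **Step 1** ranks the ten single-index fits by r² (ties: s, then column
   order). ²χ ranks first (r = 0.982).
2. **Collinearity classes** at three printed decimals: high ≥ 0.97,
   appreciable [0.90, 0.97), weak [0.50, 0.90), none < 0.50. The training
   matrix has exactly 12 high pairs.
3. **Bases** are indices with step-1 r ≥ 0.97 (⁰χ, ¹χ, ²χ, ⁰χᵛ), minus
   redundancy drops.
4. **Extension rule**: a candidate is accepted only if its two-descriptor
   r, at three decimals, exceeds both the base's r and the best
   single-index r by ≥ 0.001 (`min_delta_r`). This alone stops model 3
   (nothing beats 0.982).

Four decisions are genuinely expert judgments that the statistics cannot
produce — the step-2 table contains a 0.983 that is rejected for one base
and an equal 0.983 that is accepted for another — so they are explicit
entries of the default configuration, each application written to the
decision log: drop ⁰χ as structurally redundant with ²χ; stop model 1
(²χ) despite the marginal ⁴χ_pc gain; prefer ³χ_cᵛ over the tied ³χ_c
when extending model 2 (the valence index adds heteroatom information);
stop model 2 after two descriptors although a third reaches 0.984, the
same +0.001 margin that was accepted at step 2; and add the ¹χᵛ model 4
on interpretability grounds. With a stricter `min_delta_r` of 0.01 all
extensions are rejected and models 1–3 stay single-index.

## Synthetic-data generator

`random_molecule` grows a random tree under the degree-4 cap, optionally
closes one 5- or 6-ring, then assigns elements: N⁺ anywhere (valence 4),
O on positions of degree ≤ 2, carbon elsewhere, with hydrogens completing
the standard valence — every draw passes graph validation by
construction. Defaults (16–40 heavy atoms, 8% N⁺, 8% O, ring probability
0.15) mirror the size range and heteroatom density of the study set;
`synthetic_qspr` defaults (23 rows, response on ²χ with slope −0.18,
intercept −0.17, noise sd 0.1 log units) mirror its statistical shape.
Because descriptors are computed from actual graphs, the size indices
come out collinear at the 0.99 level, the regime the selection step must
survive. One seeded `numpy` generator drives all draws.

What the generator does **not** emulate: real homologous series
structure (tail/spacer families with shared head groups — available
separately via `homologous_series`), amide/ester functional groups,
measurement error correlated across a series, or any relation between
structure and *true* cmc beyond the imposed linear model. Passing
recovery tests therefore demonstrates correctness of the fitting and
screening machinery under the assumed model, not predictive validity for
new chemistry.

In the parameter-recovery check the slope is compared to truth within
three **true** standard errors σ/√Sxx, computable because the generator's
noise σ is known. With the estimated standard error the per-replicate
coverage is t₂₁-distributed (99.32% at 3 SE), which makes a "≥ 99% of 500
replicates" check fail by chance about one run in eight; with the true σ
the per-replicate probability is 99.73% and the check is stable. Observed
rates are 99.4–99.8% across seeds.

## Problem sizes and runtimes

The oracle-equivalence check uses 200 random molecules of 4–9 atoms (the
oracle's 12-edge limit); the recovery check uses one fixed set of 23
molecules and 500 noise replicates; the selection-consistency check draws
fresh 23-molecule datasets for 60 replicates. The full test suite runs in
under ten seconds and the acceptance script in about two.

## Known limitations

* SMILES support is a deliberate subset (C/N/O, brackets with charge and
  explicit H, branches, ring digits, aromatic lowercase); bond-order
  symbols, stereo, isotopes and other elements raise explicit errors.
* Structure fixtures are packaged only for the 12-6-12 dication
  (validated against the printed matrix) and the two test compounds
  (flagged `derived`; no printed reference values exist for them). The
  remaining training compounds enter as their printed descriptor rows,
  not re-derived from structures.
* The published single-descriptor model 1 example predictions run ~1–2%
  away from its printed equation applied to the printed matrix (e.g.
  0.401 vs 0.397 mM); the package reports the equation's value and does
  not attempt to reconcile the difference. Models 2–4 reproduce every
  quoted example to the last printed digit.
* No applicability-domain machinery beyond the descriptor ranges of the
  training set; extrapolating to very different architectures (nonionic,
  zwitterionic, bromide counterions) is outside the models' support.
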