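# sindex

Combined potency–effectiveness scoring for high-throughput drug screens.

In quantitative high-throughput screening (qHTS), compounds are usually ranked
by potency (AC50) or by the area under the concentration–response curve (AUC).
Both mislead when responses are partial: AC50 ignores how much of the signal a
compound can actually suppress, and AUC conflates potency and effectiveness
shifts. `sindex` implements a single-value index that combines both, aimed at
tumor-vs-reference cell-line panels — for example neurofibromatosis type 1
(NF1) screens comparing *NF1*−/− plexiform neurofibroma (PNF1) lines against an
*NF1*+/− non-tumor reference.

## The scores

From a 4-parameter logistic (4PL) fit of a concentration–response curve
(responses in % of DMSO control, concentrations in μM),

```
R(C)  = INF + (ZERO − INF) / (1 + 10^(h·(log10 C − log10 AC50)))
EFF   = ZERO − INF                      # effectiveness: asymptote span
S     = log10(EFF / AC50)               # combined potency + effectiveness
ΔS    = S_ref − S_test                  # unitless; < 0 sensitive, > 0 resistant
```

ΔS values across test lines are averaged into a **ΔS mean**, and compounds are
prioritized when

1. R² ≥ 0.8 in every required cell line (the reference is exempt when it shows
   no concentration–response),
2. |ΔS mean| > 0.5 (≈ 3-fold on an arithmetic scale), and
3. |ΔS mean| − √(variance of the mean) ≥ 0.3 (≈ 2-fold non-inferiority margin).

The potency-only analogue ΔpAC50 = −log10(AC50_ref/AC50_test) and the AUC
analogue ΔpAUC are computed alongside for endpoint comparison; group
differences of ΔS means (ΔΔS) support multi-control designs.

## Worked example

Generate a small synthetic screen (1 reference + 4 test lines), refit the
noisy raw curves, and prioritize:

```
$ sindex simulate --seed 7 --n-compounds 8 --out-dir demo
$ sindex fit --in demo/raw.csv --out demo/refit.csv
$ sindex prioritize --in demo/refit.csv --reference REF-01 --out-dir demo/hits
INFO sindex: prioritized 4/8 compounds

$ cat demo/hits/prioritized.csv
compound,target,ds_mean,ds_variance,ds_variance_of_mean,n_lines,verdict
CPD-0001,active,0.99,0.00,0.00,4,resistant_prioritized
CPD-0003,active,1.00,0.00,0.00,4,resistant_prioritized
CPD-0005,active,-1.05,0.00,0.00,4,sensitive_prioritized
CPD-0007,inert,0.66,0.09,0.02,4,resistant_prioritized
```

CPD-0001/0003 were generated with test-line AC50 shifted one decade up (true
ΔS = +1: resistant) and CPD-0005 one decade down (true ΔS = −1: sensitive);
the pipeline recovers their ΔS means within ±0.05 from noisy raw data and
calls the direction correctly. CPD-0007 is a false positive caused by an
ill-conditioned reference-line fit — see `docs/methods.md` for why the
variance filter cannot catch reference-side error. The truth sidecar
(`demo/truth.csv`) carries the generating parameters and true ΔS of every
record for exactly this kind of audit.

Screens in the deposited prefitted dialect (columns `LAC50`, `R2`, `TAUC`,
`INF`, `ZERO`) can be scored directly — `sindex score --in screen.csv
--reference ipnNF95.11C --out pairs.csv` — skipping the fitting step, and
`sindex compare-endpoints` emits the ΔS / ΔpAC50 / ΔpAUC rank-comparison and
correlation tables.

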