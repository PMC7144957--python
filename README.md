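# zipfnorm

Zipf-plot based normalization (ZN) for RNA-seq count profiles with
excessive zeros, together with simplified pairwise baseline normalizers
(TC, MED, UQ, TMM, RLE) and a coefficient-of-variation benchmarking
protocol.

## The problem

Bulk RNA-seq profiles from shallow or heterogeneous experiments can have
80–90% zero counts and a large mass of tiny counts. Classical linear
normalizers struggle there: the median is often zero, the upper quartile
sits among heavily tied small counts, and fold-change based factors (TMM,
RLE) are dominated by measurement error in the weak genes. The strongly
expressed genes, however, behave consistently: their expression
distribution has a power-law upper tail, and the Zipf plot — log rank
against log value of the distinct measures — is close to a straight line
with slope 1 − κ, where κ is the tail index.

ZN exploits exactly that global tail information. For a distinct value
*z<sub>i</sub>* of a profile *X* = {*X*₁, …, *X*ₙ}, the rank is

&nbsp;&nbsp;&nbsp;&nbsp;r<sub>i</sub> = Σ<sub>j</sub> **1**(X<sub>j</sub> ≥ z<sub>i</sub>),

and the upper tail is the set of Zipf-plot points with log r<sub>i</sub> < 6
(ranks up to ⌊e⁶⌋ = 403). A target profile *Y* is normalized against a
reference *X* as

&nbsp;&nbsp;&nbsp;&nbsp;Y′ = (Y / σ)<sup>γ</sup>

* **γ** (power-transform exponent) is the ratio of the two fitted tail
  slopes, slope(Y)/slope(X), which makes the transformed tail slope of
  *Y* match that of *X*; γ = 1 (the *linear scheme*) suffices whenever
  the Zipf plots are parallel.
* **log σ** (rescaling) is the horizontal shift between the two tails,
  estimated as the group coefficient in a pooled OLS of log value on log
  rank and a 0/1 profile indicator over the tail points of both profiles.
* Optionally the pair (σ, γ) is *refined* by a deterministic grid search
  minimizing the two-sample Kolmogorov–Smirnov distance
  D(σ, γ) = sup<sub>t</sub> |F̂<sub>x</sub>(t) − F̂<sub>y′</sub>(t)| between the positive
  values of the reference and the transformed target.

Because only ranks and tail positions enter the estimate, ZN needs no
assumption that most genes are non-DE and is insensitive to the zero mass.

## Worked example

Simulate three zero-inflated profiles whose tails follow a power law with
κ = 2.7, distorted by known factors σ = (1, 0.5, 2), then normalize them
against sample `s01` with the full scheme:

```bash
zipfnorm simulate --n-genes 20000 --n-samples 3 --zero-fraction 0.85 \
    --sigma 1.0,0.5,2.0 --rounding continuous --seed 42 --out demo
zipfnorm normalize --input demo/counts.tsv --reference s01 --scheme full --out demo_norm
```

which logs

```
INFO read 20000 genes x 3 samples from demo/counts.tsv
INFO removed 17028 all-zero genes; 2972 remain
INFO reference profile: s01
INFO sample s01: sigma=1 gamma=1
INFO sample s02: sigma=0.5 gamma=1
INFO sample s03: sigma=2 gamma=1
```

`demo_norm/params.tsv` holds the recovered parameters — the simulated
distortions σ = 0.5 and σ = 2.0 are recovered to ~13 significant digits
and γ stays at 1 because the tails are parallel:

```
sample_id  sigma                gamma               method   reference_id
s01        1.0                  1.0                 ZN-full  s01
s02        0.49999999999999023  0.999999999999999   ZN-full  s01
s03        1.9999999999999665   0.9999999999999996  ZN-full  s01
```

Dividing `s03` by its σ = 2 brings its Zipf plot onto the reference's.
The other subcommands follow the same pattern: `zipfnorm baseline`
computes the five pairwise baseline factors and a summary table (Min.,
quartiles, Mean, Max., SD, the fraction of factors below 1 — profiles
scaled *up* — and the fraction exactly 1), `zipfnorm refine` runs the KS
grid search for one pair and exports the D surface, and
`zipfnorm evaluate` benchmarks all methods by per-gene CV, 1000-gene
invariant sets and their agreement matrix.

The same functionality is available as a library:

```python
import zipfnorm as zn

matrix, truth = zn.generate(zn.SyntheticSpec(n_genes=50_000, n_samples=2,
                                             sigma_per_sample=[1.0, 2.0],
                                             rounding="continuous", seed=3))
ref = zn.ExpressionProfile("s01", matrix["s01"].to_numpy())
tgt = zn.ExpressionProfile("s02", matrix["s02"].to_numpy())
params = zn.normalize_pair(ref, tgt, scheme="full")   # sigma ~ 2.0, gamma ~ 1.0
```

## Scope notes

The TC/MED/UQ/TMM/RLE implementations are the simplified *pairwise*
formulations used for benchmarking here — a plain 30% symmetric trim of
M-values and an unweighted mean/median — not the canonical edgeR
`calcNormFactors` or DESeq size-factor estimators; do not expect numerical
parity with those tools. Gene-length corrections (RPKM/FPKM/TPM), quantile
normalization and DE testing are out of scope. See `docs/methods.md` for
the model, estimator and design details.
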