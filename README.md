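# splicekin

Bond-level RNA metabolism from 4sU metabolic-labeling time series
(TT-seq + RNA-seq).

## The problem

Short-read RNA-seq mixes precursor RNAs and every splice isoform
overlapping a position, which entangles synthesis, splicing and
degradation.  `splicekin` instead models the metabolism of three
individual phosphodiester bonds per intron:

* the **donor bond** between the last exonic and first intronic base
  (5′ splice site),
* the **acceptor bond** between the last intronic and first exonic base
  (3′ splice site),
* the **junction bond** between the two joined exons of the spliced
  product.

Reads spanning each bond are counted separately in every sample of a 4sU
labeling time series (TT-seq at 2, 5, 10, 15, 20, 30, 60 min plus total
RNA-seq, two replicates each).  Each bond *i* follows first-order kinetics

```
dc_i/dt = α_i − β_i c_i
```

with synthesis rate α (normalized counts·min⁻¹) and decay rate β
(min⁻¹), so the half-life is t½ = ln2/β.  During a pulse of length *t*
the labeled pool is (α/β)(1 − e^(−tβ)); a TT-seq sample captures it plus
a cross-contamination fraction χ of the unlabeled pool, giving expected
counts

```
E = F (α/β) (1 + e^(−tβ)(χ − 1))    TT-seq
E = F α/β                            RNA-seq
```

with per-sample depth factors F and χ estimated from labeled and
unlabeled spike-ins by a negative-binomial GLM, whose dispersion θ is
shared with the kinetic fits.  Donor/acceptor half-lives read out
splice-site cleavage kinetics; the junction half-life reads out the
stability of the mature RNA.  Derived quantities include the **splicing
yield** η = Σα_junction/α_acceptor (the fraction of precursor converted
to spliced product, deliberately not capped at 1) and Lasso models
linking splice-site sequence context to log half-life.

Refined kinetic models are provided for the two bonds where first-order
kinetics is a simplification: a **delay model** for donors (a lag τ for
transcribing the intron up to the branchpoint, then cleavage at rate λ)
and a **coupled model** for junctions (first-order splicing feeding a
product that decays at its own rate).

The package is aimed at people analysing TT-seq/4sU time series and at
method developers who need a fully synthetic, ground-truth-controlled
test bed: the `simulate` module reproduces the entire sample design,
spike-in behaviour and NB count noise, so every stage runs without any
sequencing data.

## Worked example

Simulate a 200-bond first-order data set under the 28-sample design,
estimate normalization factors from the simulated spike-ins, fit every
bond and compute yields:

```bash
cat > sim.yaml <<EOF
n_bonds: 200
model: first_order
seed: 11
alpha_range: [0.5, 50.0]
half_life_range: [2.0, 60.0]
EOF
splicekin run --config sim.yaml --out demo
```

On this configuration the pipeline prints/writes (abridged):

```
n bonds fitted: 188                  # 12 fell below the 100-read filter
fitted NB dispersion theta: 115.2    # spike-in GLM (true value 100)
median half-life: 10.8 min
median est/true decay rate: 0.997    # unbiased matched-model recovery
```

`demo/fit/rates.tsv` holds one row per bond (`alpha`, `beta`,
`half_life_min`, fit diagnostics); `demo/normalize/factors.tsv` the
per-sample F and χ; `demo/yield/yield.tsv` the per-site yields.

With real data the entry point is the `count` subcommand
(`splicekin count --bam sample.bam --gtf annotation.gtf --out counts/`),
which discovers introns from split reads (≥10 supporting fragments,
mapping quality 255, secondary alignments discarded), classifies them
against the annotation, and emits the three bond counts per intron; the
downstream stages are identical.

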