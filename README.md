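# dnmosaic

Genome-wide analysis of postzygotic hypermutation in a sequenced
parent–offspring trio. Given trio variant calls, `dnmosaic` selects
candidate de novo SNVs/indels through an audited filter cascade, classifies
each candidate's mitotic timing from its variant allele fraction (VAF),
groups the substitutions into single/doublet/clustered/biallelic events
with transition–transversion accounting, and refits trinucleotide
mutational signatures by non-negative least squares with backwards
elimination. A seeded synthetic-trio generator provides datasets with fully
known truth, so every stage is testable without any external download.

It is written for researchers studying mosaicism and hypermutator
phenotypes (for example in DNA-repair disorders such as Fanconi anemia,
where defective homologous-recombination repair can flood the early embryo
with postzygotic mutations) who want a reproducible, scriptable version of
this analysis.

## The model

A constitutional heterozygous variant is expected at VAF 0.5. A variant
arising at the k-th postzygotic mitosis is carried by a 2^-k fraction of
cells, so its expected VAF is 2^-(k+1): 0.25 for the first division, 0.125
for the second, 0.0625 for the third. With read depth n, the observed VAF
of a variant with true fraction p is spread as X/n with
X ~ Binomial(n, p), so adjacent components overlap and the natural
boundary between two components is where their densities cross.

`dnmosaic` models each component with the continuous extension of the
binomial distribution, whose CDF on support x ∈ [0, n+1] is the
regularized incomplete beta function

    F(x) = I_{1-p}(n + 1 − x, x),

which interpolates the discrete binomial CDF at integer points. Boundaries
are estimated the Monte-Carlo way — 10,000 draws per component, Gaussian
KDEs with a pooled Silverman bandwidth, crossing point on a common grid —
with an exact dense-grid analytic crossing available as an oracle. The
published bins (second mitosis 9.55–18.69%, first mitosis 18.7–37.41%,
germline 37.41–62.59%) are available as a preset.

Candidate filtering keeps a variant/alt pair only if: depth ≥ 20 in all
three samples, ≥ 2 alternate reads in the proband, zero alternate reads and
homozygous-reference genotypes in both parents, VAF ≤ 0.70, key absent from
a population blacklist and from segmental-duplication/centromere/repeat
regions, and GATK-style hard-filter annotations within class-specific
thresholds (SNV: MQ > 30, ReadPosRankSum > −8, FS < 60, QD > 2; indel:
ReadPosRankSum > −20, FS < 200, QD > 2).

Signature refitting minimizes ‖M·c − v‖ subject to c ≥ 0, where v is the
96-context count vector and M the catalog matrix; the lowest-contribution
signature is iteratively removed while the reconstruction cosine stays
within a tolerance of the full-catalog fit.

## Worked example

```python
import numpy as np
from dnmosaic import TimingModel, estimate_boundaries, analytic_boundaries, \
    sample_vafs, timing_table

model = estimate_boundaries(TimingModel(depth=50, n_draws=10_000, seed=7))
print([round(b, 4) for b in model.boundaries])
# [0.3792, 0.1917, 0.099]          # Monte-Carlo crossings at depth 50
print([round(b, 4) for b in analytic_boundaries(model)])
# [0.379, 0.1918, 0.1003]          # exact dense-grid crossings

rng = np.random.default_rng(7)
vafs = np.concatenate([sample_vafs(446, 0.25, 50, rng),
                       sample_vafs(384, 0.125, 50, rng)])
print(timing_table([(v, "SNV") for v in vafs]).to_string(index=False))
#            bin       vaf_range  snv  indel  total
# second-mitosis  9.55% - 18.69%  343      0    343
#  first-mitosis  18.7% - 37.41%  392      0    392
#       germline 37.41% - 62.59%   10      0     10
#  sub-threshold         < 9.55%   85      0     85
# above-germline        > 62.59%    0      0      0
```

The Monte-Carlo boundaries track the analytic crossings to ~0.002 on the
VAF axis, and the simulated first/second-mitosis components land in their
bins with the expected binomial-tail spill into the neighbouring bins.

The scripts in `examples/` each demonstrate one capability end to end
(simulate + filter, timing bins, substitution patterns, signature refit)
and print what the numbers mean. A thin CLI is also available:

```bash
dnmosaic simulate --seed 1 --out sim/
dnmosaic run --config run.yaml --out results/
```

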