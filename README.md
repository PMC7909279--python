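# mitophase

Continuous statistical phasing of forensic mitochondrial DNA mixtures.

A mixed mtDNA sample — touch DNA, hair shafts, multi-donor stains — contains
one complete haploid mitotype per contributor, in unknown proportions.
Massively parallel sequencing reports quantitative per-site allele counts,
but reads are short relative to the mitogenome, so the contributors'
full-length haplotypes cannot be read off directly.  `mitophase` deconvolves
such mixtures: it estimates the number of contributors, their proportions,
and their complete rCRS-relative mitotypes, for analysts who need individual
haplotypes (not just haplogroups) from two-person (up to five) mixtures.

## Model

Given per-site reference/alternative read counts, K contributors with
proportions `w` (softmax of Gaussian titres) and binary haplotypes
`h_k`, the alternative count at site *j* is

    a_j ~ Binomial(n_j, q_j(1-e) + (1-q_j)e),      q_j = Σ_k w_k h_kj

with read-error rate *e*.  Each haplotype is a single-donor copy of a
reference-panel member under the Li–Stephens model with recombination fixed
at 0 (mtDNA does not recombine) and per-site mis-copying rate *μ*, so
estimated mitotypes may deviate from every panel sequence.  Inference is
MCMC: Metropolis–Hastings on the titres and exact block-Gibbs draws of
(donor, haplotype) — jointly for strain pairs, which keeps heterozygous-site
assignments mixing even at near-equal proportions.  Panels are built by
filtering a haplotype database to the 25 candidates nearest the mixture in
*graph edit distance* (allele changes needed for compatibility with the
observed genotypes).  For imbalanced mixtures, an accurately phased major
determines the minor by interpolation: complement at heterozygous sites,
copy at homozygous sites.

Accuracy is scored by paired Hamming distance
`min(d(A,a)+d(B,b), d(A,b)+d(B,a))` between true (A, B) and estimated
(a, b) haplotypes; *deconvolution accuracy* is the percentage of mixtures
in which that total is zero.

## Worked example

Generate a synthetic haplogroup-structured database (a stand-in for a
population mitogenome panel), mix two of its members 4:1 at 100× depth,
build an edit-distance panel, and deconvolve:

```python
import mitophase as mp
from mitophase import empop

records = empop.read_empop("db.empop")            # 32 synthetic haplotypes
loci, haps = empop.build_site_universe(records)   # 288 bi-allelic SNPs
major, minor = haps[0], haps[12]                  # pairwise distance 50

truth = mp.make_truth(mp.MixtureSpec(major, minor, (4, 1), 100), loci)
panel = mp.build_edit_distance_panel(haps, truth.counts, mp.PanelConfig(4, 25))
result = mp.run_mcmc(truth.counts, panel, mp.EngineConfig(seed=3))

rec = mp.paired_distance(
    (truth.true_major, truth.true_minor),
    (mp.Haplotype("est_major", result.haplotypes[0]),
     mp.Haplotype("est_minor", result.haplotypes[1])),
)
```

Output:

```
panel size 4
proportions [0.806, 0.194]
total paired Hamming distance 0 | major correct: True | minor correct: True
interpolated minor == truth: True
geweke z 0.81 converged True acceptance 0.30
```

The posterior proportions (0.806/0.194) recover the 4:1 ratio — the slight
shrinkage from 0.8/0.2 is the read-error fold-in — and both 288-site
mitotypes are reconstructed exactly (total paired Hamming distance 0).
The convergence statistic near 0 corresponds to a stationary
("fuzzy caterpillar") log-posterior trace.

The same steps are available as a CLI:

```
mitophase syndata --haplogroups 8 --samples-per-group 4 --seed 7 --out db.empop
mitophase simulate --db db.empop --ratios 4:1 --depth 100 --out mixtures/
mitophase panel --db db.empop --counts mix.counts.tsv --edit-distance 4 --out panel.empop
mitophase deconvolve --counts mix.counts.tsv --panel panel.empop --seed 3 --out result.json
mitophase interpolate --result result.json --counts mix.counts.tsv --out minor.empop
mitophase evaluate --truth truth.json --result result.json --out record.json
mitophase grid --db db.empop --seed 1 --out grid.tsv
mitophase report --results grid.tsv --out report/
mitophase stats prop-test --x1 19 --n1 45 --x2 9 --n2 45
```

## Layout

| module | contents |
|---|---|
| `mitophase.empop` | EMPOP-dialect parsing/writing, bi-allelic site universe, genotype classes, count-table TSV I/O |
| `mitophase.mixtures` | exact in silico mixtures, pair enumeration |
| `mitophase.panels` | edit-distance panel filter, four experimental panel designs, private-site error report |
| `mitophase.engine` | the MCMC deconvolution engine |
| `mitophase.interpolate` | minor-contributor interpolation, phasing-error taxonomy |
| `mitophase.metrics` | paired Hamming metrics, deconvolution accuracy, proportion fit |
| `mitophase.stats` | equality-of-proportions test, variance-ratio F test, two-predictor OLS |
| `mitophase.syndata` | synthetic haplogroup-structured database generator |
| `mitophase.pipeline` | grid orchestration, study runners, reports |
| `mitophase.cli` | `mitophase` command-line verbs |

See `docs/methods.md` for the model, sampling scheme, parameter defaults
and known limitations.
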