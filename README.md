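# indelpop

Population genomics of large (≥ 1 kb) indel structural variants segregating
among inbred lines, from discordant paired-end alignments.

Resequencing a panel of fully homozygous inbred lines against one line's
reference assembly exposes large deletions as read pairs that map in the
expected (→←) orientation but with an implausibly long insert, and as
intervals of near-zero read depth in carrier lines. `indelpop` implements
the complete analysis around that signal for researchers studying standing
structural variation in natural populations:

* **SV calling** — classify read pairs as discordant (wrong orientation,
  insert span ≥ 1,000 bp, or split across sequences; both mapping
  qualities ≥ 29), pool them across accessions, single-linkage cluster
  pairs whose left and right anchors each start within 225 bp, and keep
  clusters with ≥ 3 supporting pairs.
* **Filter cascade** — drop candidates supported by the reference
  accession itself, smaller than 1 kb, without carrier read depth in the
  lowest 10th percentile (deletions), outside the 10th–90th depth band
  (inversions/transpositions), or sitting in 5 kb windows whose discordant
  read count exceeds the genome-wide 90th percentile.
* **SNP calling** — pileup-style homozygous base calls (3× ≤ depth ≤ 25×,
  strict > 75 % read majority), population SNPs at sites callable in all
  focal lines, with synonymous/nonsynonymous annotation from the longest
  transcript's frame.
* **Null models** — a Kingman-coalescent simulator conditioned on a fixed
  number of segregating sites *S* (the envelope design: *n* = 10, *S* =
  100, 10,000 replicates), and a Monte-Carlo estimate of the allele
  frequency error from observing only ten lines.
* **Frequency-spectrum statistics** — folded/unfolded SFS, Tajima's

  D = (π − S/a₁) / √(e₁S + e₂S(S−1)),

  and the normalized Fay & Wu's H = (π − θ_L)/√Var(π − θ_L) with the
  Zeng et al. variance, polarized through outgroup lines.
* **Selection strength** — intra-allelic diversity π_A on 500 bp
  haplotypes around each variant, converted to mean allele age T = π_A /
  π̄_A(synonymous) in units of 2N_e generations, then inverted through
  the diffusion expectation of allele age under additive selection to an
  estimate of |N_e s| (age is symmetric in the sign of s).
* **Selection scan** — joint Tajima's-D / normalized-H outliers in 10 kb
  windows around polarized indels, flagged when both statistics fall
  below the neutral envelope's lower 95 % bound.
* **Synthetic data** — a first-class generator of populations with
  planted deletions, SNPs, gene/TE annotation and per-line alignment
  records (insert 275.8 ± 28.8 bp, 2 × 75 reads) with chimeric-pair and
  mapping-quality noise, so the whole pipeline is testable against known
  truth.

## Worked example

Run the full synthetic study on a 1 Mb genome with ten planted deletions:

```python
from indelpop.pipeline import PipelineConfig, run_all
from indelpop.synthetic_data import SimConfig

cfg = PipelineConfig(
    sim=SimConfig(seed=1, genome_length=1_000_000, deletion_count=10,
                  deletion_size_range=(1000, 20_000), n_genes=60, n_tes=200),
    envelope_reps=2000)
report = run_all(cfg)
```

The report (abridged) reads:

```
callsv:     1,894 pooled discordant pairs -> 10 deletion candidates
filtersv:   input 10, retained 10, dropped 0
evaluation: precision 1.00, recall 1.00
popgen:     indel mean MAF 0.240, folded SFS [3, 3, 2, 1, 1],
            minor-derived fraction 0.90
callsnp:    8,562 SNPs callable in all ten lines
envelope:   D in (-1.70, +1.73), H in (-2.06, +5.49), mean MAF 0.225
maf error:  0.0963
```

Every planted deletion was recovered exactly (precision = recall = 1.0);
the ~0.24 mean minor-allele frequency of the planted indels sits near the
neutral fixed-S expectation of 0.225, and the Monte-Carlo sampling error
says a frequency estimated from ten lines is off by ±0.096 on average.

The allele-age arithmetic is a two-liner:

```python
from indelpop.popgen_stats import allele_age, nes_from_age

T = allele_age(0.0031, 0.0087)   # 0.36 coalescent time units (2Ne gen.)
nes_from_age(T, 0.2)             # |NeS| ~ 5.39  (strong selection)
nes_from_age(0.63, 0.2)          # |NeS| ~ 1.95  (weak selection)
```

The same stages are exposed as a CLI
(`indelpop simulate | callsv | filtersv | callsnp | nullsim | popgen |
overlap | scan | run-all | report`), e.g.

```bash
indelpop simulate --seed 2 --out data/
indelpop callsv --pairs data/ --out calls.tsv
indelpop nullsim envelope --reps 10000 --seed 1 --out envelope.json
```

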