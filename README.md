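# episub

Automated identification and characterization of linear antibody epitopes
from peptide-microarray single-amino-acid substitution data.

Given a target antigen (FASTA) and a quantitative peptide table containing
overlapping native peptides plus their single-substitution derivatives,
`episub`:

1. **maps** every measured peptide onto the antigen (native window,
   single-substitution variant, ambiguous, or unmapped);
2. **rescales** variant intensities into substitution values relative to the
   median intensity of the native copies (1 = no effect, < 1 loss of
   binding, > 1 heteroclitic gain);
3. **calls epitope positions per peptide** by arranging substitution values
   into a position-specific scoring matrix and testing each position's mean
   signal loss against a one-tailed Dunnett many-to-one least-significant
   difference (`1 - mu_i > t_d * sqrt(S^2 / n_i)`);
4. **profiles per-residue selectivity** by pooling substitution values of
   one protein residue across overlapping peptides, testing each replacing
   amino acid against the matrix's global mean with the Dunnett CDF, and
   emitting signed `-sign(t) * log10(p)` logo scores rescaled so that the
   absolute column height equals the mean substitution effect `1 - mu_g`;
5. **groups selective residues** into gap-tolerant epitope regions
   (at least 4 selective residues, internal gaps of at most 2).

The one-tailed (noncentral) Dunnett max-t distribution — CDF, quantile and
a seeded Monte-Carlo reference oracle — is implemented from scratch with
nested Gauss–Legendre quadrature (`episub.dunnett`) and exposed as a public
API. Single-substitution (alanine-scan) designs are detected automatically:
the per-peptide sliding table is not produced (the pooled variance is
undefined there), and the residue-level test condenses to a two-sample
Student's t-test.

A synthetic-data generator (`episub.synthetic`) emulates the tiled array
design (L-mer windows at step 1, R native copies, exhaustive or
alanine-only substitutions, planted epitopes with tolerated-amino-acid
sets, heteroclitic effects, multiplicative log-normal noise) with full
per-row ground truth, so the entire pipeline is testable offline.

## CLI

```bash
# analysis: FASTA + peptide table (TSV/CSV with columns peptide, intensity[, replicate_id])
episub analyze --fasta antigen.fasta --peptides data.tsv --out results/ \
    --alpha 0.0001 --length 15

# synthetic data with planted ground truth
episub simulate --config sim.yaml --seed 7 --out simdata/
```

`analyze` writes to the output directory:

| file                | contents                                                        |
|---------------------|-----------------------------------------------------------------|
| `peptide_calls.tsv` | per native peptide: position, sequence, dashed epitope string, median native intensity |
| `selectivity.tsv`   | per residue: global mean, per-amino-acid p-values and logo scores |
| `logo_matrix.tsv`   | 20-column logo score matrix (blank rows at non-selective positions) |
| `regions.tsv`       | epitope regions as `start-end` ranges with dashed region strings |
| `native_qc.tsv`     | native copy counts, medians, bootstrap SE of the median          |
| `run_log.txt`       | parameter echo and mapping/drop counters                         |

Useful options: `--inclusion-mode {position,peptide,all}` (which overlapping
peptides feed a residue's substitution matrix), `--min-region-length`,
`--max-gap`, `--floor` (intensity floor for the native reference),
`--min-native-intensity`, `--plots` (render logo PNGs natively).

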