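# repseq-subsets

Repertoire-level analysis of TCR clonotype tables across T-cell subsets:
CDR3 middle-region physicochemical scoring, depth normalization, diversity
estimation, clonal overlap and sharing networks, cross-donor publicity, and
a group-versus-mean statistical layer with PCA — plus a synthetic cohort
generator with planted, recoverable structure for end-to-end testing.

## What it does

* **I/O** (`repseq_subsets.io`) — read/write clonotype tables in a
  VDJtools-style dialect (`count freq cdr3nt cdr3aa v d j VEnd DStart DEnd
  JStart`) and AIRR Rearrangement TSV; validation of repertoire invariants.
* **Normalization** (`normalization`) — seeded downsampling to a fixed
  number of UMI-labeled molecules (multivariate hypergeometric, default
  16,000) and top-N truncation by clonotype frequency (default 20,000).
* **CDR3 features** (`features`) — physicochemical scales (10 Kidera
  factors, interaction strength, contact-energy, interface propensities,
  volume, charge, hydropathy, …) averaged over the five middle residues of
  the CDR3 loop; junction N-insertion statistics from V/D/J markers; the
  28-parameter frequency-weighted feature vector per cloneset.
* **Diversity** (`diversity`) — observed richness, bias-corrected Chao1,
  and the normalized Shannon-Wiener index.
* **Overlap** (`overlap`) — pairwise F2 (frequency-weighted, Σ√(fₐ·f_b))
  and relative D (shared / Sₐ·S_b) metrics on nucleotide-defined
  clonotypes, and sharing-network node/edge tables on top-2,000 clonesets.
* **Publicity** (`publicity`) — cross-donor sharing of amino-acid-defined
  CDR3 variants at Hamming distance ≤ 1, via wildcard-mask hashing.
* **Statistics** (`stats`) — mean/SD summaries, omnibus ANOVA or
  Kruskal-Wallis with a Shapiro-Wilk gate, per-group Welch (or Wilcoxon)
  tests versus the pooled distribution with Bonferroni correction,
  Benjamini-Hochberg FDR, and correlation PCA with deterministic signs.
* **Synthetic cohorts** (`synth`) — multi-donor, multi-subset generator
  with heavy-tailed clone sizes, tunable per-subset physicochemical bias
  (exponential tilting of middle-5 residue weights), Poisson junction
  inserts, planted between-subset sharing and cross-donor public
  clonotypes, all recorded in a ground-truth ledger.
* **Pipeline** (`pipeline`, `cli`) — one command running every stage over
  a sample sheet and emitting seven TSV reports with parameter headers.

## CLI

```sh
# simulate a cohort (tables + samples.tsv + ground-truth ledger.tsv)
repseq-subsets simulate --out sim/ --seed 1

# full pipeline: features, diversity, overlap, network, publicity, PCA, stats
repseq-subsets run --sample-sheet sim/samples.tsv --out reports/ --seed 1

# individual stages
repseq-subsets downsample --n 16000 --seed 1 in.tsv out.tsv
repseq-subsets topn --n 20000 in.tsv out.tsv
repseq-subsets diversity --n 16000 in.tsv
repseq-subsets features samples.tsv --weighted --out features.tsv
repseq-subsets publicity samples.tsv --topn 20000 --subset Treg
repseq-subsets stats features.tsv --metric kf4
repseq-subsets pca features.tsv
```

The sample sheet is a TSV with columns `donor`, `subset`, `chain`, `path`
(paths relative to the sheet). Input tables may be `--dialect vdjtools`
(default) or `--dialect airr`.

## Tests

```sh
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the acceptance criteria (oracle
equivalences, closed-form identities, Monte-Carlo calibrations, planted
parameter recovery, end-to-end runs); the remaining files are per-module
unit and property tests.

## Amino-acid property table

`src/repseq_subsets/data/aa_properties.tsv` ships 23 named scales for the
20 standard amino acids; the comment header records the published source
of every scale (Kidera factors, Kyte–Doolittle hydropathy, Zamyatnin
volumes, Grantham polarity, Chou–Fasman propensities, TOP-IDP disorder,
and transfer/hydrophilicity scales standing in for the interface
propensities). Swap in a custom table via `features.PropertyTable` if you
need different scale definitions.
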