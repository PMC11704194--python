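# protegrate

Proteogenomic integration of tumor multi-omics data: from copy-number
segments, somatic mutation tables and label-free peptide/protein/
phosphosite abundance matrices to cis/trans-effect ledgers, pathway and
kinase activity scores, consensus molecular subtypes and survival
associations.

Proteogenomic cohort studies ask how DNA-level lesions propagate
through the molecular layers of a tumor: does a copy-number loss on an
arm depress its genes' mRNA and protein (*cis* effects)? Do proteomic
profiles partition patients into subtypes with different outcomes?
Which kinases drive the phosphorylation programs of each subtype?
The primary data behind such studies are controlled-access, so
`protegrate` pairs every analysis stage with a synthetic cohort
generator that plants known structure — arm losses, focal gains,
dosage-coupled cis genes, cluster-specific expression programs,
kinase-driven substrate shifts, mutational-signature mixtures and
hazard differences — making the whole pipeline testable end to end.

## Methods at a glance

- **Copy number.** Gene-level copy number is the length-weighted mean
  segment log2 ratio over the gene body; arm scores are the
  length-weighted mean over the arm,
  `score = Σ len_i·r_i / Σ len_i`. Amplification/deletion calls use a
  log2-ratio cutoff of 1 (inclusive).
- **Mutations.** TMB = coding mutations (synonymous included) per Mb;
  96-trinucleotide-context matrices (pyrimidine-collapsed) are
  factorized by multiplicative-update NMF and matched to reference
  signatures by cosine similarity; co-occurrence/mutual exclusivity by
  two-sided Fisher exact tests.
- **Quantification.** iBAQ = summed peptide intensity / number of
  theoretically observable tryptic peptides (length 7–30); FOT =
  iBAQ / sample total × 10⁶, then missing values imputed with 10⁻⁵
  under a mask. Phosphosites are kept at localization probability
  > 0.75.
- **cis/trans ledger.** Spearman correlation of gene-level CNV with
  mRNA / protein / phosphoprotein abundance, BH-adjusted per layer;
  cis = same gene.
- **Activity scores.** ssGSEA (weighted ECDF difference, `α = 0.25`)
  for pathways, TF regulons, immune/stromal and cell-type signatures;
  MGPS = mean z-scored expression of cell-cycle genes; KSEA kinase
  z-score `z = (s̄ − p̄)·√m / δ` over a kinase's m substrate sites.
- **Subtyping.** Consensus clustering: resampled PAM (k-medoids) on
  1 − Spearman correlation between sample profiles, top-50% most
  variable features, `pItem = 0.8`; model selection by consensus-CDF
  delta area and silhouette.
- **Survival.** Kaplan–Meier + log-rank, Cox PH (Efron ties,
  coefficient = ln HR), and maximally selected rank statistics for
  optimal marker cutpoints with an optional permutation-adjusted p.

## Worked example

Run the full pipeline on the default synthetic cohort (200 samples,
2000 genes):

```bash
protegrate run --seed 7 --out demo_run
```

which prints (abridged):

```json
{
  "tmb_mean": 9.94,
  "signature_matches": {"Sig1": "SynSigA", "Sig2": "SynSigB"},
  "cis_region_counts": {
    "mrna": 101, "protein": 91, "phospho": 9,
    "mrna&protein": 5, "mrna&protein&phospho": 20
  },
  "chosen_k": 3,
  "silhouette": {"2": 0.81, "3": 0.95, "4": 0.69, "5": 0.70},
  "cluster_logrank_p": 2.9e-06
}
```

Reading the numbers: mean tumor mutational burden is ~10 mutations/Mb
(the generator draws Poisson(316) mutations over a 31.6 Mb coding
region); the two extracted mutational signatures are matched to the
correct references; the 20 genes planted with copy-number dosage
coupling appear in the triple mRNA ∩ protein ∩ phosphoprotein cis
intersection (the layer-exclusive counts are the expected false
positives of a raw p < 0.05 screen over 2000 genes); consensus
clustering picks k = 3 — the number of planted proteomic programs —
with the silhouette peaking there; and the log-rank test detects the
hazard increase planted in cluster C3.

Individual stages are available as subcommands
(`protegrate simulate|cnv|signatures|quant|cistrans|score|ksea|cluster|survival|diffexp`)
and as plain library functions under `protegrate.*`.

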