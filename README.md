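# cnahet

Intermetastatic DNA copy-number heterogeneity analysis for multi-lesion
tumor cohorts, built for the setting of resected colorectal liver
metastases (CRLM) profiled lesion-by-lesion with SNP arrays.

When several metastases from one patient are segmented independently
(e.g. by ASCAT), the profiles cannot be compared position-wise until
they share a region grid. `cnahet` harmonizes the per-lesion
segmentations, calls aberrations, and quantifies how divergent a
patient's metastases are — then carries those scores into mutation
grouping and cancer-specific survival analysis.

## What it computes

* **Harmonization** — segments from all lesions are split at the union
  of breakpoints into the *smallest regions of overlap*, giving a
  region × lesion copy-number matrix.
* **Gain/loss calls** — per lesion, a region is a gain (loss) when its
  copy number is ≥ 1 copy above (≤ −1 below) the lesion's median
  genome-wide copy number (length-weighted median of segment values).
* **CNA burden** — percent of covered base pairs with a non-neutral
  call; patient-level burden is the mean over lesions ("fraction of
  the genome altered").
* **Intermetastatic heterogeneity**, four estimators per patient:
  mean pairwise Euclidean distance between lesion profiles; mean
  pairwise Pearson correlation distance (1 − r); the fraction of
  aberrant genes whose ternary call is not shared by all lesions; and
  a variance-filtered Euclidean variant (regions with across-lesion
  variance ≤ 0.03 dropped). Scores are dichotomized at the cohort
  median (strictly above ⇒ "high").
* **High-level amplifications** — regions with ≥ 15 *additional
  copies* (copy number minus lesion ploidy) in any lesion; adjacent
  qualifying regions merge into events, which are classified
  `homogeneous` (all lesions ≥ 15), `intermediate_concordant` (all
  ≥ 5) or `heterogeneous`, and annotated with cancer-critical genes.
* **Mutation groups** — KRAS/NRAS/BRAF V600E/TP53 lesion calls
  aggregated to patient level (any mutated lesion ⇒ mutated), then
  classified into co-mutation strata (RAS/BRAF + TP53 co-mutation,
  either alone, double wild-type).
* **Survival** — 5-year cancer-specific survival with other-cause
  deaths censored; eligibility restricted to MSS tumors with R0/R1
  resection; Kaplan–Meier, two-group log-rank, a 1-df log-rank trend
  test for ≥ 3 ordered strata, and Cox regression (Efron ties).
* **Synthetic cohorts** — a generator producing multi-lesion profiles
  from truncal and lesion-private events on a CRC-weighted arm prior,
  injected amplifications, mutually exclusive driver mutations at
  CRC prevalences, and exponential survival under stratum-specific
  hazards, together with a ground-truth record for recovery tests.

## Worked example

The bundled `table1` fixture contains six flat-diploid patients
carrying fifteen amplification events whose per-lesion additional
copies span published-style ranges:

```python
from cnahet.synthetic import make_fixture
from cnahet.harmonize import harmonize
from cnahet.amplification import detect_amplifications, annotate_cancer_genes

cohort = make_fixture("table1")
matrix = harmonize(cohort.profiles)
for ev in detect_amplifications(matrix.subset_patient("T2")):
    ev = annotate_cancer_genes(ev, cohort.genes)
    lo, hi = ev.copy_range
    print(f"chr{ev.chromosome}:{ev.start+1}-{ev.end}  {','.join(ev.genes):12s} "
          f"+{lo:.0f} to +{hi:.0f} copies  ->  {ev.concordance_class}")
```

prints

```
chr1:65183880-66527443  JAK1         +10 to +15 copies  ->  intermediate_concordant
chr7:54576560-56118007  EGFR         +37 to +58 copies  ->  homogeneous
chr7:90792390-92573683  AKAP9,CDK6   +0 to +22 copies  ->  heterogeneous
chr18:41497284-42716881  SETBP1       +18 to +20 copies  ->  homogeneous
```

i.e. this patient's EGFR amplification is high-level in every lesion
(homogeneous), the JAK1 event reaches high level in one lesion with
≥ 5 additional copies everywhere else, and the AKAP9/CDK6 event is
absent from at least one lesion (heterogeneous).

The same flow runs from the shell:

```sh
cnahet simulate --n-patients 64 --seed 7 --out cohort/
cnahet run --segments cohort/segments.seg --patients cohort/patients.tsv \
           --genes cohort/genes.bed --out results/
```

which writes the region/call matrices, burden, heterogeneity,
amplification, mutation-group and survival tables plus a
`manifest.json` recording thresholds, the config hash, and the nested
analysis denominators (all patients → multi-lesion patients →
MSS + R0/R1 patients).

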