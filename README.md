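# repsig

Paired tumor / non-tumor immune-repertoire (TCR/BCR) signature analysis.

Bulk AIRR-seq studies of solid tumors compare the T- and B-cell receptor
repertoires of tumor tissue against adjacent non-tumor tissue from the same
patients, asking whether diversity, clonal expansion, somatic hypermutation
(SHM) or repertoire overlap track disease stage, recurrence and survival.
`repsig` implements that analysis as a tested, reusable pipeline for
clonotype tables (AIRR Rearrangement TSV or MiXCR-style exports) across the
TCR chains TRA/TRB/TRG/TRD and the BCR heavy chain (IgA/IgG/IgM isotypes):

* **QC** — productive-clonotype filtering: CDR3aa length ≥ 4, CDR3nt length
  a multiple of 3, no stop codon.
* **Diversity** — richness *S*, Shannon entropy *H*, and evenness
  NSDE = *H* / ln *S* (normalized Shannon diversity entropy), at both the
  CDR3 amino-acid and V-D-J gene-combination level.
* **Similarity** — Morisita–Horn index of each tumor/non-tumor pair,
  MHSI = 2 Σxᵢyᵢ / ((Σxᵢ²/X² + Σyᵢ²/Y²)·XY) ∈ [0, 1].
* **BCR SHM networks** — mutated clones (≥ 1 V-region mismatch to germline)
  as nodes, clonal-lineage edges (same V/J, equal CDR3aa length, Hamming
  distance ≤ 1); average degree 2E/N and the EXd1 variant that first drops
  all degree-1 nodes.
* **Gene usage** — per-sample V/J/VDJ frequency matrices with PCA and
  classical MDS ordination.
* **Cohort statistics** — exact/corrected Wilcoxon signed-rank and
  Mann–Whitney tests, Spearman correlation, Fisher/χ² for categorical
  tables, frequency summaries, optional Benjamini–Hochberg q-values.
* **Survival** — median-split Kaplan–Meier curves and log-rank tests for
  PFS/RFS/OS against any repertoire feature.
* **Synthetic cohorts** — a fully deterministic generator of paired
  repertoires (Zipf clone abundances, tunable sharing, star-shaped SHM
  lineages, censored survival with an injected hazard ratio) so the whole
  pipeline is testable without controlled-access patient data.

## Worked example

```python
import repsig as r

config = r.SimulationConfig(n_patients=4, chains=("TRB", "IGH"),
                            clones_per_sample=300, seed=42)

tumor, non_tumor, truth = r.simulate_pair(config, "P001", "IGH")
tumor = r.simulate_shm(config, tumor)
non_tumor = r.simulate_shm(config, non_tumor)
tumor.clonotypes = r.filter_productive(tumor.clonotypes)
non_tumor.clonotypes = r.filter_productive(non_tumor.clonotypes)

for s in (tumor, non_tumor):
    d = r.diversity(r.collapse(s, "CDR3aa"))
    print(s.tissue, d.richness, round(d.shannon, 3), round(d.nsde, 3))

mh = r.morisita_horn(r.collapse(tumor, "CDR3aa"), r.collapse(non_tumor, "CDR3aa"))
print("mhsi", round(mh.mhsi, 4), "shared", mh.n_shared_labels)

st = r.shm_percentages(tumor)
print("mutated%", round(st.mutated_pct, 1), "avg_degree", round(st.avg_degree, 3))
```

prints

```
tumor 466 4.235 0.689
non_tumor 456 4.717 0.77
mhsi 0.0109 shared 60
mutated% 66.7 avg_degree 1.068
```

The tumor repertoire is more clonal (lower evenness, 0.689 vs 0.770): the
generator draws tumor abundances with a steeper power law. The pair shares
60 of ~460 clonotypes but almost none of its abundance mass (MHSI 0.011),
the weak-overlap regime typical of paired tissues. Two-thirds of IgH clones
are somatically mutated, and each mutated clone sits in a lineage network
with ~1.07 connections on average.

## Command line

```sh
repsig simulate --out data/ --patients 8 --clones 300 --chains TRB,IGH --seed 1
repsig run --input-dir data/ --clinical data/clinical.csv --out results/ --seed 1
repsig diversity --input-dir data/ --out diversity.tsv
repsig shm --input-dir data/ --out shm.tsv --edge-aa-dist 1
repsig survival --features results/features.tsv --clinical data/clinical.csv \
    --feature IGH_CDR3aa_nsde_tumor --endpoint OS --out km.tsv
```

`repsig run` writes tidy TSVs (diversity, similarity, SHM, test results,
survival curves) plus a run manifest with the config hash and per-stage row
counts; identical configs reproduce byte-identical outputs.

## Acceptance script

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

runs the full pipeline end to end on a freshly simulated 8-patient,
two-chain cohort (simulate → filter → metrics → SHM → cohort statistics →
survival) and writes the results JSON after verifying every stage completed.
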