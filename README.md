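# chemscreen

Chemical-distance virtual screening for ligand-scarce natural-product
families, with a systems-pharmacology read-out.

## The problem

When only a handful of compounds in a family (here the motivating case is
ginsenosides, the triterpenoid saponins of *Panax* species, screened for
anti-photoaging activity) have reported bioactivity, there is too little
data to train a QSAR model and too little structural diversity for docking
to discriminate. This package implements a geometric alternative: the known
actives define a region of a descriptor-derived chemical space, and unknown
family members are ranked by how close they sit to it.

The screening funnel is:

1. **Standardize** structures (largest fragment, charge normalization,
   stereo preserved) and deduplicate by InChIKey.
2. **Chemical space** — z-score the 2D descriptor matrix, project with PCA,
   keep candidates inside the known actives' bounding box on PC1–PC3.
3. **Curve distance** — fit a polynomial *y = p(x)* (default cubic) through
   the actives' (PC1, PC2) points and compute each candidate's shortest
   Euclidean distance *D*min to the curve. With *Q*(x₀, y₀) the candidate
   and the curve restricted to the actives' PC1 range [x_M, x_N], the
   interior feet solve the stationarity condition of the constrained
   minimization,

       (x − x₀) + (p(x) − y₀)·p′(x) = 0,

   a polynomial of degree 2·deg − 1 solved by companion-matrix roots;
   *D*min is the minimum over interior feet and the endpoints *M*, *N*.
   Candidates with *D*min < 0.2 (strict, configurable) are significant.
4. **Similarity** — mean Tanimoto index c/(a + b − c) of each candidate's
   topological path fingerprint against the active panel; pass if the mean
   exceeds 0.7 (strict).
5. **ADMET gate** — rule-encoded drug-likeness / PAINS / ADMET verdicts on
   a table of predicted endpoints (pass needs drug-likeness ≥ 0.5, zero
   PAINS alerts, F20% ≤ 0.7, PPB < 90%, acute-oral-toxicity and
   skin-sensitization probabilities ≤ 0.7).
6. **Networks** — intersect the candidate's predicted target set with a
   disease gene set and with the tissue-specific expression network
   (genes with RPKM ≥ 1 in > 80 % of tissue samples and Z-expression score
   (E(i,t) − E(i))/δ_E(i) > 2), then hypergeometric enrichment with Holm
   (step-down Bonferroni) correction against a user-supplied GMT.

The screening stages are sklearn-style estimators (`ChemSpaceScreen`,
`TanimotoPrioritizer`, `AdmetGate`) that compose with pipelines and grid
search; the network operations are plain functions over pandas tables.

## Worked example

Everything below runs on the package's own synthetic fixture bundle (no
downloads). The built-in reference ADMET panel of ten ginsenosides is the
canonical gate example:

```bash
python -c "from chemscreen.datasets import load_reference_admet_table as t; \
           t().to_csv('admet.csv', index=False)"
chemscreen gate --admet admet.csv --out verdicts.csv
```

prints

```json
{
  "n": 10,
  "n_pass": 3,
  "pass_ids": ["Ginsenoside F2", "Ginsenoside C-Mc", "Ginsenoside Mx"],
  "rule_failures": {"druglikeness": 0, "pains": 0, "f20": 6, "ppb": 1,
                    "aot": 0, "skin_sens": 0}
}
```

— three of the ten candidates pass every rule; six fail on predicted oral
bioavailability (F20% probability > 0.7) and one on plasma protein binding
(94.05 % ≥ 90 %).

The full funnel on a generated compound family:

```bash
chemscreen make-fixtures --seed 1 --out fx
```

```python
from chemscreen import RunConfig, run_screen

cfg = RunConfig(
    structures="fx/compounds.smi", labels="fx/labels.csv", out_dir="run",
    dti_tables=[f"fx/dti_{s}.tsv"
                for s in ("docking", "literature", "network_prediction")],
    disease_lists=[f"fx/disease_source_{i}.txt" for i in range(1, 5)],
    tissue_list="fx/tissue_genes.txt",
)
report = run_screen(cfg)
print(report.counts)
print(report.overlap)
```

prints (seed 1)

```
{'loaded': 98, 'unique': 98, 'known_active': 16, 'unknown': 82,
 'in_box': 17, 'distance_significant': 3, 'similarity_passing': 1}
{'n_targets': 222, 'n_disease': 124, 'n_tissue': 907,
 'targets_in_disease': 3, 'targets_in_tissue': 13, 'targets_in_both': 0,
 'targets_in_union': 16}
```

98 unique compounds survive standardization; 17 of the 82 unknowns fall
inside the actives' PC1–PC3 box, 3 sit within 0.2 of the active curve and
1 also clears the similarity screen. The merged drug–target network holds
222 unique human interactions, of which 3 touch the 124-gene disease set
and 13 the 907-gene tissue-specific set (16 in the union, so the two
attributions are disjoint here). Funnel counts on real descriptors are
implementation-defined — they depend on the descriptor set and scaling —
which is why every threshold is exposed in `RunConfig`.

Each stage is also available standalone (`chemscreen pca-screen`,
`chemscreen similarity`, `chemscreen gate`), reading and writing plain
CSV/TSV/JSON.

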