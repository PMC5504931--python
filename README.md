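# chmnet

Co-prescription network mining for Chinese herbal medicine (CHM) claims
data.

Traditional Chinese medicine doctors rarely prescribe a single product:
an ambulatory visit for a condition such as endometriosis typically
dispenses 6–7 herbal formulas (HF) and single herbs (SH) at once, chosen
to cover a patient's syndrome pattern.  Which items form the *core* of
therapy, and which combinations are clinically established, is invisible
in simple frequency rankings.  `chmnet` implements the standard
claims-database workflow for this question:

1. **Cohort filtering** — from a one-row-per-dispensed-item claims
   table, reconstruct visits, identify patients with a
   gynecologist-confirmed index diagnosis (ICD-9-CM prefix match), and
   apply an inclusion/exclusion cascade (reproductive age 20–50 at the
   visit, disease code in the primary position, no acupuncture /
   moxibustion / manual therapy on the visit, at least one CHM item),
   with a full attrition report.
2. **Association rule mining** — a from-scratch level-wise Apriori over
   prescriptions (the set of distinct CHM codes of one retained visit).
   For an itemset *S*, support(*S*) = fraction of prescriptions
   containing *S*; for a rule *A*→*B*, confidence = support(*A*∪*B*) /
   support(*A*) and lift = confidence / support(*B*).  Rules pass the
   screen iff support ≥ 1%, confidence ≥ 30% and lift > 1 (strict);
   directions are collapsed to unordered combination tables ranked by
   prevalence.
3. **Network analysis** — the top-30 two-CHM combinations become a
   simple undirected graph (node size = item prevalence, edge weight =
   combination support, edge strength = lift); communities are detected
   automatically with Clauset–Newman–Moore greedy modularity
   maximization, and each cluster's **core CHM** (highest prevalence,
   then support-weighted degree) is identified along with the global
   core.
4. **Utilization summaries** — prevalence-ranked HF/SH tables with mean
   dose (g/day) and duration (days/visit), and the items-per-prescription
   distribution.

Because the national insurance databases such analyses are run on are
access-restricted, the package ships a **synthetic cohort generator**
(`chmnet.synth`) that emulates their observable structure — marginal
prevalences spanning ~1–30%, a dominant hub formula at 28.1%, ~6.2 items
per prescription, per-kind dose scales — and plants six disjoint item
clusters with boosted within-cluster co-occurrence plus rule-violating
decoy visits.  The planted structure is returned as a `GroundTruth`
object, so every downstream stage has a recovery target.

## Worked example

Generate a 20,000-visit synthetic cohort, filter it, mine it, and build
the network:

```bash
chmnet generate --seed 7 --n-visits 20000 --out demo/cohort.csv
chmnet filter demo/cohort.csv --out-dir demo/f
chmnet mine demo/f/transactions.tsv --out-dir demo/m
chmnet network demo/f/transactions.tsv --out demo/net.graphml
```

The mining step prints the ranked two-CHM combination table (prevalence
= fraction of all prescriptions containing the pair; confidence and lift
from the higher-confidence direction):

```
428 frequent itemsets, 116 rules
  1 GZFLW+JWXYS                7.5% conf  43.7% lift 1.6
  2 GZFLW+TAOR                 6.6% conf  46.9% lift 1.7
  3 GZFLW+LEON                 6.4% conf  45.8% lift 1.6
  4 GZFLW+SFZYT                6.3% conf  45.0% lift 1.6
  5 GZFLW+SALV                 6.1% conf  43.7% lift 1.6
  6 CORY+MELI                  4.9% conf  35.2% lift 1.7
  ...
```

and the network step recovers the planted community structure:

```
21 nodes, 17 edges, 6 clusters (modularity 0.720)
cluster 1: core GZFLW
cluster 2: core CORY
...
global core: GZFLW
```

Gui-Zhi-Fu-Ling-Wan (GZFLW), the planted hub, is the most prevalent item
(28.1% of prescriptions), sits at the centre of the largest cluster, and
is identified as the global core — the sovereign medicinal of the
co-prescription network.  The whole pipeline can equally be driven from
one YAML config with `chmnet run-all config.yaml` (every artifact is
checksummed in the run report, and a fixed seed reproduces it
byte-for-byte), or from Python via `chmnet.pipeline.run`.

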