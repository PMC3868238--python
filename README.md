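# kinconn

Connectivity mapping between kinases and kinase inhibitors from
quantitative selectivity profiles.

## The problem

Small-molecule kinase inhibitors are rarely selective: a compound
designed against one kinase typically binds or inhibits dozens of
others across the human kinome. Panel-profiling studies quantify this
promiscuity as a drug × kinase matrix — either percent kinase
inhibition at a fixed compound concentration, or direct binding
affinities (dissociation constants K<sub>d</sub>, in μM). Those
off-target interactions are an opportunity: if a gene identified in a
screen happens to be a kinase, an existing inhibitor that hits it
potently is an immediate drug-repurposing candidate.

`kinconn` answers the question *"which inhibitors specifically hit this
set of kinases?"* with a connectivity-map-style, rank-based
Kolmogorov–Smirnov enrichment score. It is aimed at computational
biologists and translational researchers who have a kinase hit list
(from a functional screen, sequencing, or an annotation such as a
kinase family or a GO biological process) and a quantitative
kinase-inhibitor activity matrix.

## The score

Each drug *i*'s activity profile is converted into a rank-ordered
kinase list: rank 1 is the kinase it hits hardest (lowest K<sub>d</sub>
or highest percent inhibition; ties broken by kinase symbol). For a
query of *M* kinases found at sorted ranks R₁ ≤ … ≤ R_M within the
drug's *N*-kinase profile, compute

    a = max_{j=1..M} ( j/M − R_j/N )
    b = max_{j=1..M} ( R_j/N − (j−1)/M )

    KS_i = a   if a > b      (query concentrated at the top)
         = −b  if b > a      (query concentrated at the bottom)

Across the drugs of one database, with P = max_i KS_i and
Q = min_i KS_i, the connectivity score is

    S_i = KS_i / P   if KS_i > 0
        = −KS_i / Q  if KS_i < 0

so the most query-specific drug scores +1 and the most anti-correlated
scores −1. Drugs are ranked by the normalized score (S + 1)/2 ∈ [0, 1].
A running sum D(r) = hits(r)/M − r/N traces the enrichment down each
ranked list; its maximum equals `a`. Per-drug permutation p-values
compare the observed |KS| against random same-size rank sets drawn from
that drug's own profile (f/T over T = 500 trials by default).

## Worked example

Simulate a 12-drug × 60-kinase K<sub>d</sub> panel in which the drug
`metinib` is engineered to bind MET and ALK 100-fold more potently than
anything else it touches, then query those two kinases:

```bash
kinconn simulate --n-drugs 12 --n-kinases 60 --seed 11 \
    --spike "metinib:MET,ALK:100" --out demo_matrix.tsv
kinconn connect --reference demo_matrix.tsv --assay-type kd --layout long \
    --query MET --query ALK --permutations 500 --seed 11 --out demo_results.tsv
```

which prints

```
scored 12 drugs (0 unscored); top hits:
  #1 metinib  normalized=1.0000  p=0.004
  #2 drug002  normalized=0.8966  p=0.104
  #3 drug005  normalized=0.8190  p=0.284
  #4 drug007  normalized=0.7586  p=0.540
  #5 drug001  normalized=0.7328  p=0.680
```

`metinib` ranks both query kinases at the very top of its profile
(KS = 0.9667, the largest in the database, hence S = 1 and normalized
score 1.0), and only 2 of 500 random 2-kinase sets from its profile
score as extremely (p = 0.004). The runner-up `drug002` happens to rank
the query kinases fairly high by chance, but its p-value (0.104) shows
that is unremarkable. `demo_results.tsv` holds the full ranked table
with a provenance header (tool version, seed, trial count, input
digest); `--json` adds the per-drug running-sum curves and `--plots`
saves them as figures.

The same pipeline is available as a scikit-learn-style estimator:

```python
from kinconn import ConnectivityMapper, load_activity_matrix

matrix = load_activity_matrix("demo_matrix.tsv", "kd", layout="long")
est = ConnectivityMapper(n_permutations=500, random_state=11).fit(matrix)
table = est.connect(["MET", "ALK"]).table   # the ranked DataFrame
scores = est.transform([["MET"], ["ALK"]])  # (n_queries, n_drugs) matrix
```

Queries can also be expanded from a kinase-family table
(`--family TK --family-map families.tsv`) or a GO biological-process
table (`--go GO:0000165 --go-map go.tsv`).

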