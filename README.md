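# ise-screen

Ligand- and structure-based virtual screening in Python: learn
descriptor-range **filter models** by iterative stochastic elimination
(ISE), rank screening libraries by the **molecular bioactivity index
(MBI)**, evaluate enrichment, and triage docking poses by **consensus
receptor-contact geometry**. The toolkit generalizes the workflow used to
discover novel, scaffold-diverse PPAR-δ agonists from a 1.56-million
compound commercial library; it is target-agnostic and runs end to end on
synthetic fixtures, so no proprietary descriptors, docking software, or
external downloads are needed.

## Who is this for

Computational chemists who want an interpretable ligand-based classifier
(conjunctions of physico-chemical property ranges rather than a black-box
model) combined with a geometry-first post-docking filter, and method
developers who need a reference implementation of balanced-MCC filter
scoring, MBI ranking, applicability-domain curation, and consensus pose
voting.

## The method

**Filters.** A filter is a conjunction of k (default 4) closed numeric
ranges over named 2D descriptors: a molecule *passes* iff every value
lies inside its range. Each filter is scored on a labeled training set by
the class-balanced Matthews correlation coefficient: with n_A actives and
n_I inactives, the inactive counts are rescaled by s = n_A/n_I (FP′ =
s·FP, TN′ = s·TN) before the standard

    MCC = (TP·TN′ − FP′·FN) / √((TP+FP′)(TP+FN)(TN′+FP′)(TN′+FN))

which removes class-imbalance bias (equivalently: standard MCC on the
exactly class-replicated dataset).

**Iterative stochastic elimination.** The space of k-descriptor subsets
is explored by alternating (1) random sampling of many scored filters
(range bounds drawn from the actives' decile grid) and (2) elimination of
the descriptors whose containing filters have the worst mean MCC. Once
the surviving pool admits exhaustive enumeration, every k-subset is
instantiated with its best-scoring range assignment, near-duplicate
filters (pass/fail vectors agreeing on >99% of molecules) are collapsed,
and filters within ~20% of the top MCC form the model.

**MBI ranking.** Each model filter i carries a weight w_i = TPR_i/FPR_i
(FPR floored at 1/(2·n_I) when FP = 0). A library molecule scores
MBI = Σ_passed w_i − Σ_failed w_i; many weak binary filters thereby yield
a quantitative ranking. Evaluation reports confusion counts, balanced
MCC, and the enrichment factor EF = (TP/n_A)/(FP/n_I) per MBI border,
plus ROC AUC and active-capture curves.

**Curation.** Training actives are diversity-pruned at a Tanimoto
threshold (default T = 0.8, hashed linear-path fingerprints, 1–7 bonds,
1024 bits); presumed inactives are sampled from random library molecules
restricted to the actives' applicability domain (mean ± 2σ on lip_acc,
lip_don, cLogP, MW).

**Geometric pose triage.** From reference crystal complexes the package
derives *important* residues (van der Waals contact ≤ 3.9 Å with more
than 3 ligands, or an H-bond — N/O pair ≤ 3.3 Å — with at least one) and
*crucial-to-H-bond* residues (H-bond with every ligand). A docked pose
passes when it lies < 3.5 Å from ≥ 2 crucial and < 5 Å from ≥ 7 important
residues; a molecule is accepted if any of its 30 best-energy poses
passes (the lowest-energy passing pose is selected), and consensus voting
across several receptor structures keeps only molecules accepted in all
of them.

## Worked example

Learn a model on a small synthetic table (3 informative + 9 noise
descriptors, 60 actives / 300 inactives), then rank a held-out table:

```python
from ise_screen.datamodel_io import ISEConfig
from ise_screen.ise_core import build_model
from ise_screen.screening import (format_threshold_report, roc_and_enrichment,
                                  score_table, threshold_report)
from ise_screen.synthetic import SyntheticSpec, gen_descriptor_dataset

spec = dict(n_actives=60, n_inactives=300, n_informative=3, n_noise=9)
train = gen_descriptor_dataset(SyntheticSpec(**spec, seed=5))
model = build_model(train.table, ISEConfig(filters_per_iteration=150,
                                           exhaustive_threshold=100, seed=5))
print(f"{len(model.filters)} filters, MCC "
      f"{model.filters[-1].mcc:.3f}-{model.filters[0].mcc:.3f}")

test = gen_descriptor_dataset(SyntheticSpec(**spec, seed=6))
scored = score_table(model, test.table, normalize=True)
print(format_threshold_report(threshold_report(scored["mbi"], scored["label"],
                                               [-20, 0, 20])))
print(f"AUC {roc_and_enrichment(scored['mbi'], scored['label']).auc:.3f}")
```

prints

```
7 filters, MCC 0.851-0.983
         tn  fn  tp  fp enrichment    mcc
border
-20     291   1  59   9       32.8  0.953
 0      298   9  51   2      127.5  0.852
 20     300  20  40   0          —  0.707
AUC 0.997
```

The model kept 7 filters inside the 20% MCC band. At the MBI border 0,
51 of 60 held-out actives are recovered against 2 of 300 inactives: a
127-fold enrichment over random picking and balanced MCC 0.85; at border
+20 no inactive survives, so the enrichment factor is undefined (printed
as an em-dash). The ranking separates the classes almost perfectly
(AUC 0.997).

The same stages are scriptable from the shell via the `ise-screen` CLI
(`descriptors`, `prune`, `pick-inactives`, `train`, `score`, `report`,
`derive-residues`, `filter-poses`, `simulate`, `run`); `ise-screen run
--config pipeline.yaml` executes a whole configured pipeline with
checksum-based stage skipping.

## Limitations

See `docs/methods.md` for the model assumptions, parameter defaults,
numerical conventions, and what the synthetic generators do and do not
emulate. The package does not perform docking, conformer generation, or
descriptor parity with any commercial package.
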