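# apoptopredict

Predicting glioma cell-line responsiveness to temozolomide (TMZ), TRAIL and
their combination from quantitative apoptosis-protein profiles.

## The science

Whether a glioma cell dies under treatment is largely decided by the balance
of its apoptosis machinery: death-receptor (extrinsic) signaling through
DR4/DR5–FADD–caspase-8, mitochondrial (intrinsic) commitment through
Bcl-2-family proteins and Bax/Bak pore formation, and downstream execution
through the apoptosome, caspase-3 and their inhibitors (cFLIP, XIAP, offset
by SMAC). This package implements a pipeline that turns absolute
quantifications of 19 such proteins into treatment-response predictions:

1. **Functional groups (FGs).** The 19 proteins are collapsed into 11
   pathway-informed features, each protein used exactly once. Redundant
   actors are summed (Bcl-2 + Bcl-xL + Mcl-1; Bax + Bak; DR4 + DR5), obligate
   complexes are multiplied (Apaf-1 × caspase-9; receptor sum × FADD), and
   inhibitor pairs become ratios (caspase-8/cFLIP, caspase-3/XIAP). BH3-only
   proteins (Bid, Bim, Puma, Noxa) and SMAC enter as singletons.
2. **PC space.** FG units are heterogeneous, so each FG is z-scored and the
   correlation matrix is eigendecomposed; components with eigenvalue > 1 are
   retained (Kaiser criterion). The standardization and loadings are frozen
   so new or perturbed lines project into the same space.
3. **Response classes and LOOCV.** Survival under each monotherapy is binned
   into HIGH / LOW / RESISTANT response classes (≤ 0.30 / ≤ 0.80 / > 0.80
   surviving fraction); linear discriminant analysis separates the classes in
   PC space, and prediction quality is measured by leave-one-out
   cross-validation with the full standardization + PCA + LDA stack refit on
   every fold.
4. **Synergy.** The TMZ+TRAIL combination index is Webb's fractional product,
   CI = s_combo / (s_TMZ × s_TRAIL); CI < 1 means synergy. CI bins feed the
   same PC-space classification machinery.
5. **Sensitization.** An in-silico Bcl-2/Bcl-xL depletion (the ABT-737
   mechanism) recomputes the FGs and reprojects each line; a line is
   predicted sensitized when it lands in a strictly more responsive class
   region. Because projection is linear, this equals an explicit
   movement-vector formulation, which the tests exploit as an oracle.

A synthetic-data module generates protein panels and viability tables with
known ground truth (response classes, true CI, sensitization targets), so
every stage of the pipeline can be validated by parameter recovery.

## Worked example

The numbered scripts under `analysis/` run the full study on a simulated
11-line cohort (seed 1) and write tables under `results/`:

```bash
python analysis/01_simulate_cohort.py
python analysis/02_functional_groups.py
python analysis/03_pc_space.py
python analysis/04_response_loocv.py
python analysis/05_synergy.py
python analysis/06_sensitization.py
```

Actual output of step 3 (the PC space):

```
retained k = 4 (Kaiser)
explained fraction = 0.805
  pc  eigenvalue  cumulative_explained
 PC1       3.830                 0.348
 PC2       2.115                 0.540
 PC3       1.658                 0.691
 PC4       1.248                 0.805
 ...
```

and of steps 4–6 (prediction, synergy, sensitization):

```
TMZ: LOOCV accuracy = 0.545
TRAIL: LOOCV accuracy = 0.091
recommendation accuracy = 0.273
median CI = 0.989 (CI < 1 = synergy)
synergy LOOCV accuracy = 0.545
3/11 lines predicted sensitized by Bcl-2/Bcl-xL depletion
```

At n = 11 lines with realistic noise and class separation, LOOCV accuracy is
highly seed-dependent — that is the honest picture for cohorts of this size.
With stronger class separation the machinery recovers the truth reliably
(mean LOOCV accuracy 0.98 over 50 seeds at 6-SD separation, n = 24; see
`results/acceptance.json`).

The same pipeline is available as a CLI:

```bash
apoptopredict simulate --seed 1 --out results/
apoptopredict run-all --panel results/panel.csv \
    --viability results/viability.csv --fraction --out results/run/
```

or programmatically:

```python
import apoptopredict as ap

panel = ap.read_protein_panel("results/panel.csv")
fg = ap.compute_fg_matrix(panel)
pc = ap.fit_pc_model(fg)
print(pc.k, pc.explained_fraction)
```

## Layout

- `src/apoptopredict/` — the package: `io_model`, `functional_groups`,
  `pc_space`, `response_classification`, `loocv_prediction`, `synergy`,
  `sensitization`, `synthetic_data`, `pipeline`, `cli`.
- `analysis/` — numbered study scripts (thin drivers over the package).
- `scripts/acceptance.py` — self-contained metrics report.
- `tests/` — unit, property-based (hypothesis) and acceptance tests.
- `docs/methods.md` — models, parameters, numerical choices, limitations.
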