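# cocultnet

Multiomic analysis of tumor-stroma contact co-culture: which molecules do
ER+ breast cancer cells *borrow* from bone-marrow stromal cells, and does
that borrowed signature carry prognostic information?

The package is organized as an analysis project: the reusable library lives
under `src/cocultnet/`, numbered narrative drivers under `analysis/` run the
study end to end on synthetic data with planted ground truth, and
`results/` collects their outputs.

## The inference chain

Starting from a four-arm expression design — stromal **donor** monoculture,
tumor **recipient** monoculture, recipient in direct-**contact** culture,
recipient in **conditioned media** — plus matched proteomics:

1. **Catalog** genes high in the donor but not the recipient
   (|log2FC| ≥ 2, BH-adjusted p < 0.05): everything the recipient could
   plausibly borrow.
2. **Triage** contact-induced molecules (RNA ∪ protein evidence):
   `borrowed` = induced ∩ catalog, `intrinsic` = induced \ catalog,
   `cm_unique` = media-induced only; genes induced in both contact and
   media keep a `cm_shared` flag. The RNA ∩ protein intersection is the
   cross-platform signature.
3. **Network**: grow a PPI network from the signature as seeds (STRING-style
   edge table, confidence ≥ 0.4), project borrowed/intrinsic bins as
   layers, and test the overlap of their closed neighborhoods with an
   exact upper-tail hypergeometric.
4. **Refine** the borrowed list by per-gene ROC-AUC (Mann-Whitney identity,
   ties 0.5): keep genes with contact-vs-mono AUC > 0.85 in *every*
   validation dataset.
5. **Score** signatures as the mean of per-gene z-scores
   (score_s = mean_g z_gs), compare groups by one-way ANOVA + Tukey HSD,
   cluster samples on the z-profiles.
6. **Survive**: split patients high/low at a one-step least-squares
   threshold on their composite scores and compare strata with
   Kaplan-Meier curves and the log-rank test.

A synthetic-data module generates every input with known ground truth —
negative-binomial counts with planted transfer/intrinsic/CM gene sets, a
proteome with abundance-dependent dropout, a scale-free interaction network
with planted inter-layer wiring (plus a degree-matched rewired control),
and a survival cohort whose hazard follows a latent signature state — so
every stage's recovery, calibration and discrimination are measurable.
`docs/methods.md` describes the models, parameters and design choices.

## Worked example

```bash
python analysis/01_simulate.py
python analysis/02_differential.py
python analysis/03_triage.py
```

prints (abridged):

```
simulated 2000 genes x 12 samples
planted: 150 transfer, 80 intrinsic, 10 conditioned-media genes
proteome detected 1428 / 2000 genes (low-abundance dropout)
...
donor-high catalog: 188 genes
contact-induced evidence: 225 RNA + 165 protein -> 232 unique molecules
bins: 141 borrowed, 91 intrinsic, 0 CM-unique (9 CM-shared flagged)
cross-platform signature (RNA & protein): 158 genes
borrowed recovery vs planted truth: precision 1.000, recall 0.940
intrinsic recovery vs planted truth: precision 0.963, recall 0.988
```

The catalog holds the 150 planted transfer genes plus ~40 genuine
cell-line-difference genes; triage then recovers the planted borrowed and
intrinsic sets at ≥ 0.94 precision/recall, with the 9 planted
conditioned-media genes correctly surfacing via the `cm_shared` flag.
Continuing the chain:

```
python analysis/04_network.py      # inter-layer hypergeometric p = 1.9e-51
                                   # (rewired degree-matched control: p = 0.019)
python analysis/05_refine_score.py # 141/141 borrowed candidates pass AUC > 0.85
                                   # ANOVA F = 2106, Tukey contact-vs-mono p = 1.8e-11
python analysis/06_survival.py     # step threshold -0.066 -> 111 high / 89 low
                                   # log-rank chi2 = 21.1, p = 4.5e-06, 44% censored
```

The same pipeline is scriptable from one config via the CLI:

```bash
cocultnet run --outdir results/cli_run --seed 7
cocultnet simulate --outdir tmp --seed 7      # stage-wise subcommands:
cocultnet deg|triage|network|refine|score|survive|verify --help
```

`cocultnet verify` recomputes printed set/network counts from
supplementary-style tables (gene lists and node/edge lists) by pure set
operations and reports match / mismatch / not-evaluable per target.

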