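# stilquant

Automated scoring of stromal tumor-infiltrating lymphocytes (sTIL) on
H&E-stained tissue images, and the downstream genotype–sTIL–survival
analysis used to evaluate sTIL and germline SNPs as prognostic markers in
esophageal squamous cell carcinoma (ESCC) cohorts.

The percentage of sTIL — the fraction of stromal area occupied by
lymphocytes, restricted to tumor regions — is a prognostic marker that is
usually estimated visually by pathologists. This package implements an
unsupervised three-step image algorithm that computes it reproducibly,
plus the statistical pipeline that relates it to genotypes and
disease-free survival (DFS):

1. **Quantization.** The intensity distribution of each RGB channel is
   decomposed into a Gaussian mixture by EM; the pooled component means
   are k-means-clustered to derive multi-class quantization thresholds,
   with the optimal class count K chosen by the Dunn cluster-validity
   criterion. Classes are annotated as nucleus / cytoplasm / stroma /
   other by nearest stain prototype.
2. **Lymphocyte identification.** Connected nucleus segments are
   classified by five features: (i) size relative to the other detected
   nuclei, (ii) roundness 4πA/P², (iii) eccentricity √(1−λ₂/λ₁),
   (iv) nucleus-to-cell size ratio, (v) staining variation. Lymphocytes
   are assembled from the nucleus and its attributed cytoplasm.
3. **sTIL scoring.** Within the tumor region,
   sTIL% = 100 · (stromal lymphocyte area) / (total stromal area).

Downstream, the package provides the tie-corrected Kruskal–Wallis H test
with pairwise rank post-hocs (genotype vs sTIL), chi-square independence
tests, Kaplan–Meier/log-rank analysis, Cox proportional-hazards fitting
(Newton–Raphson, Efron ties, reference/dominant genotype codings,
treatment-stratified fits), and a combined-vs-clinical prognostic model
comparison by test-set ROC AUC with DeLong's test.

Because the original patient data and slides are not deposited, the
package ships first-class synthetic generators: H&E-like tiles with
ground-truth masks and known true sTIL, and cohorts with Hardy–Weinberg
genotypes, genotype-dependent sTIL shifts, and proportional-hazards DFS.

## Worked example

```python
from stilquant.simtiles import TileSimConfig, render_tile
from stilquant.pipeline import score_tile

tile, truth = render_tile(TileSimConfig(target_stil_percent=25.0), seed=5)
score = score_tile(tile, tumor_mask=truth.tumor_region, seed=5)
print(score.K, round(truth.true_stil_percent, 2), round(score.result.stil_percent, 2))
```

prints `4 25.09 25.06`: the Dunn criterion recovers the four stain
classes, and the estimated sTIL percentage matches the ground truth to
within a few hundredths of a point on this tile.

The full analysis is a sequence of numbered drivers (each accepts
`--seed`) writing tables under `results/`:

```sh
python analysis/01_simulate_tiles.py --seed 7      # tiles + masks + truth
python analysis/02_quantify_stil.py --seed 7       # per-tile sTIL estimates
python analysis/03_simulate_cohort.py --seed 7     # 969-patient cohort
python analysis/04_genotype_stil_association.py --seed 7
python analysis/05_survival_models.py --seed 7
python analysis/06_prognostic_model.py --seed 7
```

With `--seed 7` the last three report, among other things: the two SNPs
given a real sTIL shift by the generator flagged by the Kruskal–Wallis
sweep (p < 0.05); a per-point sTIL hazard ratio of 0.964 in the clinical
multivariable Cox model; and a test-set AUC of 0.724 for the combined
model (clinical + sTIL + SNPs) against 0.647 for the clinical-only model
(DeLong p = 0.011) — a higher sTIL percentage predicts better DFS, and
adding sTIL and genotypes to the clinical covariates improves prognosis
prediction.

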