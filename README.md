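# stresspheno

Quantitative phenotyping tools for chronic-stress studies in mice. The
package implements, as a tested and reusable pipeline, three analyses that
commonly travel together in chronic-stress neurophysiology work:

1. **Composite physiological stress scoring (D-score).** Chronic activation
   of the HPA axis blunts body-weight gain, enlarges the adrenal glands and
   shrinks the thymus — but individual animals respond heterogeneously, so
   the assigned group label ("control" / "stress") is an unreliable readout
   of an animal's actual physiological state. Each marker is treated as a
   binary classifier: a ROC curve is built with the stressed group as the
   positive class, and the cutoff maximizing the Youden index

   *J* = TPR − FPR

   is selected per marker. A mouse scores one point per marker strictly
   beyond its cutoff in the stress direction (adrenal above; body-weight
   gain and thymus below). The cumulative **D-score** ∈ {0,1,2,3}
   classifies the animal: 0–1 non-stressed, 2–3 stressed. Cohort summaries
   report the D-score distribution per group and the *retention* — the
   fraction of controls scoring 0–1 and of stressed mice scoring 2–3.

2. **Striatal unit typing from spike waveforms.** Medium spiny neurons
   (MSNs) fire broad extracellular spikes; striatal interneurons fire
   narrow ones. From each sorted unit's mean waveform two shape features
   are measured — trough **half-width** (width at half the trough
   amplitude, linearly interpolated) and **trough-to-peak** duration — and
   a two-component Gaussian mixture fitted to the pooled 2-D feature cloud
   separates putative MSNs (the component with the larger mean
   trough-to-peak) from interneurons. Firing-rate summaries and Welch
   comparisons per (group × class) cell follow.

3. **Behavioral motif communities.** Frame-wise motif labels (from
   upstream pose estimation and unsupervised segmentation; e.g. 38 motifs
   at 60 frames/s) are summarized as usage fractions and as transition
   matrices between successive *distinct* motifs (runs collapsed). An
   average-linkage agglomerative tree on the symmetrized transition
   affinity (*A* = (P + Pᵀ)/2, distance 1 − *A*) is pruned to a target
   number of behavioral communities (walk, groom, rear, ...), and
   community usage is compared across groups (Welch) and within-animal
   conditions (paired t).

A seeded synthetic-data module emulates all three input modalities
(two-group Gaussian cohorts, trough-dominant spike templates with Poisson
trains, block-structured Markov motif sequences), so the full pipeline runs
with no downloads and every stage can be validated against generator ground
truth.

## Worked example

```python
from stresspheno import DScoreModel
from stresspheno.synthetic import PhysioGenSpec, gen_physio_cohort

cohort = gen_physio_cohort(PhysioGenSpec(seed=10))   # 88 control + 90 stress mice
print(DScoreModel(cohort).fit().summary())
```

```
D-score classification summary
  mice: 178  (cutoff source: auto)
  cutoffs:
         bw_gain_g = 4.4945, AUC=0.632
      adrenal_norm = 0.000110742, AUC=0.721
       thymus_norm = 0.00165096, AUC=0.704
  D-score distribution (% of group):
     control  D0: 31.8  D1: 43.2  D2: 22.7  D3:  2.3
      stress  D0:  2.2  D1: 27.8  D2: 42.2  D3: 27.8
  retention control: 75.0% (D0+D1)
  retention stress: 70.0% (D2+D3)
```

Reading this: the Youden cutoffs were derived from this cohort (marker AUCs
0.63–0.72, i.e. individually mediocre classifiers); combining them, 75% of
control animals keep a D-score of 0–1 ("true" controls) and 70% of the
stressed group score 2–3 ("true" stressed) — the remaining animals would be
excluded from downstream analyses as physiological non-responders or
spontaneous responders. Published cutoffs can be frozen instead of
re-derived with `fit(cutoffs=stresspheno.config.PAPER_CUTOFFS)`.

The unit-typing and motif stages follow the same model/results pattern
(`UnitTypeModel.from_units(...).fit()`, `CommunityModel(seqs, 38).fit(8)`);
see `docs/methods.md`. Everything is also available from the shell:

```sh
stresspheno --seed 4 --out-dir results simulate
stresspheno --out-dir results phenoscore --input results/synthetic_cohort.csv
stresspheno --out-dir results motifs --labels results/synthetic_motifs.csv --communities 8
stresspheno run-all
```

Each run writes CSV/JSON outputs plus a `manifest.json` with a config
snapshot and per-file SHA-256 checksums; identical config and seed give
bit-identical outputs.

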