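# fpvstag

Analysis toolkit for **fast periodic visual stimulation (FPVS) oddball
designs** — the frequency-tagging paradigm in which stimuli stream at a
base rate (6 Hz) while a deviant category recurs at an oddball rate
(3 Hz), so that any neural response distinguishing the categories appears
as a spectral peak at exactly 3 Hz. The package is written for
electrophysiology researchers (MEG/EEG) who want the full quantification
and inference chain of this paradigm as tested, reusable, scriptable code:

* a **synthetic multi-sensor data generator** (steady-state sinusoids with
  smooth sensor topographies + 1/f^β noise + subject variability) with a
  ground-truth manifest, so every stage is verifiable without real
  recordings;
* **spectral quantification**: coherent trial averaging, amplitude FFT,
  planar-gradiometer pair combination, surrounding-bin baseline
  correction, and oddball response extraction;
* **statistical inference**: paired cluster-based permutation tests on
  sensor/vertex adjacency graphs (Monte Carlo sign flips with an
  exhaustive small-n oracle), Hedges *g* with noncentral-*t* confidence
  intervals, and JZS Bayes factors with moderate-evidence tabulation;
* an **end-to-end pipeline and CLI** with deterministic, manifest-tracked
  outputs.

## The model in brief

The response of interest at sensor *s* is the baseline-corrected amplitude
at the oddball frequency,

    R_s = A_s(3 Hz) − mean of 20 surrounding bins
          (12 per side minus 1 adjacent, pooled, max & min dropped),

where `A_s` is the one-sided amplitude spectrum (`2|X_k|/N`) of the
trial-averaged epoch. Discrimination is assessed by a one-tailed paired
cluster permutation test of `R(experimental) − R(baseline)` across
subjects: node-wise paired *t* values above the critical value at α = 0.05
are clustered by graph adjacency, each cluster's mass Σt is referred to
the permutation null of the maximum cluster mass under per-subject sign
flips, with p = (1 + exceedances)/(1 + N_perm). Effect sizes are Hedges
g = (mean/SD)·(1 − 3/(4ν−1)); non-significant effects can be quantified by
the JZS Bayes factor (Cauchy prior scale r = 0.707), with BF₁₀ < 1/3 or
> 3 counted as moderate evidence for H0 / H1. See `docs/methods.md` for
the full account.

## Worked example

Simulate a 12-subject cohort with a 0.5-amplitude oddball response, run
the whole chain, and test the experimental-vs-baseline contrast:

```python
import fpvstag as f

layout = f.hemisphere_layout(n_sites=8)               # 8 mags + 16 grads
graph  = f.build_adjacency(layout, max_dist=0.08, kind="mag")
sim    = f.SimulationConfig(fs=60.0, noise_sigma=0.5, subject_cv=0.2,
                            odd_amplitudes={1: 0.5})
epochs, truth = f.simulate_cohort(sim, layout, n_subjects=12,
                                  trials_per_condition=4, seed=3)
maps = [f.epochs_to_response(es, f_target=3.0, layout=layout,
                             sensor_set="mag") for es in epochs]
model = f.FPVSContrast.from_response_maps(
    maps, "experimental", "baseline", graph,
    cluster_config=f.ClusterConfig(n_permutations=2000, seed=5))
res = model.fit()
print(res.summary())
```

prints

```
FPVS contrast: experimental vs baseline
  subjects: 12   nodes: 8   df: 11
  method: montecarlo   permutations: 2000   cluster-forming t > 1.796
  cluster 0: 2 nodes, mass = 33.70, p = 0.0005, g = 5.53 [3.19, 7.86] *
  cluster 1: 2 nodes, mass = 6.62, p = 0.0135, g = 1.02 [0.33, 1.68] *
```

Two significant clusters (starred at α = 0.05) recover the injected
effect: the cluster near the oddball topography's center has mass
Σt = 33.70 — far beyond anything the 2000 sign-flip permutations produce,
hence p = 0.0005 = 1/2001, the smallest attainable value — and a very
large standardized effect (g = 5.53) because the per-subject noise at a
single bin is tiny relative to a 0.5-amplitude response. The Bayes factor
map and evidence counts come from `res.bayes_map()` and
`res.evidence_table(...)`; here 4 of the 8 sensors show BF₁₀ > 3.

The same analysis from the shell:

```sh
fpvstag simulate --config sim.yaml --out epochs/ --seed 3
fpvstag spectrum --in epochs/ --target-freq 3.0 --sensor-set mag --out resp.tsv
fpvstag test --responses resp.tsv --exp experimental --base baseline \
             --graph epochs/layout.csv --kind mag --max-dist 0.08 \
             --n-perm 2000 --seed 5
fpvstag run  --config experiment.yaml --out results/   # full multi-contrast replica
```

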