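# nmjcal

Quantitative analysis of compartment-specific Ca²⁺ imaging at the
*Drosophila* larval neuromuscular junction (NMJ), for labs comparing evoked
and spontaneous presynaptic responses between genotypes — e.g. wild-type
terminals against mutants of ER-shaping proteins, where evoked responses in
cytosol, ER lumen and mitochondria drop to roughly half.

The package covers the full path from raw recordings to statistics:

* **Live traces** — fluorescence movies (GCaMP in the cytosol or muscle,
  ER-lumen sensors, mitochondrial CEPIA) are background-subtracted
  (rolling ball, 50 px), drift-stabilized by masked phase correlation
  within an NMJ ROI, reduced to per-ROI mean traces, and quality-filtered
  (residual motion, out-of-focus, NMJs with fewer than 3 usable ROIs).
* **Trace analysis** — photobleaching of the baseline is modeled as a
  power curve **PC(x) = a·xᵇ** fitted to the pre-stimulation frames
  (log–log ordinary least squares) and divided out of the whole time
  course, so the corrected baseline sits at 1 and **ΔF/F = F/PC − 1**.
  After a 5-frame rolling average the evoked readouts are extracted:
  resting F (the fitted curve at the last pre-stimulation frame), max F,
  ΔF, max and post-stimulation min ΔF/F, time to peak, time to 50% and
  100% recovery.
* **Miniature events** — spontaneous single-vesicle transients in resting
  recordings are detected as sharp-onset local maxima above 3 robust SDs
  and scored as events/s (5-s window) and maximal ΔF/F (20-s window).
* **Static images** — marker intensity inside an NMJ mask, ratiometry to a
  membrane-marker reference channel, Intermodes histogram thresholding to
  partition bright puncta from the dim tubule network, and
  connected-component object sizes.
* **Statistics** — per-larva datapoints (one mean per animal), a
  Shapiro-Wilk normality gate routing to Student's *t* / Mann-Whitney U
  (two groups) or ANOVA / Kruskal-Wallis (more), a genotype × stimulation-
  frequency mixed-effects repeated-measures ANOVA with a random intercept
  per larva, and Tukey HSD / Dunnett post-hoc comparisons.
* **Synthetic data** — a generator producing traces, drifting multi-bouton
  movies and two-channel static images from the forward model
  `F(i) = a·(i+1)ᵇ · [1 + g·r(tᵢ) + Σ mₖ(tᵢ)] + ε`, with
  compartment-specific evoked kernels r(t), a genotype scale g, Poisson
  miniature events mₖ and Gaussian/shot noise — every drawn quantity is
  recorded as ground truth, so each stage is testable without any
  download.

## Worked example

Simulate a wild-type and a mutant cytosolic recording (40 Hz train from
5 s to 7 s, 2% noise) and extract evoked features:

```
$ nmjcal simulate --compartment cytosol --noise-sd 20 --seed 11 --out wt.csv
wrote wt.csv (1000 frames at 50.0 Hz)
$ nmjcal trace wt.csv --out wt_features.csv
max dF/F = 1.5003; time to peak = 1.980 s
$ nmjcal simulate --compartment cytosol --genotype-scale 0.5 --noise-sd 20 --seed 12 --out mut.csv
$ nmjcal trace mut.csv --out mut_features.csv
max dF/F = 0.7447; time to peak = 2.000 s
```

The wild-type trace recovers its generating peak (ΔF/F 1.5) to 0.02%, the
mutant (generated at half amplitude) reads 0.74, and both peak at the end
of the 2-s train. A full cohort — 10 larvae per genotype across
5/20/40/80 Hz — runs end to end with one command:

```
$ nmjcal run --seed 3 --out demo_out
genotype effect p = 3.501e-40
$ cat demo_out/stats_report.txt
Genotype x frequency mixed-effects repeated-measures ANOVA
  between_effect: chi2=176.067 df=1 p=3.501e-40
  within_effect: chi2=4615.904 df=3 p=0
  interaction: chi2=458.387 df=3 p=4.966e-99
  WT: n=40 mean=0.7849 sem=0.0528
  mutant: n=40 mean=0.4162 sem=0.0276
  normalized non-control mean: 0.5303
```

The genotype main effect is decisive, evoked amplitude grows with
stimulation frequency, and the mutant mean normalized to the wild-type
mean lands near the generating ratio of 0.5.

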