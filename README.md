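# viamet

Viability-aware quantitative microbiome profiling: analysis of PMA/PMAxx
viability-PCR experiments on complex communities (saliva, feces), paired with
a forward simulator of spike-in live/dead studies.

## The problem

Shotgun metagenomics and qPCR see *all* DNA in a sample — including host DNA
and relic DNA from dead cells, which can dominate the signal and distort the
apparent community. Viability dyes (PMAxx) covalently bind exposed
double-stranded DNA under blue light and block its amplification; combined
with osmotic lysis of host cells ("lyPMAxx"), both host DNA and dead-cell
DNA are excluded, leaving the viable community. This package implements the
downstream quantification for such experiments:

* **Depletion efficiency from ΔCt.** With per-cycle amplification efficiency
  *E*, the fraction of amplifiable template removed by a treatment is

  ```
  f_removed = 1 − (1 + E)^(−ΔCt),   ΔCt = Ct_treated − Ct_control
  ```

  (for perfect doubling, `1 − 2^(−ΔCt)`; a 4.37-cycle delay = 95.16% removed).

* **Microbiota load.** Total 16S rRNA gene copies per mL (saliva) or g
  (feces), from a plasmid standard curve `Ct = b + m·log10(copies)` with
  `E = 10^(−1/m) − 1`, scaled by explicit extraction/dilution bookkeeping.

* **Absolute abundance.** Per-taxon copies per unit: each sample's relative
  (MetaPhlAn-style) composition multiplied by its microbiota load, so
  treatment effects are comparable across samples with very different loads.

* **Treatment response.** Control/treated fold changes on species shared by
  all hosts, paired by (host, replicate), tested with an exact Wilcoxon
  signed-rank, and classified against fold thresholds into *responsive*,
  *intermediate* and *resilient* species.

* **Diversity layer.** Shannon/Simpson, Bray-Curtis `Σ|x−y|/Σ(x+y)`,
  classical-scaling PCoA, seeded-permutation ANOSIM, and within- vs
  between-host distance comparisons.

* **Forward simulator.** Ground-truth communities with per-taxon live/dead
  copy pools, Gram status, DNA-extraction bias, host contamination, spike-in
  dosing, qPCR noise/censoring and multinomial sequencing — so every
  estimator above can be validated by parameter recovery.

It is aimed at microbiome researchers running viability-PCR / quantitative
microbiome profiling studies, and at method developers who need a testable
generative model of such experiments.

## Worked example

```python
>>> from viamet import depletion_efficiency, mean_killed_percent
>>> depletion_efficiency(30.33, 34.70, efficiency=1.0).percent_removed
95.16
>>> mean_killed_percent([39.8, 44.7, 36.3])   # per-host survival percents
59.7
```

The first number: a dead-strain qPCR target whose Ct rises from 30.33 to
34.70 after treatment has lost 95.16% of its amplifiable DNA — the treatment
removed that fraction of the dead cells' signal. The second: if treated
loads in three hosts are 39.8%, 44.7% and 36.3% of their untreated controls,
then on average 59.7% of the community signal was dead or injured.

End to end, from a simulated study (`python examples/05_simulate_and_recover.py`):

```
true dead-DNA retention: 0.05 (=> 95% removal expected)
estimated dead-spike removal (%): {"saliva": 94.83, "feces": 94.88}
host reads, saliva (% of reads): {"control": 86.06, "frozen_lyPMAxx": 0.98, "lyPMAxx": 0.76}
mean killed (%): {"feces": {"lyPMAxx": 65.8, "freezing": 91.2}, "saliva": {"lyPMAxx": 61.5, "freezing": 68.1}}
ANOSIM by host: {"feces": {"R": 1.0, "p": 0.002}, "saliva": {"R": 1.0, "p": 0.002}}
```

The estimators recover the planted 95% removal, host reads collapse from
~86% to under 1% after treatment, and samples cluster by individual
(ANOSIM R ≈ 1): the analysis reproduces the structure the simulator planted.

Each script in `examples/` is a short narrative of one capability:
ΔCt arithmetic, loads and survival, absolute-abundance fold changes,
the diversity layer, and full simulate-and-recover.

A thin CLI wraps the same pipeline:

```bash
viamet all --seed 17 --out results/        # simulate + full report bundle
viamet report --in study_dir/ --out results/ --seed 17
```

## Layout

```
src/viamet/       qpcr, abundance, diversity, simulate, pipeline, io, cli
tests/            unit + property + end-to-end acceptance tests
examples/         one narrative script per capability
docs/methods.md   models, parameter choices, limitations
scripts/          acceptance.py
```
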