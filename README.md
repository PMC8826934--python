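# tempomics

Temporal-pattern analysis of multi-subject blood-molecule time courses after
an oral glucose challenge.

During an oral glucose tolerance test (OGTT), dozens of blood metabolites and
hormones — glucose, insulin, C-peptide, incretins, amino acids, free fatty
acids, ketone bodies — move on characteristic trajectories over the four
hours after ingestion. `tempomics` is for researchers who have such a panel
(many subjects × many molecules × a fixed sampling grid) and want to
characterise each molecule's response by four quantitative features:

1. **Amplitude/rate decomposition.** Mean normalized trajectories are
   clustered (Euclidean distance, Ward's method) and decomposed by PCA: PC1
   tracks the overall excursion magnitude and direction ("amplitude"), PC2
   how early the excursion happens ("rate"). Clusters are labelled
   large/small, transient/sustained, increase/decrease.
2. **TPSI** — temporal pattern similarity among individuals. For molecule
   *k* with difference-from-fasting trajectories x′ⱼ, one Pearson
   correlation over the concatenation of all subject pairs:
   TPSIₖ = ρ(X, Y) where (X, Y) stacks (x′ᵢ, x′ⱼ) for every unordered pair
   i < j (190 pairs for 20 subjects).
3. **TVRI** — temporal variation of relationships among individuals.
   Concentrations are z-scored across subjects at each time point;
   TVRIₖ = 1 − meanⱼ( sdₜ(z_{j,k,t}) ). TVRI = 1 means every subject keeps
   its relative position over the whole test.
4. **TPSM** — temporal pattern similarity among molecules.
   TPSM_{kl} = ρ(x′ₖ, x′ₗ) over subject-concatenated trajectories; edges
   with |TPSM| > 0.6 form a molecule network analysed for connected
   components, Brandes betweenness centrality, and group-normalized degree
   deg_Normalized(k) = degree(k) / |metabolic group of k|.

Around these sit the standard stages: missing-data exclusion (top-5% rule),
inter-individual normalization Y = (x − x₀)/S̄, responder calling
(|log2 FC| > 0.585, i.e. 1.5-fold, with Storey q < 0.1 from paired t-tests,
direction read at the earliest significant time), fasting-vs-time
correlation profiles, and per-individual AUC / T_AUC1/2 features screened
against reference molecules.

A first-class synthetic-cohort generator produces OGTT-like panels with
known ground truth (temporal archetypes per metabolic group, subject
baselines, dialable shape noise, rank stability and missingness), so every
statistic can be validated against what was planted.

## Worked example

```sh
tempo generate --preset study-like --n-subjects 20 --seed 7 --out cohort/
tempo run --input cohort/timecourse.csv --annotation cohort/annotation.csv --out results/
```

which prints:

```
responders: 20 (6 up, 14 down)
summary written to results/summary.json
```

The generated cohort has 83 molecules on the 13-point grid
(0, 10, …, 240 min). Twenty of them were planted with non-flat archetypes
and all twenty are recovered: the 6 "up" molecules are the glucose-related
group's large transient increase (peaking 45 min), the 14 "down" molecules
are the lipid-like transient decreases, amino-acid-like sustained
decreases, the two rebounding hormones and the citrulline-like bridge
molecule. `results/summary.json` also records the PCA variance split
(PC1 + PC2 ≈ 97.5% on this preset), the component census of the |TPSM| > 0.6
network, the molecule with the highest betweenness, and the AUC / T_AUC1/2
correlation screen. Stage tables (normalized trajectories, response
statistics, cluster labels, similarity indices, network edge/node lists,
per-subject features) are written alongside as CSV.

The same analysis is available as a library:

```python
import tempomics as tm

ds, truth = tm.generate_dataset(tm.study_like(seed=7))
summary = tm.run_pipeline(tm.PipelineConfig(output_dir="results"), dataset=ds)
```

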