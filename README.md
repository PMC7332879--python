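# residomics

Ancient-residue metabolomics: attributing plant-species use in
archaeological artifacts by comparing the *full extractable compound
profile* of an artifact residue against profiles of experimentally used
reference materials, instead of relying on a single biomarker.

## The problem and the approach

A biomarker such as nicotine proves that *some* tobacco was used in a
pipe, but cannot distinguish *Nicotiana quadrivalvis* from *N. rustica*,
nor detect co-smoked plants like smooth sumac (*Rhus glabra*) that have
no accepted biomarker. The metabolomics alternative: smoke candidate
species in replicate reference pipes, extract pipes sequentially with
three solvents (2% aqueous tartaric acid, acetonitrile:2-propanol:water
3:2:2, and MTBE — abbreviated TA/APW/MTBE), acquire untargeted LC-MS1
profiles, and reduce every sample to a *compound list* of aligned
(m/z, RT) features. Species use in an artifact is then ranked by simple
presence/absence set algebra:

```
shared(s)    = | target ∩ reference_s |
exclusive(s) = | reference_s \ ∪_{t≠s} reference_t |
```

with the most-shared reference species as the leading use hypothesis.

The package implements the whole chain, testable end to end on synthetic
data with known ground truth:

1. **feature extraction** per run (`residomics.features`): crop filter →
   centroid mass detection (noise ≥ 6.0e2) → greedy chromatogram builder
   (0.01 Th / 5 ppm, min span 0.01 min, min height 5.0e3) →
   baseline-cutoff deconvolution (baseline 9.0e3, min peak height 1.0e4,
   duration ≤ 2 min) → RT keep-window filter → ¹³C isotope grouping
   (Δm = 1.00336/z, most-intense representative);
2. **join alignment and curation** (`residomics.align`): weighted
   m/z + RT matching into a compounds × runs matrix, removal of rows
   shared with blank pipes, union-merge of each sample's three
   solvent-extract columns into one compound list;
3. **attribution** (`residomics.attribution`): Venn-style
   shared/exclusive counts, species ranking, and biomarker annotation
   with isobar discrimination (e.g. nicotine vs anabasine at m/z
   163.125, separated by RT and pseudo-MS/MS cosine);
4. **formula prediction** (`residomics.chem`): exhaustive CHNO lattice
   search at 3 ppm with isotope-pattern scoring (min 95%), sorted by
   mass error — the [M+H]⁺ convention adds the H-atom mass 1.00783 Da,
   reproducing the leucine-enkephalin lockmass 556.2771;
5. **ordination** (`residomics.ordination`): Jaccard distances + NMDS
   with ward.D clustering, and Pareto-scaled PCA
   (x′ = (x − x̄)/√s) of the abundance matrix;
6. **radiocarbon** (`residomics.radiocarbon`): calibration of
   conventional ¹⁴C ages to 2σ cal BP highest-posterior-density ranges
   against `.14c` curve files;
7. **synthetic studies** (`residomics.simulate`): a ground-truthed
   generator for the full design — 8 species × 3 solvents × replicates,
   blank pipes, 27 QC pools, and "ancient" mixtures with compound
   dropout and contaminants.

## Worked example

Simulate a study whose "ancient" pipe PIPE_A mixed *N. quadrivalvis*
(NQU) and *R. glabra* (RGL) at weights 0.5/0.5 with 30% compound
dropout, then run the pipeline against the 8-species QC references:

```python
from residomics.simulate import SimConfig, make_study
from residomics.pipeline import PipelineConfig, run_study
from residomics.attribution import rank_species

bundle = make_study(SimConfig(seed=42), roles=("qc", "blank", "ancient"))
res = run_study(bundle.runs, PipelineConfig())
rep = res.reports["PIPE_A"]
print(rep.table.to_string(index=False))
print("ranking:", rank_species(rep, 3))
```

prints

```
species  exclusive  shared
    AUV         44      16
    CSE         39      15
    NAT         47       8
    NQU         43      69
    NRU         44      19
    NTA         40      19
    RGL         55      70
    TBR         47      15
ranking: ['RGL', 'NQU', 'NRU']
```

The two planted species clearly top the shared-count ranking (70 and 69
versus ≤ 19 for the others); the nonzero background sharing of the other
species comes from the generator's cross-species compound overlap (10%
per species pair) plus surviving contaminants, exactly the ambiguity the
exclusive-count column helps read. `res.nmds.stress` (0.146 here) and
`res.pca.explained` carry the ordination diagnostics.

The same pipeline runs from the shell:

```sh
residomics simulate --out study/ --seed 42
residomics run --config pipeline.yaml --out results/
residomics formula --mz 163.1235 --ppm 3
residomics calibrate-c14 --age 1520 --sigma 40 --curve intcal13.14c
```

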