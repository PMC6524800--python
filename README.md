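# corecluster

Structure-based classification of protein families from C-alpha traces.

Distantly related proteins — protease clans are the motivating case —
often share a conserved spatial fold while their sequences have diverged
beyond the reach of sequence alignment (pairwise identities down to a
fraction of a percent). `corecluster` classifies such proteins directly
from their 3D structures:

1. **Curation** (`structure_io`): read PDB chains as C-alpha traces,
   trim to the domain of interest, and filter by length, missing
   residues, resolution, and a maximum pairwise sequence identity
   (Smith–Waterman, greedy clustering).
2. **Pairwise structural alignment** (`pairwise_align`): iterated Kabsch
   superposition + dynamic programming over per-residue properties
   (amino-acid similarity, pseudo bond/dihedral angles, backbone
   direction, post-fit C-alpha distance) yields equivalent residue
   pairs within a distance cut-off `d_cut`.
3. **Common core** (`core_builder`): agglomerative clustering — the most
   similar pair of structures (score `n_eq / (1 + rmsd)`) is merged into
   a core that represents the pair thereafter; strict intersection of
   columns ends with a clan-wide core of positions equivalent in *every*
   input structure.
4. **Distance tree** (`distance_tree`): pairwise distances over the core
   columns (mean C-alpha deviation + property dissimilarity), normalized
   to max 1, converted to an unrooted tree under the Fitch–Margoliash
   weighted least-squares criterion
   `Q(T) = Σ_{i<j} (d_ij − p_ij)² / d_ij²`
   (neighbor-joining start, non-negative WLS branch lengths, NNI hill
   climbing).
5. **Jackknife** (`jackknife`): one structure removed per
   family/subfamily unit, the whole analysis rerun, and each group
   scored by the fraction of replicates in which it forms an unrooted
   clade.

A synthetic-clan generator (`synthetic_data`) produces families of
protein-like traces that share a known core decorated with
family-specific loops, so the entire pipeline is testable with no
downloads and scored against ground truth.

## Worked example

```python
from corecluster import (
    SyntheticSpec, generate_clan, build_hierarchy, core_average_rmsd,
    core_recovery_metrics, build_distance_matrix, fitch_margoliash_tree,
    family_recovery_metrics, run_jackknife,
)

models, truth = generate_clan(SyntheticSpec(seed=1))   # 4 families x 4 members
root = build_hierarchy(models)                         # agglomerative merging
core = root.payload
print(core.n_columns, round(core_average_rmsd(core), 2))
print(core_recovery_metrics(core, truth))

dm = build_distance_matrix(core)
tree = fitch_margoliash_tree(dm)
print(family_recovery_metrics(tree, truth))

report = run_jackknife(models)
print(report.stability)
```

prints

```
59 1.7
(1.0, 0.9833333333333333)
{'fam0': True, 'fam1': True, 'fam2': True, 'fam3': True}
{'fam0': 1.0, 'fam1': 1.0, 'fam2': 1.0, 'fam3': 1.0}
```

i.e. the pipeline recovers a 59-column common core (59 of the 60
planted core positions, no spurious columns) with an average pairwise
rmsd of 1.7 Å across the 16 structures, every family is monophyletic in
the Fitch–Margoliash tree, and every family remains a clade in all
jackknife replicates.

The same steps are available from the shell:

```sh
corecluster simulate --seed 1 --out-dir clan/
corecluster filter --pdb-dir clan/ --min-length 60 --out manifest.tsv
corecluster core --pdb-dir clan/ --out core.tsv --guide-tree guide.nwk
corecluster tree --pdb-dir clan/ --out tree.nwk --matrix dist.tsv
corecluster jackknife --pdb-dir clan/ --labels clan/labels.tsv --out-dir jk/
corecluster evaluate --pdb-dir clan/ --truth clan/truth.json --tree tree.nwk
```

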