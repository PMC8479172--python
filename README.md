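# hingelatch

Analysis toolkit for a recurring question in membrane-enzyme dynamics: **how
does substrate binding at one site rigidify or release a distant domain
motion?**  The package implements the full trajectory-analysis chain for
hinge–latch allostery studies of ensembles of molecular-dynamics replicas:

- **Hydrogen-bond binding states** — geometric H-bond detection
  (donor–acceptor distance < 3.5 Å, donor–hydrogen–acceptor angle > 130°),
  per-bond and joint occupancies, and a three-state machine
  (fully bound → partially bound → unbound) driven by the persistence of two
  bond groups, with a persistence window that ignores transient flickers.
- **Comparative geometry** — Kabsch superposition on a stable core,
  distance-fluctuation ("rigid cluster") core finding, average structures,
  distance-difference maps with domain-block summaries, a **hinge scan**
  that locates the pivot of an interdomain rotation (displacement of the
  mobile domain grows linearly with distance from the true pivot), and
  latch-distance histograms.
- **Interaction energetics** — pairwise Coulomb + Lennard-Jones
  peptide–protein interaction energy, per-residue decomposition,
  between-condition difference tables, and jack-knife sampling checks.
- **Essential dynamics** — Cartesian PCA over pooled conditions, RMSIP
  subspace overlap, projection densities, cross-correlation matrices.
- **Allosteric networks** — residue graphs with edges where |C| ≥ 0.7 and
  weights −ln|C|, communities, betweenness, suboptimal source→sink paths,
  and community-level summary graphs.

Because real MD trajectories have no ground truth, the package ships a
**synthetic ensemble generator** (`hingelatch.synthetic`) that manufactures
coordinate time series with *known* answers: programmed H-bond on/off
schedules (exact two-state Markov statistics), a rigid-body hinge rotation
about a known pivot, correlated atom blocks at a target correlation,
scripted unbinding events, and Gaussian noise.  Every analysis is validated
by recovering those programmed parameters.

## Worked example

The default benchmark simulates two conditions of a 108-residue model
system (static domain, mobile domain, bound peptide): **TIGHT** (high bond
occupancies, 0° mean hinge angle) and **LOOSE** (lowered occupancies, 10°
hinge opening, weakened interdomain correlation).

```bash
hingelatch run-all --seed 0 --out results
```

prints the summary (exact output, seed 0):

```json
{
  "joint_groupA_LOOSE": 0.052,
  "joint_groupA_TIGHT": 0.5700,
  "hinge_best": 61,
  "hinge_best_r": 0.9990,
  "interaction_energy_mean_LOOSE": -32.65,
  "interaction_energy_mean_TIGHT": -24.28,
  "pc1_variance_fraction": 0.9952,
  "rmsip_conditions": 0.8602,
  "n_paths_TIGHT": 100,
  "n_paths_LOOSE": 0,
  "pin_path_fraction_TIGHT": 0.71
}
```

(abridged; the full report adds per-condition tail fractions, community
counts, and a file manifest with SHA-256 hashes).  Reading the numbers:

- the three group-A bonds are jointly present in 57 % of bound TIGHT frames
  but only 5 % of LOOSE frames — the binding signature;
- the hinge scan ranks residue **61** first (r = 0.999), which is exactly
  the programmed pivot;
- PC1 carries 99.5 % of the variance (the hinge opening is the essential
  motion) and the two conditions share their essential subspace
  (RMSIP 0.86);
- at the |C| ≥ 0.7 threshold the source→sink correlation pathway exists in
  TIGHT (100 suboptimal paths, 71 % passing through the pin residue) and
  vanishes in LOOSE — allosteric connectivity is lost with the looser
  substrate.

Output tables land in `results/`: `hbond_occupancy.tsv`,
`hinge_scan.tsv`, `latch_histograms.tsv`,
`distance_difference_blocks.tsv`, `energy_per_residue_difference.tsv`,
`pca_projections.tsv`, `network_edges_{TIGHT,LOOSE}.tsv`, and
`report.json`.

The same run is available programmatically:

```python
from hingelatch import pipeline

config = pipeline.default_config(seed=0)
report, state = pipeline.run(config, write_outputs=False)
report.summary["hinge_best"]        # 61
state["ddmap"].block_means          # domain-block distance differences
```

## Benchmark script

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

runs the full two-condition benchmark plus the numerical primitives and
writes 24 headline quantities (occupancies, hinge pivot and correlation,
energies, variance fractions, path counts, detection error, Kabsch
residual, jack-knife ratio) as flat JSON.  Everything is deterministic in
the seed.

## Layout

| Module | Contents |
| --- | --- |
| `hingelatch.trajectory_io` | topology/trajectory model, selections, PDB/DCD/columnar readers and writers, parameter tables |
| `hingelatch.synthetic` | ground-truth ensemble generator and the two reference conditions |
| `hingelatch.hbonds` | H-bond detection, occupancies, binding-state machine, termination metric |
| `hingelatch.geometry` | Kabsch, stable core, averages, distance-difference maps, hinge scan, latch histograms |
| `hingelatch.energetics` | Coulomb/LJ interaction energies, per-residue differences, jack-knife |
| `hingelatch.dynamics` | cross-correlations, Cartesian PCA, RMSIP, projection densities |
| `hingelatch.network` | correlation networks, communities, centralities, suboptimal paths |
| `hingelatch.pipeline` / `hingelatch.cli` | configuration-driven orchestration and the `hingelatch` command |

See `docs/methods.md` for the model definition, parameter choices, and
limitations.  Tests: `python -m pytest -q` (unit, property, and acceptance
suites; the acceptance tests check every analysis against an independent
oracle — literal state-table transcription, brute-force path enumeration
and double-loop energies, closed-form constants, and generator ground
truth).
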