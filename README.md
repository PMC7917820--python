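# spikesom

Whole-body coordination analysis of volleyball spike kinematics with
self-organising maps (SOMs), hierarchical clustering and one-dimensional
statistical parametric mapping (SPM).

The package is aimed at movement scientists who want to ask, from
multi-segment motion-capture recordings of a discrete skill: *do
successful and faulty executions differ in their whole-body coordination
pattern, and if so, where in the movement and in which limb?*  It
implements the full analysis chain for a cohort of spikers (10 players,
6 spikes each, outcomes labelled successful/faulty), and ships a seeded
synthetic-cohort generator with the same statistical structure so the
entire pipeline can be exercised and validated without access to raw
motion-capture data.

## The method

Each trial is described by 32 kinematic channels (3D centre-of-mass
coordinates, 6 lower-limb and 8 upper-limb joint angles, 15
trunk/neck/head segment angles) sampled at 180 Hz.  Preprocessing
applies a zero-phase 4th-order Butterworth low-pass (10 Hz), trims each
trial from the plant phase (both feet grounded) to ball impact (abrupt
wrist deceleration), computes angular velocities by central differences,
and time-normalises both waveform sets to 101 points.  Per player, the
mean successful and mean faulty trial form the analysis sequences.

The coordination state at time *t* of sequence *i* is the vector

    v_i(t) = [psi_i,1(t) ... psi_i,32(t)  phi_i,1(t) ... phi_i,32(t)]

of range-normalised (−1..1) angles psi and velocities phi.  A Kohonen
SOM (hexagonal lattice, Gaussian neighbourhood, two-phase sequential
training) learns prototype states from the pooled time points of all
sequences; each sequence then maps to its best-matching-unit (BMU)
trajectory across the lattice, and sequences are compared by

    D[i,j] = sum_t || BMU_i(t) − BMU_j(t) ||^2 .

Average-linkage agglomerative clustering of D summarises which players'
patterns group together.  Independently, a node-wise two-sample t field
over the 101-point cycle compares successful vs faulty group velocity
waveforms per channel group, thresholded at alpha = 0.05 with a random
field theory correction derived from the residual smoothness (FWHM /
resel count), yielding significant windows in % of the movement.

## Worked example

```python
import spikesom as sp

trials, manifest = sp.generate_cohort(sp.SyntheticConfig(seed=0))
means = sp.condition_means([sp.preprocess_trial(t) for t in trials])
registry = sp.build_channel_registry()

# upper-limb angular-velocity SPM: successful vs faulty condition means
succ, fault = sp.velocity_group_fields(means, registry, "upper")
res = sp.spm_ttest2(succ, fault)
print(f"{len(trials)} trials -> {len(means)} condition means")
print(f"RFT threshold t* = {res.threshold:.2f} (df={res.df}, FWHM={res.fwhm:.1f} nodes)")
for c in res.clusters:
    print(f"  significant window {c.start_pct:.0f}%-{c.end_pct:.0f}%, peak |t| = {c.peak_t:.2f}")

# SOM + clustering on the whole-body coordination vectors
im = sp.assemble_input_vectors(means, registry, "whole", "both")
grid = sp.train_som(im, sp.SOMConfig(map_scale="small", seed=1))
trajs = [sp.bmu_trajectory(grid, im.sequences[i], im.ids[i])
         for i in range(im.n_sequences)]
dend = sp.agglomerate(sp.pairwise_distance_matrix(trajs), linkage="average")
pairing = {p: (f"{p}_succ", f"{p}_fault")
           for p in {m.player_id for m in means} if f"{p}_fault" in im.ids}
print(f"SOM grid {grid.rows} x {grid.cols}; "
      f"paired first-merge fraction = {sp.pair_merge_fraction(dend, pairing):.2f}")
```

prints

```
60 trials -> 19 condition means
RFT threshold t* = 3.57 (df=17, FWHM=12.7 nodes)
  significant window 36%-41%, peak |t| = 4.46
  significant window 77%-98%, peak |t| = 7.80
SOM grid 8 x 7; paired first-merge fraction = 1.00
```

The 60 trials collapse to 19 sequences because one player never faults.
The SPM flags the two windows where the generator injects the
successful/faulty difference into the upper-limb angular velocities
(around take-off and in the arm-acceleration phase before impact), while
whole-body and lower-limb comparisons stay below threshold.  A
first-merge fraction of 1.00 means every player's successful and faulty
patterns are each other's nearest neighbours in the dendrogram — each
player's coordination is individual and stable across outcomes.

The same pipeline is available from the shell:

```
spikesom simulate --seed 0 --out cohort/
spikesom run --manifest cohort/manifest.csv --out results/ --seed 0
spikesom spm --group-a a.csv --group-b b.csv --alpha 0.05
```

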