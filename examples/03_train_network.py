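"""Train the 4:3:3:1 perceptron with batch back-propagation on one phantom
cohort and watch the error descend.

The network regresses the normalized chronic-T2 intensity (range 0-3) of
each voxel from its four acute intensities; one weight update per epoch,
accumulated over every training case.
"""

import infarctnet as inf

cohort = inf.generate_cohort(4, seed=3, geometry=inf.GridSpec(3, (24, 24)),
                             model=inf.TissueModel(
                                 lesion=inf.LesionSpec(center=(12.0, 6.0), radius=3.0),
                                 csf_radius=1.5))
samples = inf.SampleSet.concatenate(
    [inf.preprocess_study(s, roi_threshold=1.4)[3] for s in cohort]
)
print(f"training on {len(samples)} voxels from {len(cohort)} subjects")

arch = inf.NetworkArchitecture()  # 4:3:3:1 with a bias unit per layer
config = inf.TrainingConfig(learning_rate=0.01, momentum=0.0, seed=0,
                            max_epochs=2000, termination_mse=0.06)
model, trace = inf.train(samples, arch, config)

print(f"architecture {arch.layers}, {arch.n_parameters} free parameters")
for e in (0, 9, 99, trace.n_epochs - 1):
    if e < trace.n_epochs:
        print(f"  epoch {e + 1:4d}: MSE {trace.mse[e]:.4f}  CCF {trace.ccf[e]:.3f}")
print(f"stopped after {trace.n_epochs} epochs "
      f"({'reached' if trace.converged else 'did not reach'} MSE 0.06)")

# MSE falls from ~0.3 (untrained) toward the target noise floor; the CCF
# (fraction of voxels predicted within the same 0.05 intensity window as the
# observed chronic value) rises as predictions sharpen.
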