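# megjoint

Multi-subject MEG source estimation on synthetic retinotopy experiments.

MEG source localization is an ill-posed inverse problem: the evoked
magnetic field pattern `Y = L X + E` (with leadfield `L`, source
amplitudes `X`, noise `E`) does not determine `X` uniquely, and
single-subject estimates of early visual responses typically land
~20 mm from their true cortical origin. Pooling subjects helps, and this
package implements and compares three ways of doing so:

1. **eLORETA with source-space averaging** — each subject is inverted
   with the weighted minimum-norm operator

   `W = D⁻¹ Lᵀ (L D⁻¹ Lᵀ + λ²Σ)⁻¹`,  `dᵢ = √(Lᵢᵀ (L D⁻¹ Lᵀ + λ²Σ)⁻¹ Lᵢ) / x₀`,

   with `λ² = 1/SNR²` and the weights `dᵢ` iterated to their fixed
   point (zero single-dipole localization error); the per-subject
   magnitude maps are then averaged vertex-wise on a shared template.
2. **Minimum Wasserstein estimates (MWE)** — all subjects are inverted
   jointly:

   `min Σₛ [ 1/(2n) ‖Yˢ − LˢXˢ‖² + λ‖Xˢ‖_q^q + (μ/S)·W(Xˢ, X̄) ]`,  `q = ½`,

   where `W` is a generalized (signed, unbalanced, entropic)
   Wasserstein distance on the cortical mesh and `X̄` the barycenter of
   the subject estimates — sparsity per subject, spatial agreement
   across subjects.
3. **MWE with source-space averaging** — the absolute values of the
   per-subject MWE estimates averaged vertex-wise.

Accuracy is scored by the geodesic distance between each estimated peak
and the ground-truth target vertex, Winsorized at 80 mm (wrong-hemisphere
peaks count as outliers), summarized as mean/median/std per method and
group size.

Because real multi-subject MEG/MRI datasets of this kind cannot be
redistributed, the package ships a synthetic generator that emulates the
statistical structure of a multifocal retinotopic mapping study: a
two-hemisphere icosphere template, a 24-region dartboard stimulus
(3 eccentricity rings × 8 polar wedges, vertical-meridian wedges driving
both hemispheres), analytic spherical-conductor (Sarvas) leadfields with
per-subject anatomical jitter, evoked responses peaking near 83 ms at an
amplitude SNR of 2, and 1806 stimulus flashes of bookkeeping per region.
Ground truth is known by construction, so localization error is exact.

## Worked example

```python
import megjoint as mj
from megjoint.evaluate import PipelineConfig, run_pipeline

cfg = PipelineConfig(n_subjects=10, group_sizes=(1, 10),
                     methods=("elora_avg",))
table, manifest = run_pipeline(cfg, master_seed=1)
print(table.summary().to_string(index=False))
```

prints

```
   method  group_size   mean_mm  median_mm    std_mm
elora_avg           1 23.094795  27.248772 24.401344
elora_avg          10 16.268566  10.247151 17.415548
```

Read: with a single subject the median peak misses its retinotopic
target by ~27 mm (several stimulus sectors away — neighbouring targets
are ~10–25 mm apart); averaging ten subjects' eLORETA maps on the
template cuts the median error to ~10 mm. The manifest records the
representative subject, the nested group ordering, each subject's
median peak time, and any calibrated MWE hyperparameters.

The same pipeline is scriptable from the shell:

```bash
megjoint simulate --subjects 10 --seed 1 --out exp.h5
megjoint evaluate --subjects 10 --seed 1 --group-sizes 1,10 \
    --method elora_avg --out results/
megjoint report --results results/
```

`megjoint calibrate` and `megjoint invert` expose the MWE
hyperparameter searches and single inversions on a saved container.

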