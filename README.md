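# facmri

Fatty-acid composition (FAC) mapping of adipose tissue from
chemical-shift-encoded multi-echo gradient-echo MRI.

The proportions of saturated, monounsaturated and polyunsaturated fatty
acids (fSFA, fMUFA, fPUFA) in adipose tissue are a cardiometabolic risk
marker traditionally measured by gas chromatography of biopsies. Multi-echo
water-fat MRI can estimate them non-invasively: the fat proton spectrum is
a known function of the mean number of double bonds (*ndb*) and of
methylene-interrupted double bonds (*nmidb*) per triglyceride, so fitting a
multi-peak spectral model to the complex echo train recovers the
composition in every voxel. `facmri` implements this pipeline end to end —
signal model, voxel-wise estimation, fraction maps, depot segmentation,
group statistics — together with a digital abdominal phantom and two-group
cohort simulator for fully synthetic validation.

## Model

With an eight-resonance triglyceride spectrum at fixed chain length
(cl = 17.3) the signal of a voxel at echo time *t* is

    S(t) = [ W + F f Σₘ αₘ(ndb, nmidb) e^{iωₘt} ] e^{Ψt},      Ψ = i2πψ − R2*

where *W*, *F* are complex water and fat amplitudes, αₘ the proton
amplitude of resonance group *m* (linear in *ndb* and *nmidb*; the bulk
methylene amplitude is 6(cl−4) − 8 ndb + 2 nmidb, i.e. 79.8 − 8 ndb + 2 nmidb),
f = 1/Σαₘ, ψ the B0 field map and R2* the effective transverse relaxation
rate. Regrouping terms makes the model linear in W, Ff, Ff·ndb and
Ff·nmidb, so the fit uses variable projection: exact linear least squares
inside a multi-start grid search plus trust-region refinement over
(ψ, R2*). Assuming at most two double bonds per fatty acid,

    fSFA = 1 − (ndb − nmidb)/3,  fMUFA = (ndb − 2·nmidb)/3,  fPUFA = nmidb/3.

Fat-fraction maps are F/(W+F); analysis ROIs keep depot voxels with
FF > 0.9 and T2* > 20 ms. Subcutaneous fat is grown as a connected
high-FF component, the visceral depot is cut from a manually supplied
cavity polygon, and the posterior subcutaneous ring can be split into deep
and superficial compartments along a fascia polyline. Depot-level group
differences use two-sided Wilcoxon rank-sum tests, within-subject depot
contrasts Wilcoxon signed-rank tests.

## Worked example

Fit a single subcutaneous-fat voxel simulated at the default acquisition
(12 echoes, TE1/ΔTE = 1.13/1.56 ms, 3 T):

```python
from facmri import (AcquisitionSpec, FatModelSpec, TriglycerideParams,
                    VoxelSignalParams, forward_signal, fit_voxel,
                    fractions_from_double_bonds)

acq, model = AcquisitionSpec(), FatModelSpec()
truth = VoxelSignalParams(
    water=5 + 0j, fat=95 + 0j,
    triglyceride=TriglycerideParams(ndb=2.56, nmidb=0.48),
    field_map_hz=20.0, r2star=35.0,
)
est = fit_voxel(forward_signal(truth, acq, model), acq, model)
frac = fractions_from_double_bonds(est.ndb, est.nmidb)
print(f"ndb   = {est.ndb:.4f}   nmidb = {est.nmidb:.4f}")
print(f"fSFA  = {float(frac.fsfa):.4f}  fMUFA = {float(frac.fmufa):.4f}  fPUFA = {float(frac.fpufa):.4f}")
```

prints

```
ndb   = 2.5600   nmidb = 0.4800
fSFA  = 0.3067  fMUFA = 0.5333  fPUFA = 0.1600
```

i.e. the fit recovers the simulated composition exactly on noiseless data,
and the fractions follow from the double-bond counts — a voxel with
nmidb = 0.48 carries a PUFA fraction of 0.160. Under complex Gaussian
noise at SNR 50 the per-voxel precision is limited by the acquisition
itself (median absolute error ≈ 0.12 in ndb; see `docs/methods.md`), which
is why depot summaries average the maps over ROIs of many voxels.

The same pipeline runs from the shell on synthetic cohorts:

```sh
facmri run-all --config examples/cohort.yaml --out results/
```

writing a per-subject depot table and a comparison table with medians,
interquartile ranges and raw p-values per depot and parameter.

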