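# smfsid

Classification and Bayesian identification of membrane proteins from AFM
single-molecule force-spectroscopy (SMFS) force-distance curves.

When an AFM tip pulls a single membrane protein out of a native membrane
patch, the retraction force-distance (F-D) curve shows a sawtooth of rising
worm-like-chain (WLC) branches, one per unfolding intermediate.  In a native
membrane the harvested curves are a heterogeneous bundle: most show no
binding, some are membrane tethers or multiple attachments, and only a small
fraction are clean single-protein unfoldings — of unknown identity.  `smfsid`
implements the full desk-side analysis for such batches:

1. **Preprocessing** — baseline zeroing from the non-contact tail, piezo →
   tip-sample-separation conversion (`s = z − F/k`), contact-point alignment,
   resampling on a 1-nm grid, and coarse rejection (no contact point, force
   range beyond 5000 pN, wavy tails above `2σ_NOISE`).
2. **WLC quality score** — each point `(x, F)` with `30 ≤ F ≤ 500` pN is
   inverted through the WLC interpolation formula
   `F(x) = (k_B T / l_p) [¼(1 − x/L_c)⁻² − ¼ + x/L_c]` (`l_p = 0.4` nm) to a
   contour length `L_c`; the `L_c` histogram (8-nm bins) is scored per peak
   with `W = exp(−2 f²)`, `f = ½(P_left/P_max + P_right/P_max)`, and traces
   whose score-to-length ratio falls below 0.5 are discarded.
3. **Pairwise distances** — dynamic-programming global alignment of the force
   profiles with match score `1 − |ΔF|/F_scoring` (else `−|ΔF|/F_scoring`),
   `F_scoring = 4σ_NOISE`; distance `d_ab = 1 − SD/N_max`, computed only for
   pairs compatible in peak count (≤ 2) and length (≤ 20%).
4. **Density-peak clustering** — `ρ_i = quality_i · (−log r_{k,i})`,
   `δ_i = min_{ρ_j > ρ_i} d_ij`, centers chosen by descending `γ = ρδ` with a
   minimum center separation `r_cut = 0.3`, members assigned via the nearest
   denser neighbour.
5. **Refinement** — each center and its two nearest neighbours rasterised
   into an "area of similarity" (5 nm × 5 pN cells); candidate curves with a
   compatible final peak (0.7–1.3 × center length) are scored by points
   inside the area, thresholded at the knee of the sorted-score curve, and
   clusters sharing > 40% of above-threshold traces are merged.
6. **Bayesian identification** — per cluster, each proteome protein `A` gets

   `P(A | cluster) ∝ P(Lc_max | L_A) · P(F̄ | class_A) · P(peaks | loops_A) · P(A)`

   with prior `abundance_A × ismembrane_A`, a Gaussian `L_c` likelihood
   centred at `0.89 L_A` (σ = 0.10 L_A; uniform over the terminal-domain
   range when that domain is long), a per-structure-class force density, and
   the lag-optimised cross-correlation between the cluster's unfolding-peak
   profile and 15-nm-FWHM Gaussians at the protein's loop positions.

A synthetic-data module generates WLC sawtooth curves, premature
detachments, multiple-attachment (spurious) traces, tether plateaus,
abundance-weighted mixtures, and matching proteome tables, so the whole
pipeline is testable without instrument data.

The clustering and identification stages are scikit-learn-style estimators
(`DensityPeakClustering`, `BayesianProteinIdentifier`, `SmfsPipeline`) and
compose with sklearn tooling.

## Worked example

Simulate a 1:1:1 mixture of three template proteins (150 curves, 10 pN
noise), run the pipeline, and identify each cluster against the paired
synthetic proteome (3 templates + 10 decoys):

```python
import numpy as np
from smfsid import synthetic as syn, run_pipeline

templates = syn.example_templates(3)
cfg = syn.SimulationConfig(seed=42, premature_detach_fraction=0.0)
curves, labels = syn.simulate_dataset(templates, [1, 1, 1], 150, cfg)
proteome = syn.synth_proteome(templates, n_decoys=10, rng=np.random.default_rng(42))

res = run_pipeline(curves, proteome=proteome)
print(f"sigma_NOISE = {res.sigma_noise:.1f} pN")
for cid in sorted(res.refined.clusters):
    obs = res.refined.observables[cid]
    top = res.posteriors[cid].rows[0]
    print(f"cluster {cid}: n={obs.n_members:3d}  Lc_max={obs.lc_max:6.1f} nm  "
          f"F_mean={obs.mean_force:5.0f} pN  ->  {top['protein_id']} (p={top['posterior']:.2f})")
```

Output:

```
sigma_NOISE = 10.0 pN
cluster 0: n= 44  Lc_max= 204.9 nm  F_mean=  124 pN  ->  tplC (p=0.99)
cluster 1: n= 43  Lc_max=  78.1 nm  F_mean=  130 pN  ->  tplA (p=0.99)
cluster 2: n= 53  Lc_max= 127.9 nm  F_mean=  126 pN  ->  tplB (p=1.00)
```

The three unfolding patterns are recovered as three pure clusters (~50
curves each, matching the 1:1:1 mixing ratio); `Lc_max` reproduces each
template's last unfolding barrier (80, 130, 210 nm) and the posterior places
the generating template first in every case.

The same run is available from the shell:

```sh
smfsid simulate --n-total 150 --seed 42 --out simdir
smfsid run-all --curves simdir/curves --proteome simdir/proteome.tsv --out results/
smfsid identify --proteome simdir/proteome.tsv --lc-max 210 --mean-force 120
```

## Layout

- `smfsid.fd_io` — curve/proteome/report I/O (TSV dialects, manifest CSV)
- `smfsid.preprocess` — Block 1: baseline, separation transform, filtering
- `smfsid.wlc_transform` — WLC force law and contour-length inversion
- `smfsid.quality_score` — Block 2: Lc histogram, peak score W, quality cut
- `smfsid.trace_distance` — Block 3: alignment distances (numba DP kernel)
- `smfsid.density_clustering` — Block 4: density-peak clustering estimator
- `smfsid.cluster_refinement` — Block 5: area of similarity, merging,
  cluster observables
- `smfsid.bayes_identify` — priors, likelihoods, posterior tables,
  sampling-yield assessment
- `smfsid.synthetic` — synthetic curve/proteome generator
- `smfsid.cli_pipeline` — `RunConfig`, `run_pipeline`, `SmfsPipeline`, CLI

See `docs/methods.md` for the modelling choices, parameter defaults and
known limitations.
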