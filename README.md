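# kymodiff

Single-molecule 1D diffusion analysis for proteins scanning stretched DNA.
The package covers the full analysis chain used in optical-tweezers /
confocal-scanning experiments, together with a synthetic ground-truth
generator so that every stage can be validated closed-loop without any
experimental data:

- **simulate** — Brownian trajectories at a chosen diffusion coefficient with
  reflecting walls, point roadblocks (reflect / stick / cross outcomes drawn
  per encounter), exponential photobleaching and unbinding; photon-level
  kymograph rendering (Poisson signal through a Gaussian PSF plus Poisson
  background); exponential binding-event streams; worm-like-chain
  force–extension curves with discrete nucleosome-unwrapping steps.
- **tracking** — per-scan-line Gaussian centroid fitting of kymographs with
  gap interpolation and segment splitting, plus the closed-form localization
  precision `sigma^2 = s^2/N + a^2/(12N) + 8*pi*s^4*b^2/(a^2*N^2)`.
- **msd** — time-averaged MSD with overlapping windows, an adaptive linear
  fit of the initial portion (windows scanned for slope p < 0.05, highest r^2
  wins; negative slopes clamped to D = 0; per-condition outlier and r^2
  refinement), anomalous-exponent fits `MSD = D*t^alpha`, saturating-plateau
  fits with confinement lengths, and ensemble statistics (median D with
  `SEM*sqrt(pi/2)` uncertainty, mobile fraction with a 5000-resample
  percentile bootstrap CI).
- **segmentation** — sliding-window (0.4 s) instantaneous diffusion with
  fast / medium / slow-immobile categories and immobile dwell episodes.
- **kinetics** — on-rates from first-arrival times (exponential MLE / molar
  concentration, per-basepair normalization), bound lifetimes from
  Kaplan–Meier survival curves fit to exponential decay (half-life = tau ln 2),
  and photobleaching correction by extrapolating apparent off-rates to zero
  laser power.
- **coloc** — dual-color roadblock encounter analysis: roadblock traces
  extended past photobleaching by their mean position, episodes classified as
  reflected / stuck / crossover.
- **force** — nucleosome counting from force–distance curves: running-median
  step detection in the 15–30 pN unwrapping window, and a compaction count
  from the tether lengthening at 5 pN (34.6 nm per nucleosome).
- **theory** — closed-form upper limits of 1D diffusion from molecular mass:
  radius from the partial specific volume, Stokes friction without rotation,
  and helically coupled sliding friction (one turn per 3.4 nm) with the
  center-of-mass offset `R_oc`; scan-time and length-per-basepair helpers.

## Command line

`kymodiff` exposes one subcommand per stage; every stochastic command takes
`--seed` and records it in its outputs.

```bash
kymodiff theory --mass-da 1e6                     # diffusion limits table
kymodiff simulate --d-true 0.024 --n-traces 100 \
    --noise-um 0.082 --seed 1 --out run/          # trajectories.csv
kymodiff msd --traj run/trajectories.csv --out run/   # estimates + ensemble
kymodiff render --d-true 0.024 --seed 1 --out run/    # kymograph TIFF + truth
kymodiff track --kymo run/kymograph.tiff --out run/
kymodiff segment --traj run/trajectories.csv --out run/
kymodiff count-nucs curve.csv --per-nuc-nm 34.6
kymodiff all --config config.yaml --out run/      # simulate->render->track->msd
```

Trajectories and event tables are plain CSV; kymographs are 16-bit TIFF with
a JSON sidecar carrying `pixel_size_um` / `line_time_s`; run manifests echo
parameters, seeds and artifact lists.

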