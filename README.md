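# pausim

Simulation and reconstruction toolkit for fast-sweep spectroscopic
photoacoustic/ultrasound (PAUS) imaging. Instead of broad-beam illumination,
a narrow laser beam is swept over 20 fibers surrounding a linear ultrasound
array at a kHz pulse rate; a partial PA image is beamformed for every firing
and the full image is the coherent sum of the partial images. The package
simulates this acquisition on synthetic phantoms and implements the full
processing chain it enables:

- **core** — probe/fiber geometry, scan sequencing (timing identities such
  as a 20 ms single-wavelength frame for 20 fibers at 1 kHz), image grids;
- **scene** — synthetic phantoms: chromophore spectra (nanorod-like
  resonance, sloped ink-like, flat), optical property maps, dense speckle
  scatterers, ground-truth motion models;
- **optics** — diffusion-approximation fluence (`exp(-mu_eff r)/(4 pi D r)`,
  `D = 1/(3 mu_s')`) and skin laser-safety (MPE) limits;
- **acoustics** — per-channel RF simulation (one-way PA, pulse-echo US) with
  exact carrier phase, element directivity and additive noise;
- **beamform** — delay-and-sum PA sub-images and B-mode frames, coherent
  compounding;
- **tracking** — PatchMatch speckle tracking between B-mode frames,
  displacement accumulation to a reference frame, image warping;
- **spectral** — per-fiber amplitude-based fluence estimation (brute-force
  grid search with a Beer's-law bracket), fluence compensation, laser-off
  noise-floor subtraction, wavelength compounding, and component-weighted
  imaging by correlation with a reference spectrum;
- **io / pipeline / cli** — HDF5 dataset container, spectrum CSV I/O, seeded
  substreams, end-to-end orchestration and the `paus` command line.

## CLI

```bash
paus mpe -w 700 -w 1064                      # laser-safety limit table
paus run --seed 1 -o out.h5                  # full pipeline on the demo scene
paus run -c my_config.yaml --seed 1 -o out.h5 --png-dir pngs
# or stage by stage:
paus simulate -c my_config.yaml --seed 1 -o ds.h5
paus reconstruct ds.h5
paus track ds.h5
paus spectra -r gnr -r ink ds.h5
```

Configs are YAML with sections `probe`, `fibers`, `sequence`, `grid`,
`phantom`, `noise`, `tracking`, `spectral`, `references`; all lengths in mm
(see `pausim.pipeline.demo_config()` for a complete example). Reference
spectra can be built-in chromophore names or CSV files with columns
`wavelength_nm,value`.

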