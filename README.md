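# bips — bridging-induced phase separation of DNA-binding proteins

Tools for studying how multivalent DNA-binding proteins (SMC complexes such
as cohesin) condense DNA into clusters by *bridging-induced phase
separation* (BIPS): a protein that holds two or more DNA segments raises
the local DNA concentration, which recruits more protein — a positive
feedback that needs no protein–protein attraction at all.

The package is aimed at single-molecule biophysicists and polymer
modellers. It provides:

- a coarse-grained Brownian-dynamics simulator of a semiflexible DNA chain
  (FENE bonds, Kratky–Porod bending with persistence length l_P = 50 nm,
  WCA excluded volume) with diffusing bridge particles holding at most
  *n* ∈ {2, 3, ~10} simultaneous DNA bonds (Metropolis binding kinetics,
  numba-compiled inner loop);
- the cluster-size analysis of the BIPS scaling law: below the critical
  looping length l_C = 2π²l_P ≈ 987 nm ≈ 2903 bp the cluster radius of
  gyration R_G is DNA-length independent, above it R_G ~ l^α with an
  exponent α that reports the condensate architecture (1/3 collapsed
  globule, ~0.45 porous bivalent condensate, 1/2 ideal chain);
- in-silico Hi-C contact maps and a compartment (checkerboard) strength
  score;
- the fluorescence-trace toolbox used for DNA–protein condensates on
  tethered DNA: kymographs, cluster size in kbp, 5–95% compaction times,
  FRAP/dissociation exponential fits, photobleaching step counting and
  stoichiometry;
- AFM height-map analysis: grain volumetry, mean + 7·SD cluster
  thresholding, stoichiometry by volume division, DNA-bridging
  classification;
- seeded synthetic-data generators with ground truth for every input class.

## Worked example

Dissociation kinetics of condensate proteins after a high-salt wash,
emulated and fitted from the shell:

```sh
bips synth --kind exponential --seed 3 --out wash \
    -p tau=41.9 -p kind=decay -p noise_sd=0.05 \
    -p frame_interval=3.5 -p n_frames=120
bips traces dissociation --trace wash/trace.tsv --out wash/fit.json
```

prints

```json
{
 "tau_s": 42.86461330894388,
 "tau_sd_s": 2.151711311471392,
 "amplitude": 0.9846765151077861,
 "baseline": -0.002282248891311803,
 "kind": "decay"
}
```

— the generator planted a 41.9 s single-exponential decay under 5%
amplitude noise; the fit returns 42.9 ± 2.2 s, i.e. the time constant is
recovered within its standard error.

Fitting the two-regime cluster-size law to a table of (DNA length, cluster
R_G) measurements:

```sh
bips scaling --table afm_rg.tsv --out fit.json
```

```json
{
 "exponent": 0.420087166589277,
 "exponent_sd": 0.007449843115638239,
 "breakpoint_bp": 2449.489742783179,
 "constant_level": 20.173950351105884,
 "fallback_single_power_law": false,
 "critical_looping_length_nm": 986.9604401089358,
 "critical_looping_length_bp": 2903
}
```

Here the input table was synthetic data constructed flat at ~21 nm below
3 kbp with a 0.45 power law above and 5% lognormal scatter: the broken-stick
fit places the breakpoint at 2.4 kbp (vs. 3 kbp planted), recovers the
exponent 0.42 ± 0.01, and reports the analytic critical looping length
2π² · 50 nm = 987 nm = 2903 bp for comparison.

Simulations run from Python (see `bips.protocols` for the standard
campaigns) or from the shell, e.g. a bivalent-bridge run of a 3.3-kbp
chain:

```sh
bips simulate --n-beads 113 --valence 2 --n-steps 200000 \
    --chain-init compact --bridge-placement near_chain \
    --seed 1 --out run1
```

which writes the trajectory (extended XYZ + bond lists) and the
largest-cluster R_G time series.

## Acceptance script

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

re-runs, from scratch, the package's three headline simulation
measurements — the cluster-size scaling exponent for trivalent bridges,
the same for multivalent (~10-site) bridges, and the ideal-polymer control
(no excluded volume, no bridges) — and writes the fitted exponents to the
JSON file. Runtime is roughly 8–10 minutes on one CPU; all randomness
derives from `--seed`.
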