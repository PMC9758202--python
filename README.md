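# mochafrap

Model-free calibrated half-FRAP (MOCHA-FRAP) analysis of membrane-less
cellular structures: does a fluorescent protein in a punctate structure
undergo liquid–liquid phase separation (LLPS), or is it merely binding to
spatially clustered sites (ICBS) on an immobile scaffold?  Classical full-
and partial-FRAP cannot tell the two apart; bleaching *half* of the
structure and jointly analysing both halves can.

The package is written for microscopists and quantitative cell biologists
who record confocal FRAP time series, and for modellers who want the
closed-form reaction–diffusion solutions behind the assay.

## The statistic and the models

After bleaching one half of a circular structure, the normalised signal of
the non-bleached half transiently *decreases* as unbleached molecules mix
into the bleached half.  The maximum fractional decrease — the **dip
depth** — is read model-free from the smoothed curve:

```
dip = 1 − min_t S_NB(t)
```

Its interpretation rests on three closed-form scenarios for diffusion in a
circle (all Bessel-eigenfunction series, all implemented in
`mochafrap.theory` and independently verified by a finite-difference
solver in `mochafrap.oracle`):

* **LLPS** — diffusion with coefficient `D_app` inside a circle of radius
  `R` whose interface attenuates the outgoing flux (Robin condition
  `−D ∂c/∂r = D h c` at `r = R`).  The dip grows with the boundary
  strength `h⁻¹`, from the transparent-boundary limit up to 0.5 for an
  impermeable interface, and is independent of `D_app` — only the
  interfacial barrier sets it.
* **free diffusion** — a fully permeable bleach circle `R_C` inside a
  large reflecting domain `R_L`: the no-interface reference.
* **ICBS** — free diffusion plus pseudo-first-order binding
  (`k*_on`, `k_off`) to immobile sites.  Dips are *at or below* the free
  reference: equal to it for fast binding (effective diffusion with
  `D_eff = D/(1 + k*_on/k_off)`), vanishing for strong slow binding.

So: dip significantly **above** the free-diffusion reference ⇒ an
interfacial barrier (LLPS); dip at or below it ⇒ ICBS-consistent.

A calibration chain turns the dip into an energy: droplet-coalescence
relaxation times give the inverse capillary velocity `η/γ`, FCS-derived
diffusion times give the viscosity `η`, hence the interfacial tension
`γ = η/(η/γ)` and the interfacial energy per molecule
`ΔG = γ·2πR_h²`.  The sigmoidal master relation dip(ΔG) is fitted and
inverted to report an apparent barrier (in kT) for any measured dip.

## Worked example

Simulate ten half-FRAP experiments on a 2 µm condensate with a moderate
interfacial barrier (`h = 0.1 µm⁻¹`, i.e. boundary strength
`h⁻¹ = 10 µm`), then run the processing chain:

```sh
mochafrap simulate --model llps --R 2 --h 0.1 --D 0.05 \
    --n-experiments 10 --frames 300 --noise 0.02 --seed 7 --out traces/
mochafrap process --mode half --traces traces/ --out result.json
```

The log line and `result.json` report

```
dip 0.370, p=3.8e-09 -> LLPS

dip_depth        0.3701978053035585
sem              0.02316969086357582
n                10
argmin_time_s    45.6
p_value          3.782288356134953e-09
classification   LLPS
```

— a dip of 37 ± 2 % at 45.6 s, far above the packaged free-diffusion
reference of 10 ± 3 % (one-sided Student's t-test, p ≈ 4·10⁻⁹), hence the
LLPS call.  Converting that dip into an energy with the packaged
*synthetic* example master curve and a 2 nm hydrodynamic radius:

```sh
mochafrap barrier --dip 0.3702 --dip-sem 0.012 --rh 2.0 --seed 1
```

```json
{"status": "ok", "energy_kT": 0.079, "ci_kT": [0.065, 0.101],
 "gamma_app_uJ_per_m2": 12.9}
```

an apparent interfacial barrier of ~0.08 kT.  (Real analyses should
supply their own measured calibration points via `--points`.)

The same operations are available as library calls
(`mochafrap.llps_curves`, `mochafrap.dip_depth`,
`mochafrap.fit_master_curve`, …); see the module docstrings.

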