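# jnktransport

A deterministic reaction–diffusion–advection simulator of **scaffold- and
motor-assisted kinase transport along an axon**, built around the JNK MAP
kinase cascade: JNK and its activating kinase MKK7 assemble on the JIP1
scaffold, the loaded scaffold binds the kinesin motor KIF5, and the cargo
is carried from the cell body (`x = 0`) toward the periphery (`x = L`)
while free proteins merely diffuse.  The package is for quantitative cell
biologists and modelers who want to ask when cytoskeletal transport beats
diffusion at delivering an activated kinase to a distant terminal — and
when it fails (too few scaffolds, too many scaffolds, motors too slow,
motors faster than cargo loading).

## Model in brief

Fifteen species obey mass-action kinetics in every mesh cell of a 1-D
domain, with species-specific mobility (diffusive / motor-advected /
immobile free motor).  Two dimensionless knobs position an experiment:

* σ = [JIP1]₀ / [JNK]₀ — scaffold abundance,
* Pe = v·L / D_JNK — motor speed relative to diffusion,

and two metrics score it, both read from free JNK* in the terminal cell:

* signaling rate R = 1 / t_max (inverse time of the peripheral peak),
* signal amplification A = peak / (σ = 0, Pe = 0 baseline peak).

The (σ, Pe) plane splits into four regimes: (1) motors slower than
diffusion, (2) no scaffold, (3) effective motor delivery, (4) transport
present but futile.  Amplification is biphasic in both σ and Pe, so an
optimal scaffold concentration and an optimal motor speed exist; their
location shifts with phosphatase (M3/6), motor (KIF5) and kinase (JNK)
abundance.  See `docs/methods.md` for equations, parameters and numerics.

## Worked example

```python
import jnktransport as jt

# pure-diffusion baseline vs a scaffold+motor run on the default scenario
base = jt.run_simulation(jt.default_scenario(0.0, 0.0, t_end=10_000))
run  = jt.run_simulation(jt.default_scenario(2.0, 5.0, t_end=6_000))

for name, kymo in [("diffusion only", base), ("sigma=2, Pe=5", run)]:
    t, s = jt.peripheral_series(kymo)
    m = jt.signaling_rate(s, t)
    print(f"{name:15s} peak {m.peak_conc:.4f} uM at t = {m.t_max:.0f} s")
print("amplification:",
      round(jt.signaling_rate(*jt.peripheral_series(run)[::-1]).peak_conc /
            jt.signaling_rate(*jt.peripheral_series(base)[::-1]).peak_conc, 3))
```

prints (default 200-cell mesh, L = 100 µm):

```
diffusion only  peak 0.0100 uM at t = 2219 s
sigma=2, Pe=5   peak 0.0168 uM at t = 491 s
amplification: 1.669
```

i.e. with scaffolds at twice the kinase level and motors five times faster
than diffusion, the periphery sees ~1.7× more active JNK, ~4.5× sooner.

The same from the shell:

```sh
jnktransport simulate --sigma 2 --pe 5 --out out/run
jnktransport scan --sigma-grid 0,0.5,1,2,3 --pe-grid 0,2,5,10 --out out/scan
jnktransport sensitivity --species KIF5 --levels 0.5,1,2 --out out/sens
```

`scan` writes a long-format phase diagram (σ, Pe, rate, amplification,
region label) and resumes partially completed grids; every command writes
a JSON manifest with the scenario hash, chosen dt and any clamped mass.

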