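# dyneinloc

**Where, in a beating cilium or flagellum, are the force-generating dyneins?**

Cilia and flagella beat because axonemal dynein motors slide adjacent
microtubule doublets past each other; sliding is converted into bending by
constraints at the base. A long-standing question in the field is which
conformational states of dynein actually generate force — and answering it
by cryo-EM requires knowing *where along a beating axoneme*, relative to the
bends, the active motors sit. `dyneinloc` answers that question with a
molecular-mechanics moment balance: it predicts (and, inversely, infers from
a waveform) the spatial relationship between the differential dynein force
density f(x,t) and the curvature C(x,t).

The package is aimed at axoneme biophysicists and cryo-EM structural
biologists who want to connect observed waveforms to motor activity.

## The model

Each dynein exerts a minus-end-directed force −F x̂ at a moment arm
a (~30 nm), producing a point bending moment. Summing motor moments against
the elastic restoring moment of the axonemal beam (flexural rigidity κ,
beam equation M = −κC with C ≅ ∂²y/∂x²) and the resistive-force-theory drag
(normal drag coefficient ξₙ) yields the moment-density balance

    a ∂f/∂x = −ξₙ ∂y/∂t − κ ∂⁴y/∂x⁴,

where f = f_l − f_r is the force density on the DM6-9 side of the axoneme
minus the DM1-4 side. For a traveling wave y = y₀ sin[2π(x/λ − νt)] the
force is also sinusoidal, f = f₀ sin[2π(x/λ − νt) + φ], with

    φ = arctan(1/Ma),        Ma = ν ξₙ λ⁴ / ((2π)³ κ),

the **Machin number** — the ratio of hydrodynamic to elastic moment
densities. The curvature lags the force in time by π − φ: π/2 in the
elastic limit (Ma ≪ 1, e.g. *Chlamydomonas*), 3π/4 (135°) at Ma = 1
(sperm-like), approaching π when drag dominates. Because φ sets where force
extrema sit relative to bends, measuring the force–curvature phase of a
waveform identifies the active dyneins' location — and, inverted, the
Machin number itself.

## Worked example

Fit the moment balance to a synthetic *Chlamydomonas*-scale beat
(λ = 10 μm, ν = 50 Hz, y₀ = 0.2 μm; κ = 800 pN·μm², ξₙ = 10⁻³ pN·s/μm²,
a = 0.03 μm):

```python
from dyneinloc import MachinModel, WaveSpec, chlamydomonas_defaults, machin_number, synthetic

params = chlamydomonas_defaults(xi_n=1e-3)
wave = WaveSpec(lam=10.0, nu=50.0, y0=0.2)
print("Ma =", machin_number(params, wave))

w = synthetic.generate(wave, params)           # sampled y(x,t), 128 x 32
res = MachinModel(w, params).fit()
print(res.summary())
```

Output:

```
Ma = 0.0025196511275937103
Machin moment-balance fit
==========================================================
grid (nt x nx)                    (32, 128)
wavelength [um]                   10
force-vs-amplitude phase [deg]    89.86 +/- 0.00
curvature lag behind force [deg]  90.14
spatial lag [wavelengths]         0.2504
spatial lag [um]                  2.5040
Machin number estimate            0.00252
----------------------------------------------------------
region [um]       bend class    active dyneins
0.00-0.16         straight      DM6-9
0.23-4.77         reverse       none
4.84-5.16         straight      DM1-4
5.23-9.77         principal     none
9.84-9.92         straight      DM6-9
```

Reading it: at this beat Ma ≈ 0.0025 ≪ 1, so elasticity dominates; the
inferred force leads the amplitude by ~90° and the curvature extrema carry
*no* differential motor activity — the active DM6-9 and DM1-4 dyneins sit
in the straight regions a quarter wavelength away from the bends they are
creating. The fitted Machin number (0.00252) recovers the generating value
to three digits. As Ma grows the spatial lag climbs from ¼ toward ½
wavelength (⅜ at Ma = 1), moving the active motors into the bends
themselves.

The same pipeline is available from the shell:

```bash
dyneinloc phase --ma 1                 # 45 deg force lead, 135 deg curvature lag
dyneinloc simulate --params p.json --wave w.json --out wave.csv
dyneinloc infer-force --waveform wave.csv --params p.json \
    --out-force force.csv --out-report report.json
dyneinloc pair-bend --x-left 4 --x-right 6 --out bend   # the 0.0002 1/um bend
```

## Layout

| module                   | contents                                                        |
| ------------------------ | --------------------------------------------------------------- |
| `dyneinloc.core`         | parameter containers, unit conventions, Machin number           |
| `dyneinloc.geometry`     | 9-doublet arm vectors, dynein moments, numbering conventions    |
| `dyneinloc.discrete`     | single/pair dynein moments, beam bends, normal forces           |
| `dyneinloc.continuum`    | static/hydrodynamic/full force balances and the residual        |
| `dyneinloc.travelling`   | closed-form traveling-wave solution and phase relations         |
| `dyneinloc.inference`    | `MachinModel`/`MachinResults`: force inference and localization |
| `dyneinloc.synthetic`    | waveform generator and pair-scenario presets                    |
| `dyneinloc.io`, `cli`    | CSV/JSON formats, SI converters, `dyneinloc` command            |

See `docs/methods.md` for the modelling assumptions, numerical choices and
limitations.
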