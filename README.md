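# sedflux

Reconstruction of trace-element and mercury pollution histories from
²¹⁰Pb-dated lake sediment cores.

Lake sediments archive the deposition of potentially toxic elements
(V, Cr, Co, Ni, Cu, Zn, As, Cd, Pb, Hg) over the past ~250 years — long
before monitoring began.  Turning a sliced core into a pollution history
takes a chain of steps that paleolimnologists and environmental
geochemists usually re-implement ad hoc: build a chronology, convert
concentrations to fluxes, separate what the catchment eroded from what
the atmosphere delivered, and judge the result against sediment-quality
guidelines.  `sedflux` implements that chain as a tested library with a
CLI, plus a forward simulator that generates cores with known ground
truth so every stage can be validated end to end.

## The model chain

**CRS chronology.** The constant-rate-of-supply model assumes a constant
flux P of unsupported ²¹⁰Pb.  With I(m) the residual unsupported
inventory below cumulative dry mass m,

    t(m) = (1/λ) · ln(I₀/I(m)),      MAR = λ·I/A,      λ = ln2 / 22.3 yr⁻¹,

giving each layer a calendar year and a mass accumulation rate
(g m⁻² yr⁻¹).  Supported ²¹⁰Pb comes from ²²⁶Ra (or a deep asymptote);
inventory missed below the core bottom is restored by an exponential
tail fit; layers older than the ~150-yr dating horizon get years by
linear extrapolation of the deepest four dated layers.

**Flux apportionment.** Per layer i and element, F_tot,i = C_i · MAR_i.
The total is split into a background flux F_B (mean pre-1900 flux), an
erosion-driven part F_V,i = F_B·(MAR_i/MAR_pre-1900 − 1), and the
residual atmospheric/point-source part F_A,i = F_tot,i − F_B − F_V,i.
The three parts sum to the total exactly at every layer; negative F_A is
kept as a diagnostic of an overestimated background or erosion term.
Instantaneous flood layers are screened out by a robust MAR spike rule
before any averaging.

**Assessment.** Period means (pre-/post-1950, recent) are classified
against LEL/ERL sediment-quality thresholds and agricultural-soil
thresholds, lakes are compared element-by-element, and concentrations
are screened for correlation with organic-matter indicators (C, N, S).

See `docs/methods.md` for assumptions, numerical choices and limitations.

## Worked example

Simulate a remote highland lake (constant pre-1950 MAR of 69 g m⁻² yr⁻¹
doubling after 1950, Hg carrying a 42% post-1950 atmospheric share) and
run the full pipeline:

```sh
sedflux simulate --preset remote-highland --seed 0 --out sim/
sedflux run sim/remote-highland_core.csv --coring-year 2014 --out run/
```

or drive the same steps from the numbered scripts:

```sh
python analysis/01_simulate_cores.py
python analysis/02_build_chronologies.py
python analysis/03_apportion_fluxes.py
python analysis/04_assess_contamination.py
python analysis/05_worked_examples.py
```

which prints, among other lines:

```
remote-highland: 16 CRS-dated layers, supported 24.9 Bq/kg, missing inventory 9.9 Bq/m2, median |year error| 0.5 yr
remote-highland: post-1950 Hg shares — background 32.0%, erosion 29.2%, atmospheric 38.8%
remote-highland: Hg vs C — r = 0.95, p = 1.4e-13
catchment/lake ratios: peri-urban 252, remote 18, quotient 14.3
peri-urban recent LEL factors: Cr 1.3, As 7
Zn pre-1950 concentration ratio: 2.34
```

Reading this: the CRS model dated 16 layers against a ²²⁶Ra-based
supported level of ~25 Bq kg⁻¹ and recovered the simulator's deposition
years to a median error of half a year despite 5% counting noise; the
post-1950 mercury flux in the
remote lake splits into roughly one third background, one third enhanced
soil erosion and 39% atmospheric deposition for this seed (42% was
generated; the 20-seed mean recovers 42.2); mercury tracks the
organic-matter series strongly, as organically bound transport predicts.
The final lines are desk calculations from the published study tables:
the peri-urban lake's catchment/lake-area ratio of 252 versus 18 for the
remote lake, and its recent sediments exceeding the low-effect level by
1.3× for Cr and 7× for As.

## Layout

```
src/sedflux/        library: core_io, chronology, apportionment,
                    assessment, synthetic, published, cli
analysis/           numbered narrative drivers writing results/
tests/              pytest suite (unit, property and acceptance tests)
scripts/acceptance.py
docs/methods.md     model assumptions, numerical choices, limitations
```
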