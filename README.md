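# aquage

Cell number balances and confocal biofilm quantification for
drinking-water reactor studies.

## The problem

Bench-scale annular reactors fed with tap water are the standard model
for asking how distribution-system conditions — water age, disinfectant
residual, stagnation — shape the microbiology of drinking water. Two
questions recur in such studies and are surprisingly fiddly to compute
reproducibly:

1. **Where do the cells in the bulk water come from?** Flow-cytometry
   intact cell counts (ICC, cells/mL) in the influent and the reactor,
   plus areal biofilm counts (cells/cm²), feed a reactor *number
   balance*. Growth in the bulk and transfer of cells from the wall
   biofilm cannot be separated from counts alone, so they are lumped
   into one source term, the **Net Growth/Transfer Rate** (NGTR,
   cells/day). Modelling the reactor as a continuously stirred tank
   (volume *V*, flow *Q*, biofilm area *A*):

   ```
   dN/dt = (dN/dt)_bulk + (dN/dt)_biofilm = C_tap·Q − C_AR·Q + NGTR
   ```

   Two estimators solve this for NGTR: a **non-steady-state** (NSS)
   balance between two biofilm sampling days, where the accumulation
   term is Δ[C_AR·V + C_BF·A]/Δt and the advective terms use window
   averages, and an **instantaneous-steady-state** (ISS) balance at a
   single sampling event, NGTR = (C_AR − C_tap)·Q, which needs no
   biofilm measurement. Negative NGTR (net decay, e.g. under high
   chlorine) is reported as-is.

2. **How much biofilm is there, and what is it made of?** Confocal
   z-stacks stained for nucleic acids (SYTO9), protein (Sypro Orange)
   and polysaccharide (ConA) are reduced to area coverage, maximum
   area, **maximum biofilm height** (MBH: number of z slices with any
   detected voxel × slice thickness), **biovolume** (Σ slice area ×
   slice thickness) and EPS metrics, via median denoising, per-channel
   global Otsu thresholding, removal of the first four z slices (a
   substrate staining artifact), and OR-merging of channel masks — all
   three channels for total biomass, protein + polysaccharide only for
   the extracellular polymeric substances (EPS).

The package also provides the derived water-quality metrics behind such
studies (ICC/TCC intact fractions, ATPi/ATPt, ATP per intact cell,
biofilm fraction of the whole reactor, geometric means and geometric
CVs, Kendall's tau-b), and synthetic-data generators — a forward CSTR
simulator and a cluster-based z-stack rasterizer — with exact ground
truth, so every stage is testable end to end.

## Worked example

```sh
python examples/02_number_balance.py
```

```
reactor HRT = 8.0 h
Phase I: ISS NGTR = 6.35e+07 cells/day, tap input = 2.99e+06 cells/day (4.7% of NGTR)
Phase II: ISS NGTR = 3.86e+08 cells/day, tap input = 7.56e+06 cells/day (2.0% of NGTR)
NSS window (0, 10] d: accumulation = 2.91e+06 cells/day, NGTR = 4.52e+07 cells/day
```

At phase-average concentrations the tap contributes only a few percent
of the cells appearing in the reactor: the bulk community is dominated
by in-reactor growth and transfer from the biofilm, and the NGTR rises
by almost an order of magnitude when influent water age is elevated
(Phase II). The other examples cover the derived water metrics
(`01`), z-stack quantification against voxel ground truth (`03`), and
NGTR recovery from a simulated series (`04`):

```
window (0, 5] d: NSS NGTR = 5.000e+07 cells/day, truth = 5.000e+07, error = 0.00%
window (5, 10] d: NSS NGTR = 5.004e+08 cells/day, truth = 5.000e+08, error = 0.09%
```

A thin CLI wraps the same functions:

```sh
aquage simulate-series --out sim/ --seed 1
aquage balance --bulk sim/bulk.csv --biofilm sim/biofilm.csv --out ngtr.csv
aquage simulate-stack --out stack.tif --seed 1
aquage quantify --stack stack.tif --out metrics.json
```

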