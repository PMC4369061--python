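# phenoshoot

Shoot phenotyping analytics for multi-view RGB imaging and PAM
chlorophyll-fluorescence quenching measurements.

Automated phenotyping platforms image potted plants from several views and
record chlorophyll fluorescence under a timed saturation-pulse protocol.
Turning those raw images and traces into biology — how fast is a cultivar
growing, how is its photosystem II coping with cold — takes a chain of
image analysis and statistics that this package implements end to end:

* **Green-mask segmentation** robust to thread-like tendrils one or two
  pixels wide: hue thresholding in HSV space fused with Canny edge
  tracking, so a single noisy pixel cannot cost a whole offshoot.
* **Growth analytics**: pixel→mm² calibration from reference objects,
  combination of the per-view projections as A = √(Ax² + Ay² + Az²),
  normalized green area NGA(d) = A(d)/A(day 1), and relative growth rate
  RGR = (mean ln W₂ − mean ln W₁)/(t₂ − t₁) over groups of plants.
* **PSII quenching analysis**: the four measured fluorescence levels
  (F0, FM, F(t), FM′) extracted from a timed trace or image stack, the
  estimated F0′ = F0/((FM−F0)/FM + F0/FM′), and the six quantum-yield /
  quenching parameters Φ_Po, Φ_P, Φ_PSII, q_P, Φ_f,D, Φ_NPQ, which satisfy
  Φ_P + Φ_f,D + Φ_NPQ = 1 and Φ_P = q_P·Φ_PSII identically.
* **Group statistics**: Mann–Whitney U tests (exact where feasible),
  Spearman rank correlation with permutation p values, median/quartile
  summaries.
* **Synthetic data** with exact ground truth — procedural plants with 1–2
  px tendrils, exponential growth series, protocol-timed quenching traces
  — so the whole pipeline is testable without instrument data.

## Worked example

Quenching analysis of one region-mean trace:

```python
from phenoshoot import fluorescence as fl
from phenoshoot import synthetic as syn

times, signal = syn.make_trace(syn.TraceSpec(f0=200, fm=1000, ft=400, fmp=700))
levels = fl.extract_levels(times, signal)
y = fl.quantum_yields(levels)
print(f"phi_Po={y.phi_po:.3f} phi_P={y.phi_p:.3f} phi_fD={y.phi_fd:.3f} "
      f"phi_NPQ={y.phi_npq:.3f} sum={y.phi_p + y.phi_fd + y.phi_npq:.3f}")
```

prints

```
phi_Po=0.800 phi_P=0.429 phi_fD=0.400 phi_NPQ=0.171 sum=1.000
```

Φ_Po = 0.8 is a healthy dark-adapted maximal PSII yield (Fv/Fm); in the
light, 43% of absorbed excitation drives photochemistry, 40% is lost to
constitutive dissipation and 17% to regulated heat dissipation — and the
three partition absorbed energy to exactly one.

The same pipeline from the shell, on a generated demo dataset of two
cultivar groups (a fast grower with stable photochemistry and a slow one
whose FM declines under cold):

```sh
phenoshoot simulate --out demo/data --seed 1 --n-trays 2 --days 1,8,21
phenoshoot segment  --images demo/data/images --out demo/seg
phenoshoot growth   --areas demo/seg/areas.csv \
                    --calibration demo/data/calibration.csv \
                    --groups demo/data/groups.csv --out demo/growth
phenoshoot fluor    --traces demo/data/traces --out demo/fluor
phenoshoot report   --plant-areas demo/growth/plant_area.csv \
                    --fluor demo/fluor/fluor.csv \
                    --groups demo/data/groups.csv \
                    --fw demo/data/fw.csv --out demo/report
```

`demo/growth/rgr.csv` then holds per-group growth rates per interval:

```
group,day_start,day_end,RGR_per_day,n
fast,1,8,0.0779176260742220,2
fast,8,21,0.0713888715904606,2
slow,1,8,0.0502994524898095,2
slow,8,21,0.0617353479716715,2
```

— the fast group grows at ~0.07–0.08 d⁻¹ versus ~0.05–0.06 d⁻¹ for the
slow group, matching the generative contrast. `demo/report` adds per-day
Mann–Whitney tests of area and NGA, per-group yield medians with
quartiles, and the Spearman correlation of final-day green area against
fresh weight.

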