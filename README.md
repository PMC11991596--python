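# vegcarbon

A raster pipeline for regional vegetation carbon-sink analysis. It answers
four questions about a landscape from gridded monthly climate
(temperature, precipitation, solar radiation), NDVI and vegetation-type
data:

1. **How much carbon does vegetation fix?** Net primary productivity via a
   light-use-efficiency (CASA-style) model,
   `NPP(x,t) = APAR(x,t) · ε(x,t)`, with `APAR = SOL · FPAR · 0.5` and
   `ε = Tε1 · Tε2 · Wε · ε_max`.
2. **Is the region a sink or a source?** Net ecosystem productivity
   `NEP = NPP − Rh`, with soil heterotrophic respiration from the
   empirical monthly form
   `Rh = 0.22 · (e^{0.0913T} + ln(0.3145R) + 1) · 30 · 0.465`;
   pixels with NEP > 0 are sinks, NEP < 0 sources, and regional totals are
   reported in Tg C a⁻¹.
3. **Where is it changing?** Per-pixel least-squares trend of annual NEP
   with F-test significance and a five-class trend map.
4. **Why?** Pixel-wise second-order partial and multiple correlations with
   climate (nine driving types), plus an optimal-parameter GeoDetector:
   the q-statistic `q = 1 − Σ_h N_h σ_h²/(N σ²)` of each driver after
   discretization search, factor-interaction typing and risk detection of
   optimal factor ranges.

Every stage is exercisable on synthetic rasters with recorded ground truth
(injected trends, stratum effects, climate couplings), so the whole chain
is testable without downloading any data. It is aimed at carbon-cycle and
spatial-ecology researchers who want a transparent, configurable
implementation of this widely used analysis stack.

## Worked example

Run the default desk-scale scenario — a synthetic subtropical province of
100×100 one-km pixels over 24 years, with a known stratified driver effect
injected through the impervious-surface-change layer:

```bash
vegcarbon run --output-dir my_run --seed 0
```

(or from Python: `run_pipeline(PipelineConfig(output_dir="my_run"))`).
`my_run/report.json` then contains, among other sections:

```
nep.multiyear_mean_gC_m2      548.62    mean annual NEP over valid area
nep.budget.sink_total_TgC     5.49      regional sink, Tg C a⁻¹ (10⁴ km²)
nep.budget.sink_area_fraction 1.0       every pixel a net sink
trend.mean_slope              1.35      g C m⁻² a⁻¹ per year, rising
validation.r                  0.938     NPP vs reference at 100 points
```

The trend classes report 40.6 % of the area with a significant NEP
increase (19.6 % extremely significant + 21.0 % significant) and 59.2 %
stable. The OPGD q-table ranks the injected causal driver first —
impervious-surface change reaches q = 0.595 against ≤ 0.18 for every
passive factor — and the risk detector recovers its stratum means
(350.5 / 533.3 / 762.0 g C m⁻² a⁻¹; the injected effects are
+100/+300/+500 on top of the process NEP), flagging stratum 3 as the
optimal range. The attribution map types 93.8 % of pixels as
climate-driven, dominated by precipitation-involving types — by
construction NDVI (and hence NEP) co-varies most strongly with
precipitation anomalies.

Each stage can also be run standalone on the saved intermediates
(`vegcarbon generate | npp | validate | nep | trend | attribute | opgd`),
and every run copies its resolved config to `config_used.yaml`; rerunning
with the same config and seed reproduces `report.json` byte for byte.

See `docs/methods.md` for the model details, the synthetic-data generating
process, and the design decisions.

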