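# lipidhca

High-content image analysis of obesogen-induced lipid accumulation in
human liver cells — with a ground-truth synthetic microscopy simulator
that makes every stage of the pipeline testable without external data.

## The problem

Environmental "obesogens" such as tributyltin (TBT) raise neutral-lipid
content in liver cells at sub-nanomolar doses, activate lipogenic genes
(*SREBF1*, *FASN*), and simultaneously drive proteasomal down-regulation
of their own receptor, RXRA — yet at the single-cell level RXRA
abundance barely correlates with lipid content. Quantifying this
requires an imaging pipeline: segment nuclei (primary objects), grow
whole cells around them (secondary), derive cytoplasm (tertiary),
segment lipid droplets, relate droplets to cells, extract per-cell
features with QC, count smFISH spots, and run the statistics —
Kruskal–Wallis/Dunn, Mann–Whitney, Spearman, four-parameter logistic
(4PL) EC50/IC50 fits, z/fold normalization and comparative Ct.

`lipidhca` is that pipeline as a reusable, tested library for imaging
scientists and tool builders. Because the original measurements come
from live cells, validation is by *parameter recovery*: a seeded
simulator renders multi-channel fields (DAPI-style nuclei with
pyknotic/mitotic outliers, dose-responsive droplets, receptor
immunofluorescence, Poisson smFISH spots, Gaussian-copula cross-channel
coupling) whose generative truth carries the study's printed effect
sizes, and the pipeline must measure them back.

## The model at the core

Responses follow the four-parameter logistic. For a stimulatory readout

    y(d) = bottom + (top − bottom) / (1 + (EC50 / d)^h),

and for an inhibitory one y(d) = top + (bottom − top)·d^h/(d^h + IC50^h).
The generator drives per-cell droplet counts (negative binomial around
the 4PL, bottom 3 → top 30, EC50 0.46 nM), droplet areas (log-normal,
scaled 1.6× at saturation), nuclear RXRA (inhibitory 4PL, IC50 9 nM,
top 1.0 → bottom 0.35) and PPARG (1.3× at saturation) through these
curves; single-cell coupling uses a Gaussian copula whose rank
correlation is r_s = (6/π)·asin(ρ/2). Fitting inverts the same model by
multi-start least squares on log10 dose. `docs/methods.md` documents
every stage, parameter and known limitation.

## Worked example

Simulate an RXRA dose series (vehicle + 50 pM–50 nM, 8 fields per
condition, ~400 cells each), run segmentation, quantification, QC and
statistics, and read off the recovered pharmacology:

```python
from lipidhca import FieldConfig, RunConfig, run_experiment

config = RunConfig(
    preset="fig4_rxra",          # vehicle + 4 TBT doses, RXRA immunofluorescence
    seed=7,
    out_dir="results/fig4_demo",
    n_fields=8,
    field_config=FieldConfig(field_size_px=(416, 416), cells_per_field_mean=50),
)
bundle = run_experiment(config)

fit = bundle.stats["ic50_fit_rxra"]
print(f"cells analyzed (QC pass): {bundle.stats['n_cells_pass']}")
print(f"fitted IC50: {fit['IC50']:.2f} nM  (hill {fit['hill']:.2f})")
print(f"RXRA fold-down at 50 nM: {bundle.stats['rxra_fold_down_top_dose']:.2f}")
print(f"Kruskal-Wallis across doses: H = {bundle.stats['kruskal_rxra']['statistic']:.1f}, "
      f"p = {bundle.stats['kruskal_rxra']['p_value']:.2e}")
```

Output:

```
cells analyzed (QC pass): 1829
fitted IC50: 11.32 nM  (hill 0.77)
RXRA fold-down at 50 nM: 2.19
Kruskal-Wallis across doses: H = 999.2, p = 5.23e-215
```

The simulator's generative truth put the IC50 at 9 nM and the maximal
down-regulation at 2.23-fold (1/0.449): from rendered, noisy, re-segmented
images the pipeline recovers 11.3 nM and 2.19-fold, and the dose effect
is overwhelmingly significant across ~1800 single cells. `out_dir` now
holds the manifest, per-cell and per-droplet tables, the condition
summary, `stats.json` and the full config with its hash — rerunning the
same config and seed reproduces them bit-for-bit.

The same machinery is available from the shell:

```bash
lipidhca run-all --preset fig6_dual --seed 42 --out results/fig6
lipidhca simulate --preset fig2_timedose --seed 1 --out plate/   # TIFFs + manifest
lipidhca segment  --manifest plate/manifest.csv --images plate/ --out masks/
```

Presets mirror the assay designs: `fig1_14day`, `fig2_timedose` (5 doses
× 3 times), `fig3_2dg` (glycolysis-inhibitor co-treatment + smFISH),
`fig4_rxra`, `fig6_dual` (RXRA+lipid dual label), `s3_pparg`
(RXRA+PPARG).

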