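# Demo configuration: full axis construction -> imputation -> axis-variable
# gene workflow on generated data. Run with:
#   axistk run --config configs/demo_axis_svg.yaml
workflow: axis_svg
seed: 7
outdir: results/demo_axis_svg
n_units: 600
n_genes: 150
frac_gradient: 0.3
n_query_cells: 400
panel_size: 40
k: 50
n_bins: 20
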