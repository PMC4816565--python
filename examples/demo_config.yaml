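# Demo battery: synthetic ternary water/DMF/trehalose box with planted
# preferential hydration (water enriched 3x, DMF depleted, trehalose
# excluded near the protein), plus synthetic fluorescence curves.
output_dir: demo_output
seed: 7
synthetic_preset: ternary_hydration
synthetic_frames: 20
analyses: [rmsd, rg, rmsf, rdf, gnow, hbonds, thermo]
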