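"""Generate a synthetic four-block case/control study and write it to CSV.

The generator emulates an untargeted plasma LC-MS study: four blocks
(lipidomics/metabolomics x ESI+/ESI-), log-normal intensities, a few planted
discriminative analytes, repeat-sample subjects, pooled QC injections, and
missing values/zeros.
"""

from mbomics import SimConfig, generate_multiblock, write_dataset

config = SimConfig(
    n_case=60,
    n_control=64,
    block_specs=[
        ("lipidomics_pos", 50, 2),
        ("lipidomics_neg", 30, 2),
        ("metabolomics_pos", 40, 2),
        ("metabolomics_neg", 20, 2),
    ],
    effect_size=1.5,  # planted shift in units of the log10 SD
    within_subject_repeats=5,
    missing_rate=0.02,
    zero_rate=0.01,
    qc_count=6,
    seed=42,
)
dataset, truth = generate_multiblock(config)

paths = write_dataset(dataset, "scratch/example_dataset")
for block in dataset.blocks:
    print(f"{block.block_id}: {block.n_samples} samples x {block.n_analytes} analytes")
print(f"groups: {dataset.samples['group'].value_counts().to_dict()}")
print(f"planted discriminative analytes: {sorted(truth.informative_ids())}")
# Each block CSV has sample_id/subject_id/group columns then analyte columns;
# the planted analytes are the ground truth every downstream model should find.
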