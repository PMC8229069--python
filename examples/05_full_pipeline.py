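"""Run the whole pipeline for all three families from a config mapping.

Equivalent to `satprofile run --config cfg.yaml`; artifacts (per family:
samples/reference FASTA, truth table, anchored MSA, profile TSV/JSON, groups
JSON, Newick tree, plus report.json and run.log) land in the output directory.
"""

from satprofile import RunConfig, run_pipeline

config = RunConfig.from_dict(
    {
        "seed": 11,
        "output_dir": "pipeline_out",
        "families": {
            "CON2": {"simulate": {"fixture": "con2", "flanks": True}},
            "CON1": {"simulate": {"fixture": "con1_triplet"}},
            "COM2": {"simulate": {"fixture": "com2_unique"}},
        },
    }
)
report = run_pipeline(config)
for name, fam in report.families.items():
    print(
        f"{name}: {fam['n_samples']} samples, {fam['msa_columns']} bp, "
        f"{fam['n_alteration_columns']} alteration columns, group sizes {fam['group_sizes']}"
    )
# Expected: CON1 11 columns, CON2 8, COM2 9 — with CON2 falling into four
# groups (4/6/2/1) and every COM2 profile unique.
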