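"""The whole workflow in one call: simulate -> QC -> averaged-LOD scan ->
PPL -> family selection -> PPLD fine-mapping -> FBA -> haplotype sharing.

Equivalent to `ngla run --config run.yaml`; every output TSV records the
seed and configuration hash, so reruns are byte-identical.
"""

from ngla.pipeline import RunConfig, run_pipeline

cfg = RunConfig(
    seed=11,
    out_dir="scratch/example_pipeline",
    overwrite=True,
    simulation={
        "n_families": 8,
        "family_size_range": (20, 30),
        "n_markers": 60,
        "planted": {"carrier_families": ("2", "4")},
    },
    # weak linkage at this study size leaves the PPL peak poorly localized,
    # so fine-map a generous flank; the haplotype MAF cap reflects the
    # founder count (2 carrier chromosomes among ~60 founders ~ 0.017)
    ppld={"families": "all", "flank_cm": 50.0},
    haplotypes={"maf_max": 0.02},
)
res = run_pipeline(cfg)
print(res["summary"])
print("tables written:", ", ".join(sorted(res["tables"])))
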