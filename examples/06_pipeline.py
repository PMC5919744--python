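"""Run the whole workflow from one config (simulate -> ... -> predict).

Equivalent shell form:
    curdpred run --config examples/pipeline_config.yaml --out scratch/run
"""

from pathlib import Path

from curdpred.pipeline import RunConfig, run_pipeline

cfg = RunConfig.from_dict(
    {
        "out_dir": "scratch/pipeline_demo",
        "seed": 1,
        "stages": ["simulate", "filter", "impute", "pheno", "gwas", "predict"],
        "simulation": {
            "n_individuals": 60,
            "n_chromosomes": 3,
            "markers_per_chromosome": 80,
            "missing_range": [0.15, 0.4],
            "traits": [{"name": "t", "n_qtl": 5, "h2": 0.8}],
        },
        "params": {"predict": {"reps": 3}},
    }
)
manifest = run_pipeline(cfg)
for a in manifest["artifacts"]:
    print(f"{a['stage']:9s} {a['path']}")
print(f"{len(manifest['artifacts'])} artifacts in {cfg.out_dir} (checksums in manifest.json)")
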