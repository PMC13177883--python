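"""Run the whole study replica end to end and show the manifest.

Equivalent to `cpcea run --config examples/pipeline_config.yaml --out out/`.
"""

from pathlib import Path

from cpcea import run_pipeline

out_dir = Path("pipeline_output")
manifest = run_pipeline(Path(__file__).with_name("pipeline_config.yaml"), out_dir)

print(f"master seed: {manifest.master_seed}")
print(f"config hash: {manifest.config_hash[:16]}...")
for stage, files in manifest.outputs.items():
    print(f"{stage}: {', '.join(files)}")
print(f"\nHuman-readable report: {out_dir / 'report.txt'}")
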