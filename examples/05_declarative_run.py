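"""Running a design from a declarative YAML config.

The same selective-binder problem as example 01, but assembled from
``selective_binder.yaml`` instead of Python objects, and executed with
the standard output layout (config.csv, optimization.log, current/ and
best/ trees with energies, per-step FASTA and mmCIF structures).

Run:  python examples/05_declarative_run.py
"""

from pathlib import Path

from foldscape import execute_run, read_run_config

config_path = Path(__file__).parent / "selective_binder.yaml"
out_dir = Path("scratch") / "declarative_run"

spec = read_run_config(config_path)
result = execute_run(spec, out_dir, structure_every=50)

print(f"steps run     : {len(result.trajectory) - 1}")
print(f"best energy   : {result.best_energy:+.4f}")
print(f"best binder   : {result.best_sequences['binder']}")
print(f"output layout : {out_dir}/")
files = sorted(p.relative_to(out_dir) for p in out_dir.rglob("*") if p.is_file())
for rel in files[:8]:
    print(f"  {rel}")
print(f"  ... ({len(files)} files total)")
print()
print("optimization.log has one row per MC step (temperature, accepted,")
print("energy); energies.csv one '<state>:<Term>' column per bound term.")
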