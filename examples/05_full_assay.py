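"""The full assay pipeline on a two-system synthetic study.

Runs windowing -> superposition -> DCCM -> region scores -> H12 profile ->
activation verdict -> signature panel -> clustering -> helicity -> RMSF for
a planted-active and a planted-inactive system, then writes the deterministic
CSV report.  Equivalent shell form:  erassay run --config cfg.yaml --out out/
"""

import tempfile
from pathlib import Path

from erassay import run_assay, write_report

config = {
    "params": {"window_mode": "fraction", "window_value": 0.6},
    "systems": [
        {
            "name": "planted_active", "isoform": "WT", "ligand": "EST",
            "synthetic": {
                "seed": 71, "n_frames": 400, "dt_ns": 0.25, "sigma": 1.0,
                "correlations": [
                    {"region_a": [540, 540], "region_b": [350, 355],
                     "rho": 0.75, "chain_a": "A", "chain_b": "A"},
                    {"region_a": [540, 540], "region_b": [350, 355],
                     "rho": 0.75, "chain_a": "B", "chain_b": "B"},
                ],
            },
        },
        {
            "name": "planted_inactive", "isoform": "WT", "ligand": "FULV",
            "synthetic": {"seed": 72, "n_frames": 400, "dt_ns": 0.25,
                          "sigma": 1.0},
        },
    ],
}

report = run_assay(config)
print(report.summary().to_string(index=False))

with tempfile.TemporaryDirectory() as td:
    paths = write_report(report, td)
    files = sorted(p.relative_to(td) for p in Path(td).rglob("*") if p.is_file())
    print("\nreport files written:")
    for f in files:
        print(f"  {f}")

print()
print("The planted-active system crosses the H12-H3 activation score of 4 in")
print("both monomers (tier high, drug ineffective); the unplanted system")
print("stays at 0 (tier low, drug effective).")
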