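"""Run the whole analysis end to end on a synthetic study:
simulate -> composite scoring -> dose-effect models -> PLSR-VIP screening
-> piecewise SEM -> liver/gastric correlation table."""

import json
from pathlib import Path

from udpharm import PipelineConfig, run_pipeline
from udpharm.simdata import default_config

outdir = Path("scratch_pipeline_run")
manifest = run_pipeline(
    PipelineConfig(outdir=outdir, simulate=default_config(seed=42), seed=42)
)

print(f"stages completed: {manifest['n_stages']}")
for stage in manifest["stages"]:
    print(" ", stage)

print("\npruned path models per composite outcome "
      "(p > 0.05 means the data are consistent with the paths kept):")
for psem_file in sorted(outdir.glob("psem_*.json")):
    psem = json.loads(psem_file.read_text())
    print(f"  {psem_file.stem[5:]:6s} Fisher's C = {psem['fisher_c']:8.3f}, "
          f"p = {psem['p_value']:.3f}, AIC = {psem['aic']:.1f}, "
          f"paths kept = {len(psem['paths'])}")
print(
    "\nMost composite outcomes are rejected here, and that is the method\n"
    "working as intended: the VIP screen wires compositionally-coupled\n"
    "genus abundances into every outcome, and the d-separation test\n"
    "correctly flags the claims those couplings violate.  Hand-built DAGs\n"
    "with the true mediators (see 05_psem_mediation.py) fit cleanly.\n"
    f"(see the CSVs in {outdir}/ for coefficients, VIPs and correlations)"
)
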