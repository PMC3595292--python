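"""Generate the synthetic study landscape and season.

Writes terrain rasters, the tree inventory, the sampling-site layout,
per-date site observations of leaf area index (L) and surface soil
moisture (theta), depth profiles, daily watershed-mean series and the
ground-truth parameter file under results/analysis/.
"""

import json

from common import OUTDIR, parse_seed, run_config

from ecokrige.pipeline import run_pipeline

seed = parse_seed(__doc__)
manifest = run_pipeline(run_config(seed, ("simulate",)))
info = manifest["stages"]["simulate"]
truth = json.load(open(f"{OUTDIR}/truth.json"))

print(f"simulated landscape -> {OUTDIR}")
print(
    f"  domain {truth['domain']['width_m']:.0f} x {truth['domain']['height_m']:.0f} m"
    f" ({truth['domain']['area_ha']:.1f} ha), relief {truth['domain']['relief_m']} m"
)
print(f"  {info['n_trees']} trees of {len(truth['species'])} species, {info['n_sites']} sites")
print(f"  measurement dates: {', '.join(info['dates'])}")
print(
    f"  planted coupling: theta responds to L with a {truth['season']['lag_days']}-day"
    f" delay (k = {truth['season']['coupling_k']})"
)
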