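"""Leave-one-out validation of the spatial model, per date and variable.

Each site is predicted from the other sites under the full-data (phi, nu)
posterior; fit quality is the R^2 of the observed-on-predicted regression,
reported alongside each date's parameter summary.
"""

import pandas as pd

from common import OUTDIR, parse_seed, run_config

from ecokrige.pipeline import run_pipeline

seed = parse_seed(__doc__)
run_pipeline(run_config(seed, ("xval",)))

xv = pd.read_csv(f"{OUTDIR}/xval_summary.csv")
print(f"leave-one-out validation -> {OUTDIR}/xval_summary.csv")
for var in ("L", "theta"):
    sub = xv[xv["variable"] == var]
    print(
        f"  {var}: R^2 = {sub['r2'].min():.2f}..{sub['r2'].max():.2f}"
        f" over {len(sub)} dates (slope {sub['slope'].mean():.2f} on average)"
    )
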