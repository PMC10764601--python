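"""Analyse a user-supplied delimited dataset.

Shows the round trip a practitioner would use: write records to CSV (here
produced by the simulator, but any file with columns time1, time2,
illness, death, treatment and numeric covariates works — column names are
remappable via the `schema` argument), read and validate them, and obtain
effect estimates either through the library or the `sepid` command line:

    sepid simulate --study 1 --scenario i --n 400 --seed 7 --out d.csv
    sepid estimate d.csv --tau-grid 5,15,25 --estimator both --boot 100
"""

import tempfile
from pathlib import Path

import sepid as sp

tmp = Path(tempfile.mkdtemp())
path = tmp / "study.csv"
sp.write_dataset(sp.simulate_observed_study1(sp.make_scenario(1, "i", n=400, seed=7)),
                 path)

data = sp.read_dataset(path)                       # validates every record
print(f"read {data.n} records with covariates {data.covariates}")

nuisances = sp.fit_nuisances(data)
result = sp.contrasts(nuisances, data, tau_grid=[5.0, 15.0, 25.0],
                      estimator="one_step")
print(result.to_frame().to_string(index=False))
result.to_csv(tmp / "effects.csv")
print(f"\nwrote {tmp / 'effects.csv'}")
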