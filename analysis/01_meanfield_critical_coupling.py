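"""Mean-field theory of the balanced LIF network and its matched rate model.

Sweeps the Ricciardi self-consistent population rate over the coupling J for
the C=1000 and C=4000 parameter sets, evaluates the bulk spectral radius of
the linearized rate dynamics along the sweep, and bisects the critical
coupling J_c where the matched rate network loses stability.  The two J_c
values (~0.49 mV at C=1000, ~0.96 mV at C=4000) are the quantities the rest
of the reanalysis compares against; note they are independent of the
transmission delay.

Writes results/meanfield/meanfield_sweep.csv and prints the two J_c values.
"""
import argparse

import numpy as np
import pandas as pd

from ratechaos.meanfield import critical_coupling, solve_selfconsistent, _bulk_radius
from ratechaos.params import default_params, scale_network


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--out", default="results/meanfield")
    args = ap.parse_args()

    rows = []
    for factor, label in [(1, "C=1000"), (4, "C=4000")]:
        p = scale_network(default_params(), factor)
        res = critical_coupling(p)
        print(f"{label}: J_c = {res.J_c:.4f} mV")
        for J in np.arange(0.1, 1.21, 0.05):
            sol = solve_selfconsistent(p, J)
            rows.append({"set": label, "J": J, "nu0_hz": sol.nu0, "mu": sol.mu,
                         "sigma": sol.sigma, "radius": _bulk_radius(J, p),
                         "J_c": res.J_c})
    import pathlib

    out = pathlib.Path(args.out)
    out.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(rows).to_csv(out / "meanfield_sweep.csv", index=False)
    print(f"wrote {out / 'meanfield_sweep.csv'}")


if __name__ == "__main__":
    main()
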