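#!/usr/bin/env python
"""Average marginal effects by year, and sign shares of random coefficients.

The marginal effect of an indicator is the mean change in the fatal
probability when it flips 0 -> 1 (toggled everywhere it appears, including
shifter roles), simulated under common draws.  The sign share is the mass of
a random coefficient's normal mixing distribution on each side of zero.
"""

import json
from pathlib import Path

import pandas as pd

import crashlogit as cl

OUT = Path("results/analysis")
DATA = Path("scratch/demo_crash_table.csv")


def main() -> None:
    table = cl.load_crash_table(DATA)
    serialized = json.loads((OUT / "fits.json").read_text())
    fits = {
        int(y): cl.FitResult.from_json_dict(b) for y, b in serialized.items() if y != "pooled"
    }
    spec = next(iter(fits.values())).spec
    variables = list(spec.fixed) + list(spec.random_names)

    rows = []
    for year in sorted(fits):
        sub = table.subset_year(year)
        draws = cl.normal_draw_matrix(spec, sub.n)
        for v in variables:
            rows.append(
                {
                    "variable": v,
                    "year": year,
                    "me": cl.average_marginal_effect(fits[year], sub, v, draws),
                }
            )
    me = pd.DataFrame(rows).pivot(index="variable", columns="year", values="me").reindex(variables)
    me.round(4).to_csv(OUT / "marginal_effects.csv")

    share_rows = []
    for year in sorted(fits):
        for name, rc in fits[year].params.random.items():
            s = cl.sign_share(rc.beta, rc.sigma, variable=name)
            share_rows.append(
                {"year": year, "variable": name,
                 "below_zero": round(s.below_zero, 4), "above_zero": round(s.above_zero, 4)}
            )
    shares = pd.DataFrame(share_rows)
    shares.to_csv(OUT / "sign_shares.csv", index=False)

    print("average marginal effects on the fatal probability:")
    print(me.round(4).to_string())
    print("\nnormal sign shares of the random coefficients:")
    print(shares.to_string(index=False))
    print(f"-> {OUT}/marginal_effects.csv, {OUT}/sign_shares.csv")


if __name__ == "__main__":
    main()
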