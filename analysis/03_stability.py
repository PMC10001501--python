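#!/usr/bin/env python
"""Temporal-stability battery over the fitted yearly models.

Reloads the serialized yearly fits, re-estimates each donor year's retained
specification on every other year, and runs the pooled-vs-separate test.
Large chi-squares mean the covariate effects are not transferable across
years — the demo regimes shift by construction, so the battery should
reject for most pairs.
"""

import json
from pathlib import Path

import crashlogit as cl

OUT = Path("results/analysis")
DATA = Path("scratch/demo_crash_table.csv")


def main() -> None:
    table = cl.load_crash_table(DATA)
    serialized = json.loads((OUT / "fits.json").read_text())
    fits = {
        int(year): cl.FitResult.from_json_dict(block)
        for year, block in serialized.items()
        if year != "pooled"
    }
    pooled = cl.FitResult.from_json_dict(serialized["pooled"])
    tables = {y: table.subset_year(y) for y in fits}

    report = cl.stability_matrix(fits, tables, retention_t=1.645)
    report.pooled = cl.pooled_separation_test(
        pooled.ll_beta,
        [fits[y].ll_beta for y in sorted(fits)],
        pooled.k,
        [fits[y].k for y in sorted(fits)],
    )
    (OUT / "stability.json").write_text(
        json.dumps(report.to_json_dict(), indent=2, sort_keys=True) + "\n"
    )
    (OUT / "stability_matrix.txt").write_text(report.render_matrix() + "\n")

    print("pairwise transferability, cells as chi2 (df) [confidence%]:")
    print(report.render_matrix())
    n_reject = sum(c.confidence >= 95.0 for c in report.cells)
    print(f"{n_reject}/{len(report.cells)} ordered pairs reject at the 95% level")
    p = report.pooled
    print(f"pooled-vs-separate: chi2={p.chi2:.3f}, df={p.df}, confidence={p.confidence:.2f}%")
    print(f"-> {OUT}/stability.json, {OUT}/stability_matrix.txt")


if __name__ == "__main__":
    main()
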