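#!/usr/bin/env python
"""Decompose the seven-site instance into main and interaction effects.

Runs the 128-equation factorial decomposition of the synthetic seven-site
landscape, imputing the nonfunctional genotypes, attaches the V = I standard
errors and z-test stars, and reports the single effects and the interaction
terms with |θ| >= 5 nm.  Also verifies the stable-only reduced analysis
returns identical values for every estimable term.
"""

from pathlib import Path

from spectune import (
    attach_uncertainty,
    decompose,
    decompose_stable_only,
    s1_like_fixture,
)
from spectune.io import write_effect_table
from spectune.landscape import bit_count

OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    land, *_ = s1_like_fixture()
    eff, completed = decompose(land)
    attach_uncertainty(eff, completed)
    write_effect_table(eff, OUT / "effects.tsv")

    sites = land.sites
    singles = {lab: eff.theta[1 << i] for i, lab in enumerate(sites.labels)}
    print("single effects (nm):",
          ", ".join(f"{k}={v:+.0f}" for k, v in singles.items()))
    big = [(m, eff.theta[m]) for m in eff.subsets()
           if bit_count(m) >= 2 and abs(eff.theta[m]) >= 5.0]
    print(f"{len(big)} of {len(eff.theta) - sites.L} interaction terms have "
          f"|θ| >= 5 nm:")
    for m, th in big:
        print(f"  θ_{'x'.join(sites.labels_of(m))} = {th:+.0f} nm "
              f"{eff.stars(m)}")
    print(f"{len(eff.imputed)} genotypes nonfunctional -> θ imputed to 0")

    red = decompose_stable_only(land)
    worst = max(abs(red.theta[m] - eff.theta[m]) for m in red.theta)
    print(f"stable-only reduced analysis: {len(red.theta)} estimable θ, "
          f"max deviation from full analysis {worst:.2e} nm")


if __name__ == "__main__":
    main()
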