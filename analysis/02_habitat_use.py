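"""Which lake conditions predict pelagic crayfish abundance?

Linear model of sqrt(pelagic CPUE) on littoral CPUE, predator BPUE, %
littoral habitat and invasion year with two-way interactions backward-
eliminated. In the generated study (as in the field data) pelagic abundance
tracks littoral abundance: crowding in the preferred littoral habitat
pushes individuals into the pelagic zone.
"""

import argparse
from pathlib import Path

import pandas as pd

from respoly import abundance_model


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--datadir", default="results/data")
    ap.add_argument("--outdir", default="results")
    args = ap.parse_args()

    env = pd.read_csv(Path(args.datadir) / "environment.csv")
    fit = abundance_model(env)
    out = Path(args.outdir)
    out.mkdir(parents=True, exist_ok=True)
    fit.tests.to_csv(out / "abundance_model_tests.csv", index=False)
    fit.coefficients.to_csv(out / "abundance_model_coefficients.csv",
                            index=False)
    print(fit.tests.to_string(index=False))
    for note in fit.notes:
        print("note:", note)
    p = float(fit.tests.set_index("term").loc["cpue_littoral", "p"])
    print(f"\nlittoral CPUE effect on pelagic abundance: p = {p:.4g} "
          f"({'supports' if p < 0.05 else 'does not support'} the "
          "crowding-spillover prediction)")


if __name__ == "__main__":
    main()
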